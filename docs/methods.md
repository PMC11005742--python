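# Methods

## Problem and approach

Supervised sweep classifiers are trained on coalescent simulations and then
applied to real genomes. Because demographic and population-genetic
parameters are never known exactly, the simulated (source) and real (target)
feature distributions differ — a covariate shift that degrades any model
trained purely on simulations. `sweepdann` addresses this with a
domain-adversarial network: a shared feature extractor feeds both a 5-class
sweep predictor (trained on labeled simulations) and a domain discriminator
(trained to tell source from target), with a gradient-reversal layer between
extractor and discriminator. The saddle-point objective

    E = (1/n) Σ_source L_y(G_y(G_f(x)), y) − (λ/N) Σ_all L_d(G_d(R(G_f(x))), d)

drives the extractor toward representations that are informative for the
sweep classes but uninformative about the domain, so prediction rules learned
on simulations transfer to the target data. Training is transductive: the
unlabeled target windows that will later be scanned participate in training
through the discriminator term. λ is held constant at 1; a linear warm-up
schedule is available behind a flag (`warmup` is not used by default because
a constant weight is the reference behaviour of this model).

Stability comes from deep ensembling: M models are independently initialized
and trained, and the predictive distribution is the arithmetic mean of the
member distributions (default M=5; the acceptance run uses M=3 to fit a
single-CPU budget).

## Feature engineering

Each genomic fragment (a simulated replicate, or a 1 Mb sliding window of a
real chromosome advanced in 50 kb steps) becomes a 40 × m matrix:

1. n central SNPs are selected uniformly over the eligible index range
   (`round(k + t·(total−2k−1)/(n−1))`), each defining a window of 2k+1 SNPs;
   fragments with fewer than 2k+n SNPs are excluded.
2. 40 summary statistics are computed per window (below), giving 40 × n.
3. Each window is assigned to one of m equal physical intervals of the
   fragment by its mean SNP position (left-open, right-closed intervals;
   position 0 joins the first interval); interval values are window means and
   empty intervals are zero-filled — zero marks absence of variation, and the
   encoding turns window *order* into physical *position*, which is what
   separates selected from merely linked windows.

Defaults are n=200, k=25, m=200, w=1 Mb, s=50 kb. Feature rows are max–min
standardized per statistic across the training set; the fitted scale is
re-applied to validation, test and target data (values clipped to [0, 1]).
Fitting the scale on the target domain independently is available as a flag,
but train-fitted scaling is the default to avoid leakage. Non-finite
statistic values are clamped to the finite per-row extremes of the run
before scaling (NaNs from undefined statistics become 0 at computation
time), so a single degenerate window cannot stretch the scale.

## The 40-statistic registry

Statistics are organised as an ordered, pluggable registry; the default
roster fills exactly 40 slots from three groups:

* **Polymorphism / SFS** (selected vs neutral): ΔAF (window mean derived
  allele frequency minus the run-level mean), π, Watterson's θ, θ_H,
  Fay–Wu's H, Zeng's θ_L, π−θ_W, the 1st–5th moments and Shannon entropy
  (natural log) of the per-site derived-allele-frequency distribution, the
  fraction of singleton sites, and the fraction of sites above 0.8 frequency.
* **Favoured-mutation localisation** (selected vs linked): per-site φ (HAF
  mass of a variant's carriers over total HAF mass), κ (fraction of distinct
  haplotypes among carriers), and the SAFE contrast (φ−κ)/√(f(1−f)); each is
  summarised per window as mean, max and value at the central SNP.
* **Haplotype structure** (hard vs soft): number of distinct haplotypes and
  its ratio to sample size, haplotype heterozygosity and entropy, top-two
  haplotype frequencies, Garud's H1/H12/H123/H2-H1, HAF mean/max/sd, and
  unstandardised iHS, nSL and ΔiHH at the central SNP.

EHH integration uses the trapezoid rule over site positions (bp scale for
iHS/ΔiHH, SNP-count scale for nSL), stops after the first point below the
0.05 decay cutoff, and truncates at the window edge rather than discarding
the window — fixed-size SNP windows make the genome-scan discard convention
inapplicable. iHS is conventionally standardised within derived-frequency
bins; `standardize_ihs` provides the 20-bin z-score, while the registry
default stores the unstandardised core-site value (per-window bin counts
are too small for stable within-window standardisation). A user holding a
different roster can pass any ordered name→function mapping.

## Network architecture

Input grids are 1 × 40 × m images. The extractor applies a (1,5) convolution
with (1,4) max-pooling — scanning each statistic's positional series — then
a (3,1) convolution with (2,1) pooling — mixing statistics at fixed
position — followed by two residual bottleneck modules (1×1 reduce by 4 →
(3,1) → 1×1 expand) and flattening. The classifier has four fully connected
layers (128→64→32→5) with batch normalisation after the first two, ReLU
activations, dropout 0.5 and a softmax output; the discriminator mirrors it
with three layers (128→32→1) behind the gradient-reversal layer. Domain
labels are source=0 / target=1, so well-aligned target data scores below
0.5 on the discriminator.

Comparator extractors used in the architecture study: a generic 2-D CNN
(two 3×3/2×2 conv-pool stages), a sequence-series 1-D CNN (each statistic
row processed independently by shared (1,5)/(1,3) convolutions, so
statistics only combine in the dense head), and a tanh RNN over the m
positional steps. All share the classifier head and training loop.

Everything is implemented in a small numpy engine (`sweepdann.nn`) with
explicit backpropagation, verified against central finite differences in the
test suite; training is deterministic given a seed on a single thread.
Optimisation uses Adam (lr 1e-3, batch 64, ≤100 epochs, early stopping on
validation loss with patience 10, best checkpoint restored; training aborts
at the last finite checkpoint if the loss diverges). One gradient-descent
pass over the composite graph implements the adversarial update: θ_d
descends L_d while θ_f receives the reversed gradient −λ ∂L_d/∂θ_f.

## Synthetic data generator

The `fixture` backend is a parametric generator designed to reproduce the
*relative geometry* of sweep signals at desk scale, not coalescent
genealogies:

* Neutral background: S ~ Poisson(θ·a_n) exchangeable sites with derived
  counts drawn from the 1/i neutral frequency spectrum and uniform
  positions; there is no background linkage disequilibrium.
* Sweeps: a selected site is placed uniformly in the central 0.475L–0.525L
  segment (sweep classes) or outside it (linked classes); a fraction
  f ~ U(0.7, 0.95) of haplotypes is collapsed onto one founder haplotype
  (hard) or 2–3 founders with distinct local tags (soft) over per-haplotype
  tracts. Tract lengths are a short guaranteed core (scale/8) plus an
  exponential draw whose scale is the physical footprint s/[r ln(Ne s)] —
  the coalescent-scaled footprint approximation s/[4 Ne r ln(Ne s)]
  multiplied by 4Ne. This produces the expected diversity reduction, SFS
  distortion, elevated H12 and EHH decay centred on the selected site.
* Defaults: Ne=10⁴, μ=1.25e−8 /bp/gen, r=5e−7 /bp/gen, s=0.05, L=100 kb,
  40 haplotypes. L is 10× smaller than a real 1 Mb scan fragment and r is
  scaled up so the footprint (~16 kb) occupies the same ~0.16 fraction of
  the fragment that a several-hundred-kb footprint occupies at full scale.

What the fixture does *not* emulate: genealogical correlation of the
neutral background (no LD decay), demographic history, recurrent mutation,
and background selection (the latter is only meaningful through a real
simulator). Passing tests on fixture data therefore demonstrate that the
pipeline recovers planted sweep geometry and class structure, not that it
matches coalescent expectations; the `msprime` backend (neutral and
genic-selection sweep models) is provided for full-fidelity runs.

Robustness transforms mirror common technical and evolutionary confounders:
contiguous missing regions totalling 20% of each fragment by default;
two-segment recombination-rate heterogeneity applied to a configurable
fraction of cases (default 50%); uniform recombination reduction by factors
5/10/50/100; and class imbalance by resampling. The 16-scenario mismatch
grid crosses four recombination rates (3.125e−9 … 3.75e−8) with four
selection coefficients (0.0075 … 0.2); the two interior values on each axis
interpolate the printed extremes geometrically.

## Evaluation conventions

Sweep detection treats hard+soft as positives and linked+neutral as
negatives; the model's scalar sweep score is P(hard)+P(soft), and per-type
ROCs are one-vs-rest with the linked and neutral classes negative. The
classical-statistic comparison hook scores a fragment by the extreme
absolute statistic value over the central 0.45L–0.55L segment. Confusion
matrices are oriented predicted-on-rows / true-on-columns with
column-normalised rates. Covariate-shift diagnostics report per-statistic
two-sample Kolmogorov–Smirnov and Mann–Whitney U tests (raw p plus
Benjamini–Hochberg q across the 40 statistics), PCA of the pooled centred
features (features arrive min–max scaled, so no variance rescaling is
applied — planted mean shifts then surface in the leading component), and a
5-fold cross-validated RBF-SVM domain AUC with label-shuffle controls;
per-fold AUCs are averaged because pooling decision scores across folds
inflates the null variance.

## Desk-scale study conditions

Model-level tests and the acceptance run use 200 cases per class
(140/30/30 train/validation/test), FragmentSpec n=64, k=25/5→5, m=64 — i.e.
64 windows of 11 SNPs in 64 positional intervals — chosen as the smallest
configuration that preserves the 40×m pipeline shape, the central-segment
geometry, and a test set large enough (150 cases) to resolve class
structure. The architecture comparison trains each extractor for ≤50
epochs with three seeds; the acceptance ensemble uses M=3.

## Known limitations

* The default statistic roster is a reconstruction: the named statistics
  plus standard window summaries to fill 40 slots; a user with a different
  roster can supply it to the registry.
* The fixture generator's neutral background has no LD, so EHH-family
  statistics carry signal only through the imposed sweep structure.
* iHS/nSL at a window's central SNP are undefined when either allele has
  fewer than two carriers; such values become 0 rather than being imputed.
* Real-data polarization requires an AA annotation; without one, REF is
  treated as ancestral (with a warning) or `fold=True` switches the
  polarization-dependent statistics to major/minor coding.
* The adversarial game can saturate (discriminator wins, reversed gradient
  vanishes) when domains are grossly separable and capacity is small;
  validation-checkpoint selection and the optional λ warm-up mitigate this.
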