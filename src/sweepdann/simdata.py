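"""Labeled 5-class sweep dataset generation.

Two backends produce :class:`LabeledCase` objects:

* ``fixture`` — a fast parametric generator: exchangeable neutral mutation
  placement at rate θ = 4 Ne μ L, with sweep classes imposed by collapsing
  haplotypes onto one (hard) or several (soft) founder haplotypes over
  recombination-limited tracts whose scale follows the hard-sweep footprint
  approximation s / [4 Ne r ln(Ne s)]. Selected sites for the sweep classes
  fall inside the central 0.475 L – 0.525 L segment, linked classes outside
  it, and neutral cases carry no selected site.
* ``msprime`` — coalescent simulation (neutral background, hard/soft sweeps
  through a genic-selection trajectory) for higher-fidelity runs.

The same module provides the 16-scenario parameter-mismatch grid and the
robustness transforms (missing regions, recombination-rate heterogeneity,
uniformly lowered recombination, class imbalance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .haplotypes import HaplotypeWindow

CLASSES = ("hard", "linked_hard", "soft", "linked_soft", "neutral")
SWEEP_CENTER = (0.475, 0.525)

# Figure-level mismatch grid values; the two intermediate points per axis
# interpolate geometrically between the printed extremes.
DEFAULT_R_GRID = (3.125e-9, 6.25e-9, 2.75e-8, 3.75e-8)
DEFAULT_S_GRID = (0.0075, 0.02, 0.08, 0.2)


@dataclass(frozen=True)
class ScenarioParams:
    """Population-genetic parameters of one simulation scenario."""

    Ne: float = 10_000.0
    r: float = 5e-7  # per-bp per-generation recombination rate
    mu: float = 1.25e-8  # per-bp per-generation mutation rate
    s: float = 0.05  # selection coefficient of the beneficial allele
    initial_freq: float = 0.0  # 0 for de novo hard sweeps, >0 for soft
    L: float = 100_000.0  # fragment length in bp
    n_hap: int = 40  # sampled haplotypes
    demographic_model: str = "constant"

    def __post_init__(self):
        if min(self.Ne, self.r, self.mu, self.s) <= 0:
            raise ValueError("all rates must be positive")
        if not (0 <= self.initial_freq < 1):
            raise ValueError("initial_freq must be in [0, 1)")


@dataclass
class LabeledCase:
    window: HaplotypeWindow
    label: str
    params: ScenarioParams
    selected_pos: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        lo, hi = SWEEP_CENTER
        rel = None if self.selected_pos is None else self.selected_pos / self.params.L
        if self.label == "neutral":
            if self.selected_pos is not None:
                raise ValueError("neutral cases carry no selected site")
        elif self.label in ("hard", "soft"):
            if rel is None or not (lo < rel < hi):
                raise ValueError("sweep classes need a selected site in the central segment")
        else:
            if rel is None or lo < rel < hi:
                raise ValueError("linked classes need a selected site outside the central segment")


@dataclass
class DatasetSplit:
    train: list[LabeledCase]
    validation: list[LabeledCase]
    test: list[LabeledCase]

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for name in ("train", "validation", "test"):
            cases = getattr(self, name)
            out[name] = {c: sum(1 for x in cases if x.label == c) for c in CLASSES}
        return out


def sweep_footprint(s: float, Ne: float, r: float) -> float:
    """Approximate scale of a hard-sweep footprint: s/[4 Ne r ln(Ne s)].

    The value is in coalescent-scaled (per 4 Ne generations) length units;
    multiply by 4 Ne for the physical bp scale used by the generator
    (:func:`footprint_bp`).
    """
    if Ne * s <= 1:
        raise ValueError("Ne*s must exceed 1 for the footprint approximation")
    return s / (4.0 * Ne * r * math.log(Ne * s))


def footprint_bp(params: ScenarioParams) -> float:
    """Physical sweep-tract decay scale s/[r ln(Ne s)] in bp."""
    return 4.0 * params.Ne * sweep_footprint(params.s, params.Ne, params.r)


# ---------------------------------------------------------------------------
# fixture backend


def _neutral_background(params: ScenarioParams, rng: np.random.Generator) -> HaplotypeWindow:
    """Exchangeable-site neutral matrix with 1/i frequency spectrum."""
    n = params.n_hap
    theta = 4.0 * params.Ne * params.mu * params.L
    a_n = np.sum(1.0 / np.arange(1, n))
    # E[S] = theta * a_n under the standard neutral model
    n_sites = max(int(rng.poisson(theta * a_n)), 2)
    positions = np.sort(rng.uniform(0, params.L, size=n_sites))
    # enforce strictly increasing positions
    positions = np.unique(positions)
    n_sites = positions.size
    counts = rng.choice(
        np.arange(1, n), size=n_sites, p=(1.0 / np.arange(1, n)) / a_n
    )
    matrix = np.zeros((n, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        matrix[rng.choice(n, size=c, replace=False), j] = 1
    return HaplotypeWindow(matrix, positions, (0.0, params.L))


def _draw_selected_pos(label: str, L: float, rng: np.random.Generator) -> float | None:
    lo, hi = SWEEP_CENTER
    if label == "neutral":
        return None
    if label in ("hard", "soft"):
        return float(rng.uniform(lo * L, hi * L))
    # linked: outside the central segment, away from the fragment edges
    while True:
        x = rng.uniform(0.05 * L, 0.95 * L)
        if not (lo * L < x < hi * L):
            return float(x)


def _impose_sweep(
    win: HaplotypeWindow,
    params: ScenarioParams,
    label: str,
    selected_pos: float,
    rng: np.random.Generator,
    footprint_scales: tuple[float, float] | None = None,
) -> HaplotypeWindow:
    """Collapse haplotypes onto founder(s) over exponential sweep tracts."""
    n = win.n_hap
    matrix = win.matrix.copy()
    n_founders = 1 if label in ("hard", "linked_hard") else int(rng.integers(2, 4))
    f_end = rng.uniform(0.7, 0.95)
    n_swept = int(round(f_end * n))
    n_swept = min(max(n_swept, n_founders + 1), n - 1)
    swept = rng.choice(n, size=n_swept, replace=False)
    founders = swept[:n_founders]
    fp = footprint_bp(params)
    if footprint_scales is None:
        footprint_scales = (fp, fp)
    assignment = np.repeat(np.arange(n_founders), math.ceil(n_swept / n_founders))[:n_swept]
    founder_rows = [matrix[f].copy() for f in founders]
    if n_founders > 1:
        # distinct origins: each founder lineage differs at a couple of sites
        # close to the selected position, so soft sweeps stay locally soft
        near = np.flatnonzero(np.abs(win.positions - selected_pos) < footprint_scales[0] / 8.0)
        for fidx in range(1, n_founders):
            if near.size:
                tags = rng.choice(near, size=min(2, near.size), replace=False)
                founder_rows[fidx][tags] = 1 - founder_rows[fidx][tags]
    for h, fidx in zip(swept, assignment):
        # every carrier keeps a short unbroken core around the selected site;
        # beyond it the tract length decays exponentially with the footprint scale
        dl = footprint_scales[0] / 8.0 + rng.exponential(footprint_scales[0])
        dr = footprint_scales[1] / 8.0 + rng.exponential(footprint_scales[1])
        sel = (win.positions >= selected_pos - dl) & (win.positions <= selected_pos + dr)
        matrix[h, sel] = founder_rows[fidx][sel]
    # insert the selected site itself, derived on all swept haplotypes
    col = np.zeros((n, 1), dtype=np.int8)
    col[swept] = 1
    j = int(np.searchsorted(win.positions, selected_pos))
    positions = np.insert(win.positions, j, selected_pos)
    matrix = np.hstack([matrix[:, :j], col, matrix[:, j:]])
    out = HaplotypeWindow(matrix, positions, win.span).drop_monomorphic()
    return out


def fixture_sweep_generator(
    params: ScenarioParams,
    label: str,
    seed: int,
    footprint_scales: tuple[float, float] | None = None,
) -> LabeledCase:
    """Parametric desk-scale sweep case generator (see module docstring)."""
    rng = np.random.default_rng(seed)
    win = _neutral_background(params, rng)
    pos = _draw_selected_pos(label, params.L, rng)
    if pos is not None:
        win = _impose_sweep(win, params, label, pos, rng, footprint_scales)
    win.meta.update({"label": label, "seed": seed})
    return LabeledCase(win, label, params, pos, seed)


# ---------------------------------------------------------------------------
# msprime backend


def _msprime_case(params: ScenarioParams, label: str, seed: int) -> LabeledCase:
    import msprime

    rng = np.random.default_rng(seed)
    pos = _draw_selected_pos(label, params.L, rng)
    base = dict(
        samples=params.n_hap,
        ploidy=1,
        population_size=params.Ne,
        sequence_length=params.L,
        recombination_rate=params.r,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    if label == "neutral":
        ts = msprime.sim_ancestry(**base)
    else:
        start = params.initial_freq if params.initial_freq > 0 else 1.0 / (2 * params.Ne)
        sweep = msprime.SweepGenicSelection(
            position=pos,
            start_frequency=start,
            end_frequency=1.0 - 1.0 / (2 * params.Ne),
            s=params.s,
            dt=1e-6,
        )
        ts = msprime.sim_ancestry(model=[sweep, msprime.StandardCoalescent()], **base)
    ts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    matrix = ts.genotype_matrix().T.astype(np.int8)
    positions = np.array([s.position for s in ts.sites()])
    win = HaplotypeWindow(matrix, positions, (0.0, params.L)).drop_monomorphic()
    win.meta.update({"label": label, "seed": seed})
    return LabeledCase(win, label, params, pos, seed)


def simulate_case(
    params: ScenarioParams, label: str, seed: int, backend: str = "fixture"
) -> LabeledCase:
    """Simulate one labeled case with the chosen backend (seeded)."""
    if backend == "fixture":
        return fixture_sweep_generator(params, label, seed)
    if backend == "msprime":
        return _msprime_case(params, label, seed)
    raise ValueError(f"unknown backend {backend!r}")


# ---------------------------------------------------------------------------
# dataset assembly


def generate_cases(
    params: ScenarioParams,
    per_class: int,
    seed: int,
    backend: str = "fixture",
    classes: tuple[str, ...] = CLASSES,
) -> list[LabeledCase]:
    """Generate per_class cases for each sweep class, deterministically seeded."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(per_class * len(classes)) % (2**31 - 1)
    cases = []
    i = 0
    for label in classes:
        for _ in range(per_class):
            cases.append(simulate_case(params, label, int(child_seeds[i]), backend))
            i += 1
    return cases


def make_splits(
    cases: list[LabeledCase],
    per_class: tuple[int, int, int] = (2400, 300, 300),
    seed: int = 0,
) -> DatasetSplit:
    """Disjoint stratified train/validation/test splits."""
    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = per_class
    buckets: dict[str, list[LabeledCase]] = {c: [] for c in CLASSES}
    for case in cases:
        buckets[case.label].append(case)
    train, val, test = [], [], []
    for c, pool in buckets.items():
        need = n_train + n_val + n_test
        if len(pool) < need:
            raise ValueError(f"class {c!r} has {len(pool)} cases, needs {need}")
        order = rng.permutation(len(pool))
        chosen = [pool[i] for i in order[:need]]
        train += chosen[:n_train]
        val += chosen[n_train : n_train + n_val]
        test += chosen[n_train + n_val :]
    return DatasetSplit(train, val, test)


def generate_dataset(
    params: ScenarioParams,
    per_class: tuple[int, int, int] = (2400, 300, 300),
    seed: int = 0,
    backend: str = "fixture",
) -> DatasetSplit:
    total = sum(per_class)
    cases = generate_cases(params, total, seed, backend)
    return make_splits(cases, per_class, seed=seed + 1)


# ---------------------------------------------------------------------------
# mismatch grid and robustness transforms


def mismatch_grid(
    base: ScenarioParams,
    r_values: tuple[float, ...] = DEFAULT_R_GRID,
    s_values: tuple[float, ...] = DEFAULT_S_GRID,
) -> list[ScenarioParams]:
    """Cartesian 4 x 4 grid of target-domain parameters (16 scenarios)."""
    if len(r_values) != 4 or len(s_values) != 4:
        raise ValueError("the mismatch grid takes 4 values per axis")
    return [replace(base, r=r, s=s) for r, s in itertools.product(r_values, s_values)]


def _mask_missing(case: LabeledCase, fraction: float, rng: np.random.Generator) -> LabeledCase:
    """Drop SNPs in contiguous regions totalling ``fraction`` of the fragment bp."""
    L = case.params.L
    total = fraction * L
    n_gaps = int(rng.integers(1, 4))
    widths = rng.dirichlet(np.ones(n_gaps)) * total
    keep = np.ones(case.window.n_sites, dtype=bool)
    masked = []
    for wdt in widths:
        a = rng.uniform(0, L - wdt)
        keep &= ~((case.window.positions >= a) & (case.window.positions < a + wdt))
        masked.append((a, a + wdt))
    win = HaplotypeWindow(
        case.window.matrix[:, keep], case.window.positions[keep], case.window.span
    )
    win.meta.update(case.window.meta)
    win.meta["masked_regions"] = masked
    win.meta["masked_fraction"] = fraction
    return LabeledCase(win, case.label, case.params, case.selected_pos, case.seed)


def _regenerate(case: LabeledCase, params: ScenarioParams, **kw) -> LabeledCase:
    rng = np.random.default_rng(case.seed)
    win = _neutral_background(params, rng)
    pos = _draw_selected_pos(case.label, params.L, rng)
    if pos is not None:
        win = _impose_sweep(win, params, case.label, pos, rng, kw.get("footprint_scales"))
    win.meta.update({"label": case.label, "seed": case.seed})
    return LabeledCase(win, case.label, params, pos, case.seed)


def robustness_transform(
    split: DatasetSplit, kind: str, seed: int = 0, **knobs
) -> DatasetSplit:
    """Apply one robustness scenario to a dataset split.

    kinds
    -----
    missing_regions : drop contiguous SNP runs totalling ``fraction`` (default
        0.20) of each fragment.
    recomb_hetero : regenerate a ``mix`` fraction (default 0.5) of cases with a
        two-segment recombination map (independent log-uniform side multipliers
        on [1/10, 10]).
    low_recomb_factor : regenerate all cases with r divided by ``factor``
        (the standard factors are 5, 10, 50 and 100).
    imbalance : resample class counts to ``weights`` (mapping class -> count).
    """
    rng = np.random.default_rng(seed)

    def transform(cases: list[LabeledCase]) -> list[LabeledCase]:
        if kind == "missing_regions":
            fraction = knobs.get("fraction", 0.20)
            if not (0 <= fraction < 1):
                raise ValueError("missing fraction must be in [0, 1)")
            if fraction == 0:
                return list(cases)
            return [_mask_missing(c, fraction, rng) for c in cases]
        if kind == "low_recomb_factor":
            factor = knobs["factor"]
            if factor <= 0:
                raise ValueError("factor must be positive")
            return [_regenerate(c, replace(c.params, r=c.params.r / factor)) for c in cases]
        if kind == "recomb_hetero":
            mix = knobs.get("mix", 0.5)
            if not (0 <= mix <= 1):
                raise ValueError("mix must be in [0, 1]")
            out = []
            for c in cases:
                if rng.random() < mix:
                    mult = 10.0 ** rng.uniform(-1, 1, size=2)
                    fp = footprint_bp(c.params)
                    out.append(
                        _regenerate(c, c.params, footprint_scales=(fp / mult[0], fp / mult[1]))
                    )
                else:
                    out.append(c)
            return out
        if kind == "imbalance":
            weights: dict[str, int] = knobs["weights"]
            out = []
            for cls, count in weights.items():
                pool = [c for c in cases if c.label == cls]
                if not pool:
                    raise ValueError(f"no cases of class {cls!r}")
                idx = rng.choice(len(pool), size=count, replace=count > len(pool))
                out.extend(pool[i] for i in idx)
            return out
        raise ValueError(f"unknown robustness kind {kind!r}")

    return DatasetSplit(
        transform(split.train), transform(split.validation), transform(split.test)
    )
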