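"""Summary statistics for selective-sweep feature engineering.

Forty statistics are computed per SNP window, organised as a fixed-order
registry with three groups:

* polymorphism / site-frequency-spectrum statistics separating selected from
  neutral windows (ΔAF, π, Watterson's θ, θ_H, Fay–Wu's H, SFS moments and
  entropy, singleton and high-frequency site fractions, θ_L);
* favoured-mutation statistics separating selected from merely linked windows
  (SAFE and its components φ and κ, summarised per window);
* haplotype-structure statistics separating hard from soft sweeps
  (haplotype-spectrum counts and entropies, Garud's H1/H12/H123/H2/H1,
  HAF scores, iHS, nSL and ΔiHH).

All functions operate on a :class:`~sweepdann.haplotypes.HaplotypeWindow`
with derived-allele coding (0 = ancestral, 1 = derived).
"""

from __future__ import annotations

import warnings
from functools import cached_property

import numpy as np

from .haplotypes import HaplotypeWindow

__all__ = [
    "SiteFrequencySpectrum",
    "HapFreqSpectrum",
    "WindowContext",
    "nucleotide_diversity",
    "watterson_theta",
    "theta_h",
    "fay_wu_h",
    "theta_l",
    "site_frequency_spectrum",
    "sfs_moments",
    "hap_spectrum",
    "garud_h_stats",
    "haf_scores",
    "ehh_curve",
    "ehh_family",
    "safe_family",
    "delta_af",
    "standardize_ihs",
    "default_registry",
    "compute_stat_vector",
    "N_STATS",
]

EHH_CUTOFF = 0.05


# ---------------------------------------------------------------------------
# spectra


class SiteFrequencySpectrum:
    """Unfolded SFS: counts of sites at each derived-allele count 1..n-1."""

    def __init__(self, counts: np.ndarray, n_hap: int):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (n_hap - 1,):
            raise ValueError("SFS must have n_hap - 1 classes")
        if (counts < 0).any():
            raise ValueError("SFS counts must be non-negative")
        self.counts = counts
        self.n_hap = n_hap

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


class HapFreqSpectrum:
    """Relative frequencies of distinct haplotypes, sorted descending."""

    def __init__(self, freqs: np.ndarray):
        freqs = np.sort(np.asarray(freqs, dtype=np.float64))[::-1]
        if freqs.size == 0 or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("haplotype frequencies must sum to 1")
        self.freqs = freqs

    @property
    def n_distinct(self) -> int:
        return self.freqs.size


def site_frequency_spectrum(win: HaplotypeWindow) -> SiteFrequencySpectrum:
    counts = win.matrix.sum(axis=0)
    seg = counts[(counts > 0) & (counts < win.n_hap)]
    sfs = np.bincount(seg, minlength=win.n_hap)[1 : win.n_hap]
    return SiteFrequencySpectrum(sfs, win.n_hap)


# ---------------------------------------------------------------------------
# SFS-based scalars


def nucleotide_diversity(win: HaplotypeWindow) -> float:
    """Mean pairwise difference π = Σ_i 2 c_i (n − c_i) / (n(n−1))."""
    n = win.n_hap
    c = win.matrix.sum(axis=0).astype(np.float64)
    return float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))


def watterson_theta(win: HaplotypeWindow) -> float:
    """S / a_n with a_n the (n−1)-th harmonic number."""
    n = win.n_hap
    c = win.matrix.sum(axis=0)
    s = int(np.count_nonzero((c > 0) & (c < n)))
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(s / a_n)


def theta_h(win: HaplotypeWindow) -> float:
    """Fay and Wu's θ_H = Σ_i 2 ξ_i i² / (n(n−1)), weighting high frequencies."""
    n = win.n_hap
    c = win.matrix.sum(axis=0).astype(np.float64)
    c = c[(c > 0) & (c < n)]
    return float(np.sum(2.0 * c * c) / (n * (n - 1)))


def fay_wu_h(win: HaplotypeWindow) -> float:
    """H = π − θ_H; negative values flag an excess of high-frequency derived alleles."""
    return nucleotide_diversity(win) - theta_h(win)


def theta_l(win: HaplotypeWindow) -> float:
    """Zeng's θ_L = Σ_i i ξ_i / (n−1), intermediate SFS weighting."""
    n = win.n_hap
    c = win.matrix.sum(axis=0).astype(np.float64)
    c = c[(c > 0) & (c < n)]
    return float(np.sum(c) / (n - 1))


def sfs_moments(sfs: SiteFrequencySpectrum) -> np.ndarray:
    """1st–5th moments of the per-site derived-allele frequency, plus entropy.

    Moments weight each segregating site equally; the entropy is the Shannon
    entropy (natural log) over occupied SFS classes. An empty spectrum maps
    to six zeros.
    """
    if sfs.n_sites == 0:
        return np.zeros(6)
    i = np.arange(1, sfs.n_hap)
    f = i / sfs.n_hap
    w = sfs.counts / sfs.n_sites
    moments = [float(np.sum(w * f**k)) for k in range(1, 6)]
    occ = w[w > 0]
    entropy = float(-np.sum(occ * np.log(occ)))
    return np.array(moments + [entropy])


# ---------------------------------------------------------------------------
# haplotype spectrum


def hap_spectrum(win: HaplotypeWindow) -> HapFreqSpectrum:
    _, counts = np.unique(win.matrix, axis=0, return_counts=True)
    return HapFreqSpectrum(counts / win.n_hap)


def garud_h_stats(hfs: HapFreqSpectrum) -> tuple[float, float, float, float, float]:
    """(H1, H12, H123, H2/H1, haplotype heterozygosity)."""
    p = hfs.freqs
    h1 = float(np.sum(p**2))
    h12 = float((p[:2].sum()) ** 2 + np.sum(p[2:] ** 2))
    h123 = float((p[:3].sum()) ** 2 + np.sum(p[3:] ** 2))
    h2h1 = float((h1 - p[0] ** 2) / h1)
    return h1, h12, h123, h2h1, 1.0 - h1


def hap_entropy(hfs: HapFreqSpectrum) -> float:
    p = hfs.freqs[hfs.freqs > 0]
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# HAF / SAFE


def haf_scores(win: HaplotypeWindow) -> np.ndarray:
    """Haplotype allele frequency score per haplotype.

    HAF(h) = sum over derived alleles carried by h of the derived count of
    that allele. Sites fixed-derived within the window still contribute
    (they carry frequency information inherited from the parent fragment).
    """
    c = win.matrix.sum(axis=0).astype(np.float64)
    return win.matrix.astype(np.float64) @ c


def safe_family(win: HaplotypeWindow) -> dict[str, np.ndarray]:
    """Per-site φ, κ and SAFE scores.

    φ(v) is the HAF mass carried by v's carriers relative to the whole
    window; κ(v) is the fraction of distinct haplotypes represented among
    carriers. SAFE contrasts the two, standardised by the binomial null
    standard deviation sqrt(f(1−f)) of the carrier frequency f.
    """
    haf = haf_scores(win)
    total_haf = haf.sum()
    _, inverse = np.unique(win.matrix, axis=0, return_inverse=True)
    n_distinct = int(inverse.max()) + 1

    n_sites = win.n_sites
    phi = np.empty(n_sites)
    kappa = np.empty(n_sites)
    carrier_f = win.matrix.mean(axis=0)
    for j in range(n_sites):
        carriers = win.matrix[:, j] == 1
        phi[j] = haf[carriers].sum() / total_haf if total_haf > 0 else 0.0
        kappa[j] = np.unique(inverse[carriers]).size / n_distinct
    denom = np.sqrt(carrier_f * (1.0 - carrier_f))
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(denom > 0, (phi - kappa) / denom, 0.0)
    return {"phi": phi, "kappa": kappa, "safe": safe, "haf": haf}


# ---------------------------------------------------------------------------
# EHH family


def ehh_curve(matrix: np.ndarray, rows: np.ndarray, core: int) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity for ``rows`` extending from ``core``.

    Returns (offsets, ehh) where offsets are signed site-index offsets from
    the core (0 at the core, EHH=1 there) ordered left-to-right, and ehh the
    homozygosity of the sub-haplotypes spanning core..core+offset.
    """
    sub = matrix[rows]
    nc = sub.shape[0]
    if nc < 2:
        raise ValueError("need at least two carrier haplotypes")
    n_sites = matrix.shape[1]

    def one_side(step: int) -> list[float]:
        ids = np.zeros(nc, dtype=np.int64)
        out = []
        j = core + step
        while 0 <= j < n_sites:
            ids = ids * 2 + sub[:, j]
            _, ids, counts = np.unique(ids, return_inverse=True, return_counts=True)
            ehh = float(np.sum(counts * (counts - 1)) / (nc * (nc - 1)))
            out.append(ehh)
            j += step
        return out

    left = one_side(-1)
    right = one_side(+1)
    offsets = np.concatenate(
        [-np.arange(len(left), 0, -1), [0], np.arange(1, len(right) + 1)]
    )
    vals = np.array(left[::-1] + [1.0] + right)
    return offsets, vals


def _ihh(offsets, vals, positions, core, cutoff=EHH_CUTOFF, scale="bp"):
    """Integrate an EHH curve outward from the core by the trapezoid rule.

    Integration proceeds site to site and stops after the first point whose
    EHH falls below ``cutoff``; if the curve never decays it is truncated at
    the window edge (fixed-size windows, no discard convention).
    """
    mid = int(np.where(offsets == 0)[0][0])
    total = 0.0
    for direction in (-1, 1):
        prev_v = 1.0
        prev_x = positions[core] if scale == "bp" else 0.0
        i = mid + direction
        while 0 <= i < len(offsets):
            v = vals[i]
            x = positions[core + offsets[i]] if scale == "bp" else float(abs(offsets[i]))
            total += 0.5 * (prev_v + v) * abs(x - prev_x)
            if v < cutoff:
                break
            prev_v, prev_x = v, x
            i += direction
    return total


def ehh_family(win: HaplotypeWindow, core_index: int) -> tuple[float, float, float]:
    """(unstandardised iHS, unstandardised nSL, ΔiHH) at a core SNP.

    iHH integrates EHH decay on the bp scale for ancestral and derived
    carrier sets separately; iHS = ln(iHH_A / iHH_D), nSL is the analogue on
    the SNP-count scale and ΔiHH = iHH_A − iHH_D. Returns NaNs when either
    allele has fewer than two carriers or an integral vanishes.
    """
    col = win.matrix[:, core_index]
    derived = np.flatnonzero(col == 1)
    ancestral = np.flatnonzero(col == 0)
    if derived.size < 2 or ancestral.size < 2:
        return (np.nan, np.nan, np.nan)
    out = {}
    for name, rows in (("A", ancestral), ("D", derived)):
        offsets, vals = ehh_curve(win.matrix, rows, core_index)
        out[name + "_bp"] = _ihh(offsets, vals, win.positions, core_index, scale="bp")
        out[name + "_snp"] = _ihh(offsets, vals, win.positions, core_index, scale="snp")
    with np.errstate(divide="ignore", invalid="ignore"):
        ihs = np.log(out["A_bp"] / out["D_bp"]) if out["D_bp"] > 0 and out["A_bp"] > 0 else np.nan
        nsl = (
            np.log(out["A_snp"] / out["D_snp"])
            if out["D_snp"] > 0 and out["A_snp"] > 0
            else np.nan
        )
    dihh = out["A_bp"] - out["D_bp"]
    return (float(ihs), float(nsl), float(dihh))


def standardize_ihs(values: np.ndarray, freqs: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Within-run z-score of unstandardised iHS in derived-frequency bins."""
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = np.full_like(values, np.nan)
    edges = np.linspace(0, 1, n_bins + 1)
    bins = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = (bins == b) & np.isfinite(values)
        if sel.sum() >= 2:
            mu, sd = values[sel].mean(), values[sel].std()
            if sd > 0:
                out[sel] = (values[sel] - mu) / sd
            else:
                out[sel] = 0.0
    return out


# ---------------------------------------------------------------------------
# ΔAF


def delta_af(win: HaplotypeWindow, baseline: float) -> float:
    """Deviation of the window mean derived-allele frequency from a run baseline."""
    return float(win.matrix.mean(axis=0).mean() - baseline)


# ---------------------------------------------------------------------------
# registry


class WindowContext:
    """Lazy cache of shared intermediates for one window's statistics."""

    def __init__(self, win: HaplotypeWindow, baseline_af: float = 0.0, core: int | None = None):
        self.win = win
        self.baseline_af = baseline_af
        self.core = win.n_sites // 2 if core is None else core

    @cached_property
    def sfs(self) -> SiteFrequencySpectrum:
        return site_frequency_spectrum(self.win)

    @cached_property
    def sfs_mom(self) -> np.ndarray:
        return sfs_moments(self.sfs)

    @cached_property
    def hfs(self) -> HapFreqSpectrum:
        return hap_spectrum(self.win)

    @cached_property
    def garud(self) -> tuple[float, float, float, float, float]:
        return garud_h_stats(self.hfs)

    @cached_property
    def safe(self) -> dict[str, np.ndarray]:
        return safe_family(self.win)

    @cached_property
    def ehh(self) -> tuple[float, float, float]:
        return ehh_family(self.win, self.core)

    @cached_property
    def daf(self) -> np.ndarray:
        return self.win.matrix.mean(axis=0)


def _seg_fraction(ctx, lo, hi):
    f = ctx.daf
    seg = (f > 0) & (f < 1)
    if not seg.any():
        return 0.0
    fs = f[seg]
    return float(np.mean((fs > lo) & (fs <= hi)))


def default_registry() -> dict:
    """The default fixed-order roster of 40 statistics.

    The roster is reconstructed from the named statistics plus window
    summaries (mean / max / value at the central SNP) of per-site scores
    and standard haplotype-spectrum summaries; users can supply their own
    ordered mapping to :func:`compute_stat_vector` to change it.
    """
    reg = {
        "delta_af": lambda c: delta_af(c.win, c.baseline_af),
        "pi": lambda c: nucleotide_diversity(c.win),
        "theta_w": lambda c: watterson_theta(c.win),
        "theta_h": lambda c: theta_h(c.win),
        "fay_wu_h": lambda c: fay_wu_h(c.win),
        "sfs_m1": lambda c: c.sfs_mom[0],
        "sfs_m2": lambda c: c.sfs_mom[1],
        "sfs_m3": lambda c: c.sfs_mom[2],
        "sfs_m4": lambda c: c.sfs_mom[3],
        "sfs_m5": lambda c: c.sfs_mom[4],
        "sfs_entropy": lambda c: c.sfs_mom[5],
        "n_hap_types": lambda c: float(c.hfs.n_distinct),
        "hap_heterozygosity": lambda c: c.garud[4],
        "hap_entropy": lambda c: hap_entropy(c.hfs),
        "p1": lambda c: float(c.hfs.freqs[0]),
        "p2": lambda c: float(c.hfs.freqs[1]) if c.hfs.n_distinct > 1 else 0.0,
        "h1": lambda c: c.garud[0],
        "h12": lambda c: c.garud[1],
        "h123": lambda c: c.garud[2],
        "h2_h1": lambda c: c.garud[3],
        "haf_mean": lambda c: float(c.safe["haf"].mean()),
        "haf_max": lambda c: float(c.safe["haf"].max()),
        "haf_std": lambda c: float(c.safe["haf"].std()),
        "phi_mean": lambda c: float(c.safe["phi"].mean()),
        "phi_max": lambda c: float(c.safe["phi"].max()),
        "phi_core": lambda c: float(c.safe["phi"][c.core]),
        "kappa_mean": lambda c: float(c.safe["kappa"].mean()),
        "kappa_max": lambda c: float(c.safe["kappa"].max()),
        "kappa_core": lambda c: float(c.safe["kappa"][c.core]),
        "safe_mean": lambda c: float(c.safe["safe"].mean()),
        "safe_max": lambda c: float(c.safe["safe"].max()),
        "safe_core": lambda c: float(c.safe["safe"][c.core]),
        "ihs_unstd": lambda c: c.ehh[0],
        "nsl_unstd": lambda c: c.ehh[1],
        "delta_ihh": lambda c: c.ehh[2],
        "singleton_prop": lambda c: _seg_fraction(c, 0.0, 1.0 / c.win.n_hap),
        "high_freq_prop": lambda c: _seg_fraction(c, 0.8, 1.0),
        "theta_l": lambda c: theta_l(c.win),
        "pi_minus_theta_w": lambda c: nucleotide_diversity(c.win) - watterson_theta(c.win),
        "distinct_hap_ratio": lambda c: c.hfs.n_distinct / c.win.n_hap,
    }
    assert len(reg) == 40
    return reg


N_STATS = 40


def compute_stat_vector(
    win: HaplotypeWindow,
    registry: dict | None = None,
    baseline_af: float = 0.0,
    core: int | None = None,
) -> np.ndarray:
    """Evaluate the registry on one window, in fixed order.

    Degenerate windows (no segregating site) yield a zero vector with a
    warning; NaNs from undefined statistics (e.g. iHS with a monoallelic
    core) become 0, while infinities are left for run-level clamping during
    standardisation.
    """
    registry = default_registry() if registry is None else registry
    counts = win.matrix.sum(axis=0)
    if not np.any((counts > 0) & (counts < win.n_hap)):
        warnings.warn("window with no segregating sites: zero-filled statistics")
        return np.zeros(len(registry))
    ctx = WindowContext(win, baseline_af=baseline_af, core=core)
    vals = np.array([float(fn(ctx)) for fn in registry.values()])
    return np.where(np.isnan(vals), 0.0, vals)
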