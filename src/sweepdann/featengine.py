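"""Feature engineering: haplotype fragment -> standardized 40 x m feature matrix.

The pipeline has three steps: (i) uniformly select n central SNPs and form
2k+1-SNP windows around each; (ii) compute the 40-statistic vector per
window, giving a 40 x n grid; (iii) positionally encode the grid into m
equal physical intervals of the fragment (empty intervals zero-filled),
then max-min standardize per statistic row across the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeWindow
from . import sumstats

logger = logging.getLogger(__name__)


class ExcludedFragment(Exception):
    """Raised when a fragment has fewer than 2k + n SNPs."""


@dataclass(frozen=True)
class FragmentSpec:
    """Windowing parameters for feature construction.

    Defaults follow the method's standard configuration: n=200 feature
    windows of 2k+1 = 51 SNPs, m=200 positional intervals, and a 1 Mb
    genome window advanced in 50 kb steps.
    """

    n: int = 200
    k: int = 25
    m: int = 200
    w: int = 1_000_000
    s: int = 50_000

    def __post_init__(self):
        if min(self.n, self.k, self.m) < 1:
            raise ValueError("n, k, m must all be >= 1")
        if self.w < self.s:
            raise ValueError("genome window w must be >= step s")

    @property
    def min_sites(self) -> int:
        return 2 * self.k + self.n


@dataclass
class FeatureMatrix:
    """Positionally encoded statistic grid for one fragment."""

    grid: np.ndarray  # (40, m)
    interval_edges: np.ndarray  # (m + 1,)
    window_positions: np.ndarray  # (n,)
    meta: dict = field(default_factory=dict)


@dataclass
class StandardizedDataset:
    """A stack of feature grids plus the min-max scale fitted on them.

    ``X`` has shape (cases, n_stats, m). ``scale`` is (min, max) per
    statistic row, fitted on a source/training dataset and reusable on any
    other dataset in apply mode.
    """

    X: np.ndarray
    stat_names: list[str]
    domain_tag: str = "source"
    labels: np.ndarray | None = None
    scale: tuple[np.ndarray, np.ndarray] | None = None
    meta: list[dict] = field(default_factory=list)


def select_central_snps(total_sites: int, spec: FragmentSpec) -> np.ndarray:
    """Evenly spaced central-SNP indices with k flanking sites on each side.

    Uses round(k + t*(total-2k-1)/(n-1)) over the eligible index range
    [k, total-k-1]; fragments with fewer than 2k+n sites are excluded.
    """
    if total_sites < spec.min_sites:
        raise ExcludedFragment(
            f"fragment has {total_sites} SNPs < 2k+n = {spec.min_sites}"
        )
    lo, hi = spec.k, total_sites - spec.k - 1
    if spec.n == 1:
        return np.array([(lo + hi) // 2])
    t = np.arange(spec.n)
    idx = np.round(lo + t * (hi - lo) / (spec.n - 1)).astype(int)
    return idx


def build_raw_matrix(
    fragment: HaplotypeWindow,
    spec: FragmentSpec,
    registry: dict | None = None,
    baseline_af: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the 40 x n raw statistic grid and per-window mean positions."""
    registry = sumstats.default_registry() if registry is None else registry
    centers = select_central_snps(fragment.n_sites, spec)
    raw = np.empty((len(registry), spec.n))
    positions = np.empty(spec.n)
    for j, c in enumerate(centers):
        win = fragment.site_window(c - spec.k, c + spec.k)
        raw[:, j] = sumstats.compute_stat_vector(
            win, registry, baseline_af=baseline_af, core=spec.k
        )
        positions[j] = win.positions.mean()
    return raw, positions


def positional_encode(
    raw: np.ndarray,
    positions: np.ndarray,
    spec: FragmentSpec,
    length: float,
    origin: float = 0.0,
) -> FeatureMatrix:
    """Bin window columns into m equal physical intervals of [0, L].

    Interval j covers (L*(j-1)/m, L*j/m]; a window at position exactly 0
    goes to the first interval. Cells are window means; empty intervals are
    zero-filled to signal absence of variation.
    """
    rel = np.asarray(positions, dtype=float) - origin
    if rel.min() < 0 or rel.max() > length:
        raise ValueError("window positions fall outside [0, L]")
    m = spec.m
    bins = np.clip(np.ceil(rel * m / length).astype(int), 1, m) - 1
    grid = np.zeros((raw.shape[0], m))
    counts = np.bincount(bins, minlength=m)
    for i in range(raw.shape[0]):
        sums = np.bincount(bins, weights=raw[i], minlength=m)
        np.divide(sums, counts, out=grid[i], where=counts > 0)
    edges = origin + np.linspace(0.0, length, m + 1)
    return FeatureMatrix(grid, edges, np.asarray(positions, float))


def featurize_fragment(
    fragment: HaplotypeWindow,
    spec: FragmentSpec,
    registry: dict | None = None,
    baseline_af: float = 0.0,
) -> FeatureMatrix:
    """Raw grid + positional encoding in one call (steps i-iii, unscaled)."""
    raw, pos = build_raw_matrix(fragment, spec, registry, baseline_af)
    fm = positional_encode(raw, pos, spec, fragment.length, origin=fragment.span[0])
    fm.meta = dict(fragment.meta)
    fm.meta.update({"span": fragment.span})
    return fm


def _clamp_non_finite(X: np.ndarray) -> np.ndarray:
    """Clamp infinities per statistic row to the finite min/max of the run."""
    X = X.copy()
    for i in range(X.shape[1]):
        row = X[:, i, :]
        bad = ~np.isfinite(row)
        if bad.any():
            finite = row[np.isfinite(row)]
            lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 0.0)
            row[np.isposinf(row)] = hi
            row[np.isneginf(row)] = lo
            row[np.isnan(row)] = lo
            X[:, i, :] = row
    return X


def minmax_standardize(
    dataset: StandardizedDataset,
    mode: str = "fit",
    scale: tuple[np.ndarray, np.ndarray] | None = None,
) -> StandardizedDataset:
    """Max-min standardize each statistic row across the dataset.

    ``fit`` computes per-row min/max over all cases and positions and stores
    them; ``apply`` reuses a previously fitted scale (values are clipped to
    [0, 1] so shifted data cannot leave the training range). Constant rows
    map to zero.
    """
    X = _clamp_non_finite(dataset.X)
    if mode == "fit":
        if X.shape[0] < 2:
            raise ValueError("fit mode requires at least 2 matrices")
        lo = X.min(axis=(0, 2))
        hi = X.max(axis=(0, 2))
    elif mode == "apply":
        scale = scale if scale is not None else dataset.scale
        if scale is None:
            raise ValueError("apply mode requires a fitted scale")
        lo, hi = scale
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = hi - lo
    safe_rng = np.where(rng > 0, rng, 1.0)
    Xs = (X - lo[None, :, None]) / safe_rng[None, :, None]
    Xs[:, rng == 0, :] = 0.0
    Xs = np.clip(Xs, 0.0, 1.0)
    return StandardizedDataset(
        Xs,
        dataset.stat_names,
        dataset.domain_tag,
        dataset.labels,
        (np.asarray(lo, float), np.asarray(hi, float)),
        dataset.meta,
    )


def genome_to_fragments(chrom: HaplotypeWindow, spec: FragmentSpec):
    """Yield half-open sliding fragments [a, a + w) advanced by s.

    A chromosome shorter than w yields a single fragment covering it.
    Fragments failing the 2k+n SNP rule are skipped and logged.
    """
    start0, end0 = chrom.span
    clen = end0 - start0
    if clen <= 0 or chrom.n_sites == 0:
        return
    if clen <= spec.w:
        starts = [start0]
        width = clen
    else:
        n_frag = int((clen - spec.w) // spec.s) + 1
        starts = [start0 + i * spec.s for i in range(n_frag)]
        width = spec.w
    for a in starts:
        b = a + width
        sel = (chrom.positions >= a) & (chrom.positions < b)
        n_snp = int(sel.sum())
        if n_snp < spec.min_sites:
            logger.info("fragment [%d, %d) skipped: %d SNPs < %d", a, b, n_snp, spec.min_sites)
            continue
        frag = HaplotypeWindow(
            chrom.matrix[:, sel], chrom.positions[sel], (a, b), dict(chrom.meta)
        )
        yield frag


def featurize_cases(
    windows: list[HaplotypeWindow],
    spec: FragmentSpec,
    registry: dict | None = None,
    domain_tag: str = "source",
    labels: np.ndarray | None = None,
) -> StandardizedDataset:
    """Featurize a list of fragments into an (unscaled) dataset stack.

    The ΔAF baseline is the run-level mean derived-allele frequency over
    all fragments.
    """
    registry = sumstats.default_registry() if registry is None else registry
    baseline = float(np.mean([w.matrix.mean() for w in windows])) if windows else 0.0
    grids, meta = [], []
    for w in windows:
        fm = featurize_fragment(w, spec, registry, baseline_af=baseline)
        grids.append(fm.grid)
        meta.append(fm.meta)
    X = np.stack(grids) if grids else np.empty((0, len(registry), spec.m))
    return StandardizedDataset(X, list(registry), domain_tag, labels, None, meta)
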