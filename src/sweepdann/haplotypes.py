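"""Core haplotype container shared by all statistic and feature modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypeWindow:
    """A phased 0/1 haplotype matrix with physical site positions.

    Parameters
    ----------
    matrix : ndarray of shape (n_hap, n_sites)
        Binary grid; 0 = ancestral allele, 1 = derived allele.
    positions : ndarray of shape (n_sites,)
        Physical coordinate of each site in bp, strictly increasing.
    span : tuple of (start_bp, end_bp)
        Coordinates of the parent fragment (0-based, half-open).
    """

    matrix: np.ndarray
    positions: np.ndarray
    span: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.int8))
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match number of sites")
        if self.matrix.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        vals = np.unique(self.matrix)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("matrix entries must be 0/1")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.span == (0.0, 0.0) and self.positions.size:
            self.span = (0.0, float(self.positions[-1]) + 1.0)

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def length(self) -> float:
        return float(self.span[1] - self.span[0])

    def drop_monomorphic(self) -> "HaplotypeWindow":
        """Return a copy with monomorphic columns removed (parse-time filter)."""
        counts = self.matrix.sum(axis=0)
        keep = (counts > 0) & (counts < self.n_hap)
        if keep.all():
            return self
        return HaplotypeWindow(
            self.matrix[:, keep], self.positions[keep], self.span, dict(self.meta)
        )

    def site_window(self, lo: int, hi: int) -> "HaplotypeWindow":
        """Sub-window over site index range [lo, hi] inclusive."""
        return HaplotypeWindow(
            self.matrix[:, lo : hi + 1],
            self.positions[lo : hi + 1],
            self.span,
            dict(self.meta),
        )
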