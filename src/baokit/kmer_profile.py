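"""Genome profiling from a k-mer depth histogram.

Estimates haploid genome size, the unique/repeat partition, and
heterozygosity from a two-column k-mer depth histogram (jellyfish ``.histo``
style). The model is a deliberately simple peak-based one, not a full
mixture fit: the error cutoff is the first local minimum of the smoothed
counts, the homozygous peak is the dominant mode above it (with the
heterozygous peak, if present, near half its depth), genome size is the
above-cutoff k-mer mass divided by the homozygous peak depth, k-mers beyond
1.5x the homozygous depth contribute their excess copies to the repeat
partition, and per-base heterozygosity h is recovered from the
haplotype-specific fraction f of distinct k-mers via ``h = 1 - (1-f)^(1/k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._util import moving_average3
from .io import warn


class InsufficientCoverageError(ValueError):
    """Raised when the spectrum has no usable mode above the error cutoff."""


@dataclass
class KmerSpectrum:
    """A depth -> distinct-k-mer-count histogram for k-mers of length k."""

    k: int
    depths: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.depths.size != self.counts.size:
            raise ValueError("depths and counts must have equal length")
        if self.depths.size == 0:
            raise ValueError("empty spectrum")
        if np.any(self.depths < 1) or np.any(self.counts < 0):
            raise ValueError("depths must be >= 1 and counts >= 0")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.mass <= 0:
            raise ValueError("total k-mer mass must be positive")

    @property
    def mass(self) -> int:
        """Total k-mer mass, sum of depth x count."""
        return int(np.sum(self.depths * self.counts))

    def dense_counts(self) -> np.ndarray:
        """Counts on a dense depth grid; index d holds c(d), index 0 unused."""
        dense = np.zeros(int(self.depths[-1]) + 1, dtype=np.int64)
        dense[self.depths] = self.counts
        return dense


@dataclass
class GenomeProfile:
    """Genome-size / repeat / heterozygosity estimates from one spectrum."""

    genome_size_bp: int
    unique_bp: int
    repeat_bp: int
    repeat_fraction: float
    heterozygosity_fraction: float
    het_peak_depth: int | None
    hom_peak_depth: int
    error_depth_cutoff: int
    k: int = field(default=0)

    def to_table(self) -> pd.DataFrame:
        """One-row summary with the conventional report columns."""
        return pd.DataFrame(
            [
                {
                    "Genome size (bp)": self.genome_size_bp,
                    "Unique genome (bp)": self.unique_bp,
                    "Repeat genome (bp)": self.repeat_bp,
                    "Repeat fraction (%)": round(100 * self.repeat_fraction, 1),
                    "Heterozygosity (%)": round(100 * self.heterozygosity_fraction, 2),
                }
            ]
        )

    def to_dict(self) -> dict:
        return {
            "genome_size_bp": self.genome_size_bp,
            "unique_bp": self.unique_bp,
            "repeat_bp": self.repeat_bp,
            "repeat_fraction": self.repeat_fraction,
            "heterozygosity_fraction": self.heterozygosity_fraction,
            "het_peak_depth": self.het_peak_depth,
            "hom_peak_depth": self.hom_peak_depth,
            "error_depth_cutoff": self.error_depth_cutoff,
            "k": self.k,
        }


def parse_histo(path, k: int | None = None) -> KmerSpectrum:
    """Parse a whitespace-separated two-column depth histogram.

    ``k`` may be supplied directly or through a ``#k=NN`` header comment.
    Out-of-order rows are re-sorted with a warning; duplicate depths and
    non-integer fields are errors naming the offending line.
    """
    depths, counts = [], []
    header_k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].replace(" ", "").startswith("k="):
                    header_k = int(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            try:
                d, c = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            depths.append(d)
            counts.append(c)
    if not depths:
        raise ValueError(f"{path}: empty histogram")
    depths = np.array(depths)
    counts = np.array(counts)
    if len(np.unique(depths)) != len(depths):
        dup = depths[pd.Series(depths).duplicated()][0]
        lineno = int(np.flatnonzero(depths == dup)[-1]) + 1
        raise ValueError(f"{path}: line {lineno}: duplicate depth {dup}")
    if np.any(np.diff(depths) < 0):
        warn(f"{path}: depths out of order; re-sorting")
        order = np.argsort(depths)
        depths, counts = depths[order], counts[order]
    k_final = k if k is not None else header_k
    if k_final is None:
        raise ValueError("k must be supplied directly or via a '#k=' header")
    return KmerSpectrum(k=k_final, depths=depths, counts=counts)


def _error_cutoff(smoothed: np.ndarray) -> int:
    """First local minimum of the smoothed counts, scanning from depth 1.

    ``smoothed`` is indexed by depth (index 0 unused).
    """
    d = 1
    dmax = smoothed.size - 1
    if d + 1 <= dmax and smoothed[d + 1] > smoothed[d]:
        return 0  # counts rise from the start: no error tail
    while d + 1 <= dmax and smoothed[d + 1] <= smoothed[d]:
        d += 1
    return d  # d == dmax means the spectrum never rises: no usable mode


def fit_spectrum(spectrum: KmerSpectrum, ploidy_hint: int = 2) -> GenomeProfile:
    """Fit the peak-based genome profile to a spectrum.

    ``ploidy_hint`` only relabels peaks (it is recorded; the homozygous peak
    is taken as the dominant mode either way) and defaults to 2.
    """
    dense = spectrum.dense_counts().astype(float)
    smoothed = np.concatenate([[0.0], moving_average3(dense[1:])])
    cutoff = _error_cutoff(smoothed)
    region = smoothed[cutoff + 1 :]
    if region.size == 0 or region.max() <= 0:
        raise InsufficientCoverageError("insufficient coverage: no mode above the error cutoff")
    padded = np.concatenate([[-1.0], region, [-1.0]])
    peaks, props = find_peaks(padded, height=0)
    peaks = peaks - 1 + cutoff + 1  # back to depth coordinates
    heights = props["peak_heights"]
    if peaks.size == 0:
        raise InsufficientCoverageError("insufficient coverage: no mode above the error cutoff")
    dominant = int(peaks[np.argmax(heights)])
    hom_peak = dominant
    # if a substantial peak sits near twice the dominant depth, the dominant
    # mode is the heterozygous peak and the doubled one is homozygous
    for p, h in zip(peaks, heights):
        if abs(p - 2 * dominant) <= 0.25 * 2 * dominant and h >= 0.2 * heights.max():
            hom_peak = int(p)
            break
    het_lo, het_hi = cutoff, int(np.floor(0.75 * hom_peak))
    het_candidates = [(int(p), h) for p, h in zip(peaks, heights) if het_lo < p <= het_hi]
    het_peak = max(het_candidates, key=lambda t: t[1])[0] if het_candidates else None

    depth_grid = np.arange(dense.size)
    above = depth_grid > cutoff
    mass_above = float(np.sum(depth_grid[above] * dense[above]))
    genome_size = mass_above / hom_peak
    repeat_sel = depth_grid > 1.5 * hom_peak
    repeat_bp = float(np.sum((depth_grid[repeat_sel] - hom_peak) * dense[repeat_sel])) / hom_peak
    het_sel = above & (depth_grid <= het_hi)
    hom_sel = (depth_grid > het_hi) & (depth_grid <= 1.5 * hom_peak)
    n_het = float(dense[het_sel].sum())
    n_hom = float(dense[hom_sel].sum())
    if n_het > 0 and (0.5 * n_het + n_hom) > 0:
        f = 0.5 * n_het / (0.5 * n_het + n_hom)
        het = 1.0 - (1.0 - f) ** (1.0 / spectrum.k)
    else:
        het = 0.0
    return GenomeProfile(
        genome_size_bp=int(round(genome_size)),
        unique_bp=int(round(genome_size - repeat_bp)),
        repeat_bp=int(round(repeat_bp)),
        repeat_fraction=repeat_bp / genome_size if genome_size else 0.0,
        heterozygosity_fraction=het,
        het_peak_depth=het_peak,
        hom_peak_depth=hom_peak,
        error_depth_cutoff=cutoff,
        k=spectrum.k,
    )
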