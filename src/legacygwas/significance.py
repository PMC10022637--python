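"""SimpleM effective test count, genome-wide thresholds, and peak calling.

Markers in linkage disequilibrium do not contribute independent tests, so a
plain Bonferroni correction over the raw marker count is too strict.
SimpleM instead counts, per window of the marker correlation matrix, the
number of leading eigenvalues needed to capture a fixed fraction of its
total variance; the sum over windows and chromosomes is the effective
number of tests M_eff.  Genome-wide significance cutoffs are then
-log10(alpha / M_eff) for alpha = 0.1 (stringent) and 0.2 (lenient).

Peaks are called deterministically: significant markers on a chromosome
within ``merge_gap`` bp of each other form one region, padded on both
sides, so the regions the identity test consumes are reproducible instead
of hand-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypePanel
from .mixed_model_scan import ScanResult


@dataclass
class MeffResult:
    per_chromosome: dict[str, int]
    M_eff: int
    window_size: int
    variance_fraction: float

    def __post_init__(self) -> None:
        if self.M_eff != sum(self.per_chromosome.values()):
            raise ValueError("M_eff must equal the per-chromosome sum")
        if self.M_eff < 1:
            raise ValueError("M_eff must be >= 1")


@dataclass
class ThresholdSet:
    """-log10 p cutoffs at alpha / M_eff for each significance level."""

    m_eff: int
    alpha_levels: tuple[float, ...] = (0.1, 0.2)
    thresholds: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.alpha_levels:
            if not 0.0 < a < 1.0:
                raise ValueError("alpha must lie strictly in (0, 1)")
        if not self.thresholds:
            self.thresholds = {a: float(-np.log10(a / self.m_eff))
                               for a in self.alpha_levels}

    def cutoff(self, alpha: float) -> float:
        return self.thresholds[alpha]


@dataclass
class PeakRegion:
    """Half-open genomic interval [start, end) around a scan maximum."""

    chrom: str
    start: int
    end: int
    top_marker: str
    top_minus_log10_p: float
    n_significant: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


# ---------------------------------------------------------------------------

def _window_effective_count(block: np.ndarray, variance_fraction: float) -> int:
    """Smallest k with top-k eigenvalue sum >= fraction of the total.

    ``block`` is the dosage submatrix (n x w).  Monomorphic columns carry
    no correlation information; each counts as one test on its own.
    """
    w = block.shape[1]
    if w < 2:
        return w
    sd = block.std(axis=0)
    poly = sd > 0
    n_const = int((~poly).sum())
    sub = block[:, poly]
    if sub.shape[1] < 2:
        return sub.shape[1] + n_const
    C = np.corrcoef(sub, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(C))[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    csum = np.cumsum(evals)
    k = int(np.searchsorted(csum, variance_fraction * total - 1e-12) + 1)
    return min(k, sub.shape[1]) + n_const


def simple_m(panel: GenotypePanel, window_size: int = 200,
             variance_fraction: float = 0.995) -> MeffResult:
    """Effective number of independent tests by windowed eigenanalysis.

    Per chromosome, markers are processed in consecutive non-overlapping
    windows of at most ``window_size``; each window contributes the number
    of leading eigenvalues of its marker correlation matrix needed to reach
    ``variance_fraction`` of the total.  Chromosome counts sum to M_eff.
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("impute the panel before SimpleM")
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    per_chrom: dict[str, int] = {}
    for chrom, idx in panel.markers.groupby("chrom", sort=False).groups.items():
        cols = np.asarray(idx, dtype=int)
        count = 0
        for start in range(0, len(cols), window_size):
            block = panel.dosages[:, cols[start:start + window_size]]
            count += _window_effective_count(block, variance_fraction)
        per_chrom[str(chrom)] = count
    return MeffResult(per_chromosome=per_chrom, M_eff=sum(per_chrom.values()),
                      window_size=window_size, variance_fraction=variance_fraction)


def thresholds(meff: MeffResult | int,
               alpha_levels: tuple[float, ...] = (0.1, 0.2)) -> ThresholdSet:
    """Genome-wide -log10 p cutoffs at alpha / M_eff."""
    m = meff if isinstance(meff, int) else meff.M_eff
    if m < 1:
        raise ValueError("M_eff must be >= 1")
    return ThresholdSet(m_eff=m, alpha_levels=tuple(alpha_levels))


def call_peaks(scan: ScanResult, cutoff: float, merge_gap: int = 300_000,
               pad: int = 100_000) -> list[PeakRegion]:
    """Cluster significant markers into padded peak regions.

    Consecutive significant markers on one chromosome at most ``merge_gap``
    bp apart join the same region; region bounds are [min - pad, max + pad)
    clipped at 0.  Returns regions sorted by (chrom, start); an empty list
    when nothing passes the cutoff.
    """
    t = scan.tested()
    sig = t[t["minus_log10_p"] >= cutoff]
    regions: list[PeakRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            chunk = grp.iloc[s:e + 1]
            top = chunk.loc[chunk["minus_log10_p"].idxmax()]
            regions.append(PeakRegion(
                chrom=str(chrom),
                start=max(int(chunk["pos"].min()) - pad, 0),
                end=int(chunk["pos"].max()) + (pad if pad > 0 else 1),
                top_marker=str(top["id"]),
                top_minus_log10_p=float(top["minus_log10_p"]),
                n_significant=len(chunk),
            ))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def peaks_to_bed(regions: list[PeakRegion]) -> pd.DataFrame:
    """BED-style table (0-based half-open) for peak regions."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [max(r.start - 1, 0) for r in regions],
        "end": [r.end - 1 for r in regions],
        "name": [r.top_marker for r in regions],
        "score": [int(round(10 * r.top_minus_log10_p)) for r in regions],
    })
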