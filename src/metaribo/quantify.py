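"""Strand-enforced feature counting, RPKM, and signal-comparison statistics.

A read is assigned to a feature when its footprint 5' end lies inside the
feature span; transcriptomic and ribosome-profiling assays additionally
require the read strand to match the feature strand, while metagenomic
coverage is unstranded.  A 5' end inside two same-strand overlapping
features counts once for each (multi-coverage semantics).

RPKM is count / ((length/1000) * (library_size/1e6)) with library size
defined as the number of retained unique-perfect alignments in the sample.
The translation-evidence call is strict: RPKM > threshold (default 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .mapping import AlignmentRecord
from .orfs import OrfRecord

ASSAYS = ("metagenomic", "rna", "ribo")
STRANDED_ASSAYS = ("rna", "ribo")


class FeatureIndex:
    """Interval lookup from (contig, strand-aware position) to ORF ids."""

    def __init__(self, orfs: Sequence[OrfRecord]) -> None:
        self.orfs = {o.orf_id: o for o in orfs}
        self._trees: dict[str, IntervalTree] = {}
        for o in orfs:
            tree = self._trees.setdefault(o.contig_id, IntervalTree())
            tree.addi(o.start, o.end + 1, o)  # half-open on 1-based coords

    def hits(
        self, contig_id: str, pos: int, strand: Optional[str] = None
    ) -> list[OrfRecord]:
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        out = [iv.data for iv in tree.at(pos)]
        if strand is not None:
            out = [o for o in out if o.strand == strand]
        return sorted(out, key=lambda o: (o.start, o.end, o.strand))


def count_features(
    alignments: Iterable[AlignmentRecord],
    orfs: Sequence[OrfRecord],
    assay: str,
) -> tuple[pd.Series, int]:
    """Count alignments per feature; returns (counts, library_size)."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    index = FeatureIndex(orfs)
    counts = {o.orf_id: 0 for o in orfs}
    library_size = 0
    for a in alignments:
        library_size += 1
        strand = a.strand if assay in STRANDED_ASSAYS else None
        for orf in index.hits(a.contig_id, a.five_prime(), strand):
            counts[orf.orf_id] += 1
    return pd.Series(counts, name=assay, dtype=np.int64), library_size


def rpkm(
    counts: pd.Series, lengths: pd.Series, library_size: int
) -> pd.Series:
    """Reads per kilobase of feature per million library reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    return counts / ((lengths.loc[counts.index] / 1e3) * (library_size / 1e6))


def call_translated(rpkm_value: float, threshold: float = 10.0) -> bool:
    """Translation evidence: strictly greater than the RPKM threshold."""
    return rpkm_value > threshold


def translation_efficiency(ribo_rpkm: float, rna_rpkm: float) -> float:
    """Footprint abundance relative to mRNA abundance; NaN when mRNA is 0."""
    if rna_rpkm == 0:
        return math.nan
    return ribo_rpkm / rna_rpkm


# ---------------------------------------------------------------------------
# Signal-comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class SignalComparison:
    pearson_r: float
    ks_D: float
    ks_p: float
    zou_ci: Optional[tuple[float, float]] = None
    zou_significant: Optional[bool] = None


def _log_scale(*vectors: np.ndarray) -> list[np.ndarray]:
    """log10 with half the smallest positive value across inputs as pseudocount."""
    pooled = np.concatenate(vectors)
    positive = pooled[pooled > 0]
    pseudo = 0.5 * positive.min() if positive.size else 1.0
    return [np.log10(v + pseudo) for v in vectors]


def zou_ci_dependent(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Zou's CI for r(x,y) - r(x,z): overlapping dependent correlations.

    Combines the Fisher-z confidence limits of the two correlations with
    the correlation between the two correlation estimates (which share
    variable x).
    """
    n = len(x)
    if n < 4:
        raise ValueError("zou_ci requires n >= 4")
    r12 = float(stats.pearsonr(x, y)[0])
    r13 = float(stats.pearsonr(x, z)[0])
    r23 = float(stats.pearsonr(y, z)[0])
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / math.sqrt(n - 3)

    def fisher_limits(r: float) -> tuple[float, float]:
        zr = math.atanh(r)
        return math.tanh(zr - zcrit * se), math.tanh(zr + zcrit * se)

    l1, u1 = fisher_limits(r12)
    l2, u2 = fisher_limits(r13)
    denom = (1 - r12**2) * (1 - r13**2)
    corr = (
        (r23 * (1 - r12**2 - r13**2) - 0.5 * r12 * r13 * (1 - r12**2 - r13**2 - r23**2))
        / denom
        if denom > 0
        else 0.0
    )
    diff = r12 - r13
    lower = diff - math.sqrt(
        max(0.0, (r12 - l1) ** 2 + (u2 - r13) ** 2 - 2 * corr * (r12 - l1) * (u2 - r13))
    )
    upper = diff + math.sqrt(
        max(0.0, (u1 - r12) ** 2 + (r13 - l2) ** 2 - 2 * corr * (u1 - r12) * (r13 - l2))
    )
    return lower, upper


def compare_signal_stats(
    x: Sequence[float],
    y: Sequence[float],
    z: Optional[Sequence[float]] = None,
    log_scale: bool = True,
) -> SignalComparison:
    """Pearson correlation (log scale with pseudocount), KS test, Zou CI.

    With a third vector z, also computes Zou's 95% CI for the difference of
    the overlapping dependent correlations r(x,y) - r(x,z); the difference
    is significant when the CI excludes 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    vecs = [x, y]
    if z is not None:
        z = np.asarray(z, dtype=float)
        if len(z) != len(x):
            raise ValueError("paired vectors must have equal length")
        vecs.append(z)
    scaled = _log_scale(*vecs) if log_scale else vecs
    r = float(stats.pearsonr(scaled[0], scaled[1])[0])
    ks = stats.ks_2samp(x, y, method="auto")
    result = SignalComparison(pearson_r=r, ks_D=float(ks.statistic), ks_p=float(ks.pvalue))
    if z is not None:
        ci = zou_ci_dependent(scaled[0], scaled[1], scaled[2])
        result.zou_ci = ci
        result.zou_significant = not (ci[0] <= 0.0 <= ci[1])
    return result
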