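"""Ribosome-footprint signal diagnostics.

Signal is summarized at footprint 5' ends with no P-site offset: each
unique-perfect alignment contributes one count at its 5' position on its
strand.  Three diagnostics validate that a library behaves like ribosome
profiling rather than RNA-Seq:

* a metagene profile — per-gene-normalized 5'-end density averaged over all
  genes holding at least ``min_reads`` footprints, aligned at the start or
  stop codon;
* start-codon enrichment — mean metagene signal in a window at the start
  divided by mean signal over the gene body;
* triplet periodicity — the distribution of in-ORF 5' ends over the three
  codon frames, with a Pearson chi-square test against uniformity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .config import GenomeSet
from .mapping import AlignmentRecord
from .orfs import OrfRecord

logger = logging.getLogger("metaribo")

SignalTrack = dict[tuple[str, str], np.ndarray]


@dataclass
class MetageneProfile:
    offsets: np.ndarray  # nt relative to the anchor (0 = first nt of anchor codon)
    mean_signal: np.ndarray
    n_genes_used: int


@dataclass
class PeriodicityStat:
    frame_counts: tuple[int, int, int]
    frame_fractions: tuple[float, float, float]
    chi2: float
    p_value: float


def signal_track(
    alignments: Iterable[AlignmentRecord], genomes: GenomeSet
) -> SignalTrack:
    """Per-contig, per-strand arrays of footprint 5'-end counts.

    Total mass equals the number of alignments; an alignment extending past
    its contig is a hard error.
    """
    track: SignalTrack = {
        (c.id, s): np.zeros(len(c), dtype=np.int64) for c in genomes for s in "+-"
    }
    for a in alignments:
        if a.contig_id not in genomes:
            raise ValueError(f"alignment on unknown contig {a.contig_id!r}")
        clen = len(genomes[a.contig_id])
        if a.pos < 1 or a.pos + a.length - 1 > clen:
            raise ValueError(
                f"read {a.read_id} at {a.contig_id}:{a.pos} (len {a.length}) "
                f"extends beyond contig bounds (len {clen})"
            )
        track[(a.contig_id, a.strand)][a.five_prime() - 1] += 1
    return track


def _oriented_window(
    track: SignalTrack, orf: OrfRecord, anchor_pos: int, offsets: np.ndarray
) -> np.ndarray:
    """Signal at strand-oriented offsets around a 1-based anchor position."""
    arr = track[(orf.contig_id, orf.strand)]
    sign = 1 if orf.strand == "+" else -1
    idx = anchor_pos - 1 + sign * offsets
    out = np.zeros(len(offsets), dtype=float)
    ok = (idx >= 0) & (idx < len(arr))
    out[ok] = arr[idx[ok]]
    return out


def _in_orf_counts(track: SignalTrack, orf: OrfRecord) -> np.ndarray:
    """5'-end counts over ORF positions in the gene's reading direction."""
    arr = track[(orf.contig_id, orf.strand)]
    window = arr[orf.start - 1 : orf.end]
    return window if orf.strand == "+" else window[::-1]


def metagene_profile(
    track: SignalTrack,
    orfs: Sequence[OrfRecord],
    flank_nt: int = 50,
    min_reads: int = 10,
    anchor: str = "start",
) -> MetageneProfile:
    """Average per-gene-normalized 5'-end density around start or stop codons.

    Only genes with at least ``min_reads`` in-ORF 5' ends are used; each
    qualifying gene's window is normalized to sum 1 before averaging, so no
    single highly-expressed gene dominates the mean.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    offsets = np.arange(-flank_nt, flank_nt)
    total = np.zeros(len(offsets), dtype=float)
    n_used = 0
    for orf in orfs:
        if (orf.contig_id, orf.strand) not in track:
            raise ValueError(f"ORF {orf.orf_id} on contig absent from track")
        if int(_in_orf_counts(track, orf).sum()) < min_reads:
            continue
        if anchor == "start":
            anchor_pos = orf.start if orf.strand == "+" else orf.end
        else:  # first nt of the stop codon
            anchor_pos = orf.end - 2 if orf.strand == "+" else orf.start + 2
        window = _oriented_window(track, orf, anchor_pos, offsets)
        s = window.sum()
        if s > 0:
            window = window / s
        total += window
        n_used += 1
    mean = total / n_used if n_used else total
    return MetageneProfile(offsets=offsets, mean_signal=mean, n_genes_used=n_used)


def frame_periodicity(
    track: SignalTrack,
    orfs: Sequence[OrfRecord],
    taxa: Optional[dict[str, str]] = None,
    taxon: Optional[str] = None,
) -> PeriodicityStat:
    """Codon-frame distribution of in-ORF 5' ends, tested against uniform.

    Frame 0 is the first nucleotide of each codon in the gene's reading
    direction.  Optionally restrict to the ORFs of one taxon (per-taxon
    codon resolution varies in mixed communities).
    """
    if taxon is not None:
        if taxa is None:
            raise ValueError("taxon filter requires a taxa mapping")
        orfs = [o for o in orfs if taxa.get(o.orf_id) == taxon]
    counts = np.zeros(3, dtype=np.int64)
    for orf in orfs:
        in_orf = _in_orf_counts(track, orf)
        for frame in range(3):
            counts[frame] += int(in_orf[frame::3].sum())
    n = int(counts.sum())
    if n == 0:
        return PeriodicityStat((0, 0, 0), (0.0, 0.0, 0.0), 0.0, 1.0)
    expected = n / 3.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    fractions = tuple(float(c) / n for c in counts)
    return PeriodicityStat(tuple(int(c) for c in counts), fractions, chi2, p)


def start_enrichment(
    profile: MetageneProfile,
    start_window_nt: int = 12,
    body_range: Optional[tuple[int, int]] = None,
) -> float:
    """Ratio of mean metagene signal at the start window over the gene body.

    ``body_range`` is a half-open offset interval; by default it runs from
    the end of the start window to the end of the profiled window.  A zero
    body mean yields +inf with a warning.
    """
    offsets = profile.offsets
    if body_range is None:
        body_range = (start_window_nt, int(offsets[-1]) + 1)
    start_mask = (offsets >= 0) & (offsets < start_window_nt)
    body_mask = (offsets >= body_range[0]) & (offsets < body_range[1])
    if not start_mask.any() or not body_mask.any():
        raise ValueError("profile window does not cover the requested ranges")
    start_mean = float(profile.mean_signal[start_mask].mean())
    body_mean = float(profile.mean_signal[body_mask].mean())
    if body_mean == 0.0:
        logger.warning("zero body-mean signal; start enrichment undefined (+inf)")
        return math.inf
    return start_mean / body_mean
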