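"""Per-read footprint calling: adjusted binomial window test and segmentation.

Each read is scanned with a sliding window (default 25 bp).  For a window with
n adenines (both strands) of which k are called m6A, the null is that calls
occur at the calibrated expected rate p_exp, so X ~ Binomial(n, p_exp); the
lower tail P(X <= k) tests "nucleosomal" (hypo-methylated) and the upper tail
P(X >= k) tests "accessible" (hyper-methylated), both tails including the
observed count.  p-values are Benjamini-Hochberg adjusted per read and per
tail, the central base of each window is labelled by comparing the adjusted
values with the state thresholds, and boundary/ambiguity rules then sharpen
the segmentation.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import MIN_TESTABLE_N, CalibrationTable, ThresholdPair, DEFAULT_THRESHOLDS
from .read_model import (
    ACCESSIBLE,
    AMBIGUOUS,
    NUCLEOSOMAL,
    MethylatedRead,
    ReferenceGenome,
    StateTrack,
    ValidationError,
)
from .windows import read_window_counts

logger = logging.getLogger(__name__)


class WindowStats(NamedTuple):
    """Statistics of one sliding window (centre = genome position)."""

    center: int
    n_adenines: int
    k_m6a: int
    p_exp: float
    p_low: float   # P(X <= k): small means hypo-methylated (nucleosomal)
    p_high: float  # P(X >= k): small means hyper-methylated (accessible)
    testable: bool


@dataclass
class WindowScan:
    """Vectorised window statistics for one read (sequence of WindowStats)."""

    molecule_id: str
    chrom: str
    start: int
    end: int
    window_size: int
    read_methylation: float
    centers: np.ndarray
    n_adenines: np.ndarray
    k_m6a: np.ndarray
    p_exp: np.ndarray
    p_low: np.ndarray
    p_high: np.ndarray
    testable: np.ndarray
    p_adj_low: np.ndarray | None = None
    p_adj_high: np.ndarray | None = None
    too_short: bool = False

    def __len__(self) -> int:
        return self.centers.size

    def __getitem__(self, i: int) -> WindowStats:
        return WindowStats(
            int(self.centers[i]),
            int(self.n_adenines[i]),
            int(self.k_m6a[i]),
            float(self.p_exp[i]),
            float(self.p_low[i]),
            float(self.p_high[i]),
            bool(self.testable[i]),
        )


def _empty_scan(read: MethylatedRead, window_size: int, too_short: bool) -> WindowScan:
    z = np.zeros(0)
    return WindowScan(
        read.molecule_id, read.chrom, read.start, read.end, window_size,
        read.avg_methylation, z.astype(np.int64), z.astype(np.int64),
        z.astype(np.int64), z, z, z, z.astype(bool), too_short=too_short,
    )


def scan_windows(
    read: MethylatedRead,
    genome: ReferenceGenome,
    table: CalibrationTable,
    window_size: int = 25,
) -> WindowScan:
    """Compute the two one-tailed binomial p-values for every complete window.

    Windows with fewer than 3 adenines (the smallest calibrated N) carry no
    test and are flagged untestable.  A read shorter than the window returns
    an empty scan flagged ``too_short``.
    """
    if len(read) < window_size:
        return _empty_scan(read, window_size, too_short=True)
    m = read.avg_methylation
    if not np.isfinite(m):
        raise ValidationError(
            f"{read.molecule_id}: average methylation undefined (no adenines)"
        )
    centers, n, k = read_window_counts(read, genome, window_size)
    testable = n >= MIN_TESTABLE_N
    p_exp = np.full(n.size, np.nan)
    p_low = np.full(n.size, np.nan)
    p_high = np.full(n.size, np.nan)
    if testable.any():
        nt, kt = n[testable], k[testable]
        pe = table.expected(nt, m)
        p_exp[testable] = pe
        p_low[testable] = stats.binom.cdf(kt, nt, pe)
        p_high[testable] = stats.binom.sf(kt - 1, nt, pe)
    return WindowScan(
        read.molecule_id, read.chrom, read.start, read.end, window_size, m,
        centers, n, k, p_exp, p_low, p_high, testable,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_i = min over j >= i (in the ascending sort) of p_(j) * m / j, capped
    at 1.  Values outside [0, 1] raise ValidationError.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def adjusted_scan(
    read: MethylatedRead,
    genome: ReferenceGenome,
    table: CalibrationTable,
    window_size: int = 25,
) -> WindowScan:
    """scan_windows plus per-read BH adjustment of each tail family.

    The lower-tail (nucleosomal) and upper-tail (accessible) p-values form two
    separate BH families; only testable windows enter a family.
    """
    scan = scan_windows(read, genome, table, window_size)
    scan.p_adj_low = np.full(len(scan), np.nan)
    scan.p_adj_high = np.full(len(scan), np.nan)
    t = scan.testable
    if t.any():
        scan.p_adj_low[t] = bh_adjust(scan.p_low[t])
        scan.p_adj_high[t] = bh_adjust(scan.p_high[t])
    return scan


def assign_states(
    scan: WindowScan, thresholds: ThresholdPair = DEFAULT_THRESHOLDS
) -> StateTrack:
    """Label the central base of every window from its adjusted p-values.

    ACCESSIBLE if adj(p_high) < threshold_accessible, NUCLEOSOMAL if
    adj(p_low) < threshold_nucleosomal; if both pass, the smaller adjusted
    p-value wins and an exact tie stays AMBIGUOUS.  Untestable windows and
    edge bases without a complete centred window stay AMBIGUOUS.
    """
    if scan.p_adj_low is None or scan.p_adj_high is None:
        raise ValidationError("assign_states requires a BH-adjusted scan")
    L = scan.end - scan.start
    labels = np.full(L, AMBIGUOUS, dtype=np.uint8)
    p_acc = np.full(L, np.nan)
    p_nuc = np.full(L, np.nan)
    if len(scan):
        idx = scan.centers - scan.start
        p_acc[idx] = scan.p_adj_high
        p_nuc[idx] = scan.p_adj_low
        with np.errstate(invalid="ignore"):
            acc = scan.p_adj_high < thresholds.threshold_accessible
            nuc = scan.p_adj_low < thresholds.threshold_nucleosomal
        both = acc & nuc
        lab = np.full(len(scan), AMBIGUOUS, dtype=np.uint8)
        lab[acc & ~nuc] = ACCESSIBLE
        lab[nuc & ~acc] = NUCLEOSOMAL
        lab[both & (scan.p_adj_high < scan.p_adj_low)] = ACCESSIBLE
        lab[both & (scan.p_adj_low < scan.p_adj_high)] = NUCLEOSOMAL
        labels[idx] = lab
    return StateTrack(
        scan.molecule_id, scan.chrom, scan.start, scan.end, labels, p_acc, p_nuc
    )


def resolve_boundaries(
    track: StateTrack,
    extension: int = 12,
    max_boundary_gap: int | None = None,
    max_ambiguous_reassign: int = 25,
) -> StateTrack:
    """Sharpen state boundaries and reassign short ambiguous runs.

    Rules, applied in this fixed order (coordinates increase left to right):

    1. at each accessible -> nucleosomal transition, the ambiguous bases among
       the ``extension`` (12) nt downstream of the last accessible base become
       accessible;
    2. symmetrically, at nucleosomal -> accessible transitions the ambiguous
       bases among the 12 nt downstream of the last nucleosomal base become
       nucleosomal;
    3. bases claimed by both extensions become nucleosomal;
    4. remaining ambiguous runs shorter than ``max_ambiguous_reassign`` that
       touch a nucleosomal run become nucleosomal.

    A transition fires only when the ambiguous gap between the two called runs
    is at most ``max_boundary_gap`` (default ``2 * extension``, the widest
    boundary ambiguity a sliding window can create); this makes the operation
    idempotent.  Called bases are never flipped between accessible and
    nucleosomal.
    """
    if max_boundary_gap is None:
        max_boundary_gap = 2 * extension
    labels = track.labels.copy()
    L = labels.size
    called = [
        (int(labels[s]), s, e)
        for s, e in _local_runs(labels)
        if labels[s] != AMBIGUOUS
    ]
    acc_cand = np.zeros(L, dtype=bool)
    nuc_cand = np.zeros(L, dtype=bool)
    for (st, s, e), (st2, s2, e2) in zip(called, called[1:]):
        gap = s2 - e
        if st == st2 or gap == 0 or gap > max_boundary_gap:
            continue
        # the extension consumes the ambiguous gap only, up to 12 nt; it never
        # reaches past the next called run
        window = slice(e, min(e + extension, s2))
        if st == ACCESSIBLE and st2 == NUCLEOSOMAL:
            acc_cand[window] |= labels[window] == AMBIGUOUS
        elif st == NUCLEOSOMAL and st2 == ACCESSIBLE:
            nuc_cand[window] |= labels[window] == AMBIGUOUS
    labels[acc_cand & ~nuc_cand] = ACCESSIBLE
    labels[nuc_cand] = NUCLEOSOMAL  # includes the overlap -> nucleosomal rule

    # rule 4: short leftover ambiguous runs adjacent to nucleosomal DNA
    for s, e in _local_runs(labels):
        if labels[s] != AMBIGUOUS or e - s >= max_ambiguous_reassign:
            continue
        left_nuc = s > 0 and labels[s - 1] == NUCLEOSOMAL
        right_nuc = e < L and labels[e] == NUCLEOSOMAL
        if left_nuc or right_nuc:
            labels[s:e] = NUCLEOSOMAL
    return StateTrack(
        track.molecule_id, track.chrom, track.start, track.end, labels,
        track.p_adj_accessible, track.p_adj_nucleosomal,
    )


def _local_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels.astype(np.int16)) != 0) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def call_read(
    read: MethylatedRead,
    genome: ReferenceGenome,
    table: CalibrationTable,
    thresholds: ThresholdPair = DEFAULT_THRESHOLDS,
    window_size: int = 25,
) -> StateTrack:
    """Full per-read pipeline: scan -> BH -> assign -> resolve.

    Reads that cannot be tested (shorter than one window, or without a single
    adenine) pass through fully ambiguous with a logged reason.
    """
    if len(read) < window_size or read.n_adenines == 0:
        reason = "shorter than one window" if len(read) < window_size else "no adenines"
        logger.info("read %s not testable (%s): all-ambiguous track", read.molecule_id, reason)
        return StateTrack(
            read.molecule_id, read.chrom, read.start, read.end,
            np.full(len(read), AMBIGUOUS, dtype=np.uint8),
            np.full(len(read), np.nan), np.full(len(read), np.nan),
        )
    scan = adjusted_scan(read, genome, table, window_size)
    return resolve_boundaries(
        assign_states(scan, thresholds),
        extension=window_size // 2,
        max_ambiguous_reassign=window_size,
    )


def call_reads(
    reads: Iterable[MethylatedRead],
    genome: ReferenceGenome,
    table: CalibrationTable,
    thresholds: ThresholdPair = DEFAULT_THRESHOLDS,
    window_size: int = 25,
) -> list[StateTrack]:
    return [call_read(r, genome, table, thresholds, window_size) for r in reads]


# --------------------------------------------------------------------------- #
# Footprint summaries
# --------------------------------------------------------------------------- #

def footprint_lengths(tracks: Iterable[StateTrack]) -> pd.Series:
    """Histogram of nucleosomal run lengths, per million nucleotides.

    Run-length encodes each resolved track, counts NUCLEOSOMAL runs by length
    and divides by (total nucleotides across tracks) / 1e6.
    """
    counts: dict[int, int] = {}
    total_nt = 0
    for t in tracks:
        total_nt += len(t)
        for st, s, e in t.runs():
            if st == NUCLEOSOMAL:
                counts[e - s] = counts.get(e - s, 0) + 1
    if total_nt == 0 or not counts:
        s = pd.Series(dtype=float, name="per_million_nt")
        s.index.name = "footprint_bp"
        return s
    s = pd.Series(counts, dtype=float).sort_index() / (total_nt / 1e6)
    s.name = "per_million_nt"
    s.index.name = "footprint_bp"
    return s


def write_state_bed(
    tracks: Iterable[StateTrack], path, state: int = NUCLEOSOMAL
) -> None:
    """BED6 of per-molecule runs of one state (name = molecule id)."""
    from .read_model import STATE_NAMES

    with open(path, "w") as fh:
        for t in tracks:
            for st, s, e in t.runs():
                if st == state:
                    fh.write(f"{t.chrom}\t{s}\t{e}\t{t.molecule_id}\t0\t+\n")
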