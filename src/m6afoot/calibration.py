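"""AT-content calibration of expected window methylation, and thresholds.

Long-read m6A calling is inefficient and biased: the called methylation of a
25-bp window depends not only on the molecule's overall methylation but also
on the window's AT content (high-AT windows are under-called) and on poly(A)
run length.  On a fully accessible control (purified DNA treated with the
methyltransferase, "gDNA"), window methylation is linear in the average read
methylation for each AT count N, so the expected window methylation is
modelled as

    p_exp = k(N) * AverageReadMethylation + beta(N),      N = 3 .. window_size

with one (slope, intercept) pair fitted per N.  The footprint caller uses
p_exp as the null of its per-window binomial test.  This module fits the
table from control reads, profiles the poly(A) bias, and calibrates the
caller's adjusted-p-value state thresholds against a target false-positive
rate measured on control data.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .read_model import (
    NUCLEOSOMAL,
    ACCESSIBLE,
    MethylatedRead,
    ReferenceGenome,
    ValidationError,
)
from .windows import read_window_counts

logger = logging.getLogger(__name__)

#: Clamp for predicted window methylation: the binomial test needs p in (0, 1).
P_EXP_EPS = 1e-6

#: Smallest testable window adenine count (smallest calibrated N).
MIN_TESTABLE_N = 3

DEFAULT_FIT_RANGE = (0.07, 0.41)


class CalibrationError(ValueError):
    """Calibration could not be fitted or a threshold target is unattainable."""


@dataclass
class CalibrationTable:
    """Per-AT-count linear calibration of window vs read methylation.

    One row per window adenine count ``N in [3, window_size]`` holding slope
    ``k_N``, intercept ``beta_N``, the fit's R^2 and the number of
    (N, read-methylation-bin) cells it used.  Rows with too few cells are
    filled by linear interpolation in N and flagged ``interpolated``.
    """

    window_size: int
    slope: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    n_cells: np.ndarray
    interpolated: np.ndarray
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE

    def __post_init__(self):
        n_rows = self.window_size - MIN_TESTABLE_N + 1
        for name in ("slope", "intercept", "r2", "n_cells", "interpolated"):
            arr = np.asarray(getattr(self, name))
            if arr.size != n_rows:
                raise CalibrationError(
                    f"{name}: expected {n_rows} rows (N = {MIN_TESTABLE_N}.."
                    f"{self.window_size}), got {arr.size}"
                )
            setattr(self, name, arr)

    @property
    def n_values(self) -> np.ndarray:
        return np.arange(MIN_TESTABLE_N, self.window_size + 1)

    @classmethod
    def identity(cls, window_size: int = 25) -> "CalibrationTable":
        """Unbiased calibration: p_exp equals the read methylation for all N."""
        n = window_size - MIN_TESTABLE_N + 1
        return cls(
            window_size,
            np.ones(n),
            np.zeros(n),
            np.ones(n),
            np.zeros(n, dtype=int),
            np.zeros(n, dtype=bool),
        )

    def coefficients(self, N: int) -> tuple[float, float]:
        if not (MIN_TESTABLE_N <= N <= self.window_size):
            raise CalibrationError(
                f"window adenine count N={N} outside calibrated range "
                f"[{MIN_TESTABLE_N}, {self.window_size}]"
            )
        i = N - MIN_TESTABLE_N
        return float(self.slope[i]), float(self.intercept[i])

    def expected(self, N: np.ndarray, read_methylation: float) -> np.ndarray:
        """Vectorised p_exp for an array of window adenine counts."""
        N = np.asarray(N)
        if N.size and (N.min() < MIN_TESTABLE_N or N.max() > self.window_size):
            bad = N[(N < MIN_TESTABLE_N) | (N > self.window_size)][0]
            raise CalibrationError(
                f"window adenine count N={int(bad)} outside calibrated range "
                f"[{MIN_TESTABLE_N}, {self.window_size}]"
            )
        i = N - MIN_TESTABLE_N
        p = self.slope[i] * read_methylation + self.intercept[i]
        return np.clip(p, P_EXP_EPS, 1.0 - P_EXP_EPS)

    # Serialisation ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.n_values,
                "k": self.slope,
                "beta": self.intercept,
                "r2": self.r2,
                "n_points": self.n_cells,
                "interpolated": self.interpolated.astype(int),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        window_size = int(df["N"].max())
        df = df.sort_values("N")
        return cls(
            window_size,
            df["k"].to_numpy(float),
            df["beta"].to_numpy(float),
            df["r2"].to_numpy(float),
            df["n_points"].to_numpy(int),
            df["interpolated"].to_numpy(bool),
        )


def expected_window_methylation(
    table: CalibrationTable, N: int, read_methylation: float
) -> float:
    """p_exp = clamp(k_N * read_methylation + beta_N, eps, 1 - eps)."""
    if not (0.0 <= read_methylation <= 1.0):
        raise ValidationError(f"read_methylation {read_methylation} outside [0, 1]")
    k, beta = table.coefficients(int(N))
    return float(np.clip(k * read_methylation + beta, P_EXP_EPS, 1.0 - P_EXP_EPS))


# --------------------------------------------------------------------------- #
# Fitting
# --------------------------------------------------------------------------- #

def fit_calibration(
    control_reads: Iterable[MethylatedRead],
    genome: ReferenceGenome,
    window_size: int = 25,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    min_cell_windows: int = 5,
    min_cells: int = 3,
) -> CalibrationTable:
    """Fit the per-N linear calibration from a fully accessible control.

    Control reads with average methylation inside ``fit_range`` (closed
    interval) are grouped by their methylation rounded to 1%; every complete
    window is binned by its AT count N; the mean window methylation (k/N) is
    computed per (N, rounded-methylation) cell with at least
    ``min_cell_windows`` windows; and ordinary least squares is fitted per N
    across cells.  Rows with fewer than ``min_cells`` cells are filled by
    linear interpolation from neighbouring N and flagged (logged).

    Accepts any iterable of reads, so large controls can be streamed.
    """
    lo, hi = fit_range
    w = window_size
    n_rows = w + 1  # index by N directly, 0..w
    counts = np.zeros((n_rows, 101), dtype=np.int64)
    frac_sums = np.zeros((n_rows, 101), dtype=np.float64)
    n_used = 0
    for read in control_reads:
        if len(read) < w or read.n_adenines == 0:
            continue
        m = read.avg_methylation
        if not (lo <= m <= hi):
            continue
        b = int(round(m * 100))
        _, n, k = read_window_counts(read, genome, w)
        mask = n >= 1
        if not mask.any():
            continue
        n_used += 1
        np.add.at(counts, (n[mask], b), 1)
        np.add.at(frac_sums, (n[mask], b), k[mask] / n[mask])
    if n_used == 0:
        raise CalibrationError("no control reads inside the fit range")

    n_values = np.arange(MIN_TESTABLE_N, w + 1)
    slope = np.full(n_values.size, np.nan)
    intercept = np.full(n_values.size, np.nan)
    r2 = np.full(n_values.size, np.nan)
    n_cells = np.zeros(n_values.size, dtype=int)
    interpolated = np.zeros(n_values.size, dtype=bool)
    for i, N in enumerate(n_values):
        ok = counts[N] >= min_cell_windows
        n_cells[i] = int(ok.sum())
        if n_cells[i] < max(min_cells, 2):  # a line needs two points
            interpolated[i] = True
            continue
        x = np.flatnonzero(ok) / 100.0
        y = frac_sums[N, ok] / counts[N, ok]
        fit = stats.linregress(x, y)
        slope[i], intercept[i], r2[i] = fit.slope, fit.intercept, fit.rvalue**2

    reliable = ~interpolated
    if not reliable.any():
        raise CalibrationError("no window AT count had enough data to fit")
    if interpolated.any():
        logger.info(
            "calibration: interpolating rows for N = %s",
            list(n_values[interpolated]),
        )
        xs = n_values[reliable].astype(float)
        slope[interpolated] = np.interp(n_values[interpolated], xs, slope[reliable])
        intercept[interpolated] = np.interp(
            n_values[interpolated], xs, intercept[reliable]
        )
    return CalibrationTable(
        w, slope, intercept, r2, n_cells, interpolated, fit_range=(lo, hi)
    )


# --------------------------------------------------------------------------- #
# Poly(A) bias profile
# --------------------------------------------------------------------------- #

def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """For each True position, the length of its maximal True run (else 0)."""
    out = np.zeros(mask.size, dtype=np.int64)
    if mask.size == 0:
        return out
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def polyA_bias_profile(
    control_reads: Iterable[MethylatedRead],
    genome: ReferenceGenome,
    max_run: int = 8,
) -> pd.Series:
    """Mean called-m6A fraction of control adenines by poly(A) run length.

    Each genomic adenine is assigned the length of its maximal same-strand A
    run (a run of A on the Watson strand, or of T on the Watson strand for
    --strand adenines); runs of at least ``max_run`` are pooled into the top
    bin.  Returns a Series indexed by run length 1..max_run.
    """
    run_plus: dict[str, np.ndarray] = {}
    run_minus: dict[str, np.ndarray] = {}
    called = np.zeros(max_run + 1, dtype=np.int64)
    total = np.zeros(max_run + 1, dtype=np.int64)

    def chrom_runs(chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in run_plus:
            seq = genome.fetch_array(chrom, 0, genome.lengths[chrom])
            run_plus[chrom] = np.minimum(_run_lengths(seq == ord("A")), max_run)
            run_minus[chrom] = np.minimum(_run_lengths(seq == ord("T")), max_run)
        return run_plus[chrom], run_minus[chrom]

    for read in control_reads:
        rp, rm = chrom_runs(read.chrom)
        for a_pos, m6a_pos, runs in (
            (read.a_plus, read.m6a_plus, rp),
            (read.a_minus, read.m6a_minus, rm),
        ):
            if a_pos.size == 0:
                continue
            rl = runs[a_pos]
            np.add.at(total, rl, 1)
            if m6a_pos.size:
                np.add.at(called, runs[m6a_pos], 1)
    with np.errstate(invalid="ignore"):
        frac = called[1:] / total[1:]
    s = pd.Series(frac, index=np.arange(1, max_run + 1), name="m6a_fraction")
    s.index.name = "polyA_run_length"
    return s


# --------------------------------------------------------------------------- #
# Threshold calibration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ThresholdPair:
    """Adjusted-p-value cutoffs for the two state calls."""

    threshold_accessible: float = 0.853
    threshold_nucleosomal: float = 0.918
    target_fp_rate: float = 0.01

    def __post_init__(self):
        for name in ("threshold_accessible", "threshold_nucleosomal"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name}={v} outside (0, 1]")


DEFAULT_THRESHOLDS = ThresholdPair()


def _state_fp_fraction(scans, thresholds, state: int) -> tuple[float, float]:
    """(mean, standard error) across reads of the per-read fraction of bases
    labelled ``state``.  Reads are the sampling units because false calls
    arrive in within-read bursts, not independently per base."""
    # local import: caller depends on this module for the table types
    from . import caller

    fracs = np.empty(len(scans))
    for i, scan in enumerate(scans):
        track = caller.resolve_boundaries(
            caller.assign_states(scan, thresholds),
            extension=scan.window_size // 2,
            max_ambiguous_reassign=scan.window_size,
        )
        fracs[i] = track.state_fraction(state)
    se = fracs.std(ddof=1) / np.sqrt(fracs.size) if fracs.size > 1 else 0.0
    return float(fracs.mean()), float(se)


def _largest_passing(grid, fp_at, target, z, label):
    """Largest grid threshold whose FP bound (mean + z*SE) is < target.

    The FP fraction is monotone non-decreasing in the threshold, so the
    search bisects the grid.
    """

    def bound(t):
        mean, se = fp_at(t)
        return mean + z * se

    if bound(grid[0]) >= target:
        mean, _ = fp_at(grid[0])
        raise CalibrationError(
            f"{label}: no grid threshold achieves FP < {target}; minimum achievable "
            f"is {mean:.4f} at threshold {grid[0]}"
        )
    lo, hi = 0, len(grid) - 1
    while lo < hi:  # invariant: bound(grid[lo]) < target
        mid = (lo + hi + 1) // 2
        if bound(grid[mid]) < target:
            lo = mid
        else:
            hi = mid - 1
    return float(grid[lo])


def calibrate_thresholds(
    control_reads: Sequence[MethylatedRead],
    genome: ReferenceGenome,
    table: CalibrationTable,
    protected_reads: Sequence[MethylatedRead] | None = None,
    target_fp_rate: float = 0.01,
    grid: Sequence[float] | None = None,
    window_size: int = 25,
    init_accessible: float = 0.853,
    fp_z: float = 3.0,
) -> ThresholdPair:
    """Choose state thresholds so false-positive call rates stay below target.

    The fully accessible control contains no nucleosomes, so any base labelled
    nucleosomal on it is a false positive; the largest grid threshold keeping
    that fraction below ``target_fp_rate`` becomes ``threshold_nucleosomal``;
    "below" means the estimate plus ``fp_z`` standard errors (computed across
    reads): maximising the threshold subject to an estimated constraint is a
    winner's-curse selection, so a conservative margin is needed for the
    constraint to keep holding on unseen data of the same composition.
    Symmetrically, ``threshold_accessible`` is calibrated on simulated fully
    protected reads (every accessible call on them is false).  If no protected
    reads are supplied the accessible threshold stays at ``init_accessible``.

    Window scans and BH adjustment are computed once per read; only the cheap
    state assignment is re-run per candidate threshold, searched by bisection
    (the false-positive fraction is monotone in the threshold).
    """
    from . import caller

    control_reads = list(control_reads)
    if not control_reads:
        raise CalibrationError("empty control read set")
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0, 0.025), 3)
    grid = np.sort(np.asarray(grid, dtype=float))

    scans = [
        caller.adjusted_scan(r, genome, table, window_size)
        for r in control_reads
        if len(r) >= window_size and r.n_adenines > 0
    ]
    if not scans:
        raise CalibrationError("no control read is long enough to scan")

    thr_nuc = _largest_passing(
        grid,
        lambda t: _state_fp_fraction(
            scans, ThresholdPair(init_accessible, t, target_fp_rate), NUCLEOSOMAL
        ),
        target_fp_rate,
        fp_z,
        "threshold_nucleosomal",
    )

    thr_acc = init_accessible
    if protected_reads:
        pscans = [
            caller.adjusted_scan(r, genome, table, window_size)
            for r in protected_reads
            if len(r) >= window_size and r.n_adenines > 0
        ]
        if pscans:
            thr_acc = _largest_passing(
                grid,
                lambda t: _state_fp_fraction(
                    pscans, ThresholdPair(t, thr_nuc, target_fp_rate), ACCESSIBLE
                ),
                target_fp_rate,
                fp_z,
                "threshold_accessible",
            )
    else:
        logger.info(
            "no protected reads supplied; threshold_accessible kept at %.3f",
            init_accessible,
        )

    # the conflict-resolution rule couples the two thresholds: re-check the
    # nucleosomal FP under the final pair and back off if needed
    gi = int(np.searchsorted(grid, thr_nuc))
    while gi >= 0:
        pair = ThresholdPair(thr_acc, float(grid[gi]), target_fp_rate)
        mean, se = _state_fp_fraction(scans, pair, NUCLEOSOMAL)
        if mean + fp_z * se < target_fp_rate:
            return pair
        gi -= 1
    raise CalibrationError(
        f"threshold_nucleosomal: no grid threshold achieves FP < {target_fp_rate} "
        "under the final threshold pair"
    )
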