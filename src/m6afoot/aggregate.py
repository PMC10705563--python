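"""Population aggregates: TSS-anchored nucleosome density and per-gene
nucleosome-position heterogeneity.

Nucleosome density at a base pair is the fraction of covering molecules in
which that base is nucleosomal; averaging strand-oriented densities over a
set of well-separated genes yields the familiar phased-array profile around
the TSS.  Heterogeneity is scored per gene by encoding every fully covering
molecule's 601-bp window (TSS +/- 300 bp) as a vector (accessible = 0,
ambiguous = 0.5, nucleosomal = 1) and averaging the Pearson correlation over
all molecule pairs: 1 means every cell has the same nucleosome arrangement,
values near 0 mean positions are essentially unrelated between cells.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .read_model import ACCESSIBLE, AMBIGUOUS, NUCLEOSOMAL, StateTrack

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]

#: StateVector encoding of the three chromatin states.
_ENCODING = np.array([0.5, 0.0, 1.0])  # index by label: AMBIGUOUS, ACCESSIBLE, NUCLEOSOMAL


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected 6-column BED (chrom start end name score strand)")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS
    return df


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """0-based TSS: gene start on the + strand, end - 1 on the - strand."""
    return np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1).astype(int)


@dataclass
class GeneRecord:
    """A gene with the state tracks overlapping its TSS anchor window."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    tracks: list[StateTrack] = field(default_factory=list)
    het_score: float | None = None


# --------------------------------------------------------------------------- #
# Gene selection
# --------------------------------------------------------------------------- #

def select_phasing_genes(
    annotation: pd.DataFrame,
    min_gene_length: int = 200,
    min_promoter: int = 200,
) -> pd.DataFrame:
    """Genes usable for TSS-anchored analyses.

    Keeps genes that (a) overlap no other annotated gene, (b) are at least
    ``min_gene_length`` long and (c) whose TSS lies at least ``min_promoter``
    from the nearest other-gene boundary upstream (strand-oriented, on either
    strand).  A missing upstream neighbour counts as an unbounded promoter.
    """
    ann = annotation.reset_index(drop=True)
    keep = np.ones(len(ann), dtype=bool)
    tss = tss_positions(ann)
    for chrom, idx in ann.groupby("chrom").groups.items():
        idx = np.asarray(list(idx))
        starts = ann.loc[idx, "start"].to_numpy(int)
        ends = ann.loc[idx, "end"].to_numpy(int)
        for a, i in enumerate(idx):
            others = np.arange(len(idx)) != a
            overlap = (starts[others] < ends[a]) & (ends[others] > starts[a])
            if overlap.any():
                keep[i] = False
                continue
            if ends[a] - starts[a] < min_gene_length:
                keep[i] = False
                continue
            t = tss[i]
            if ann.loc[i, "strand"] == "+":
                up_ends = ends[others][ends[others] <= t]
                dist = t - up_ends.max() if up_ends.size else np.inf
            else:
                down_starts = starts[others][starts[others] > t]
                dist = down_starts.min() - (t + 1) if down_starts.size else np.inf
            if dist < min_promoter:
                keep[i] = False
    return ann[keep].reset_index(drop=True)


# --------------------------------------------------------------------------- #
# Track lookup
# --------------------------------------------------------------------------- #

def _index_tracks(tracks: Sequence[StateTrack]) -> dict[str, list[StateTrack]]:
    by_chrom: dict[str, list[StateTrack]] = {}
    for t in tracks:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)
    return by_chrom


def _overlapping(by_chrom, chrom: str, lo: int, hi: int) -> list[StateTrack]:
    out = []
    for t in by_chrom.get(chrom, []):
        if t.start >= hi:
            break
        if t.end > lo:
            out.append(t)
    return out


# --------------------------------------------------------------------------- #
# Phasing profile
# --------------------------------------------------------------------------- #

def phasing_profile(
    tracks: Sequence[StateTrack],
    genes: pd.DataFrame,
    flank: int = 400,
) -> pd.DataFrame:
    """Mean nucleosome density at strand-oriented offsets -flank..+flank.

    Per gene and offset, density = (#covering reads with a nucleosomal label)
    / (#covering reads); offsets without coverage do not contribute to that
    gene.  The profile is the unweighted mean over genes with coverage, with
    upstream offsets negative.  Returns columns offset/density/n_genes.
    """
    by_chrom = _index_tracks(tracks)
    width = 2 * flank + 1
    dens_sum = np.zeros(width)
    gene_n = np.zeros(width, dtype=int)
    tss = tss_positions(genes)
    for i, row in enumerate(genes.itertuples(index=False)):
        t0 = int(tss[i])
        lo, hi = t0 - flank, t0 + flank + 1
        nuc = np.zeros(width, dtype=np.int64)
        cov = np.zeros(width, dtype=np.int64)
        for t in _overlapping(by_chrom, row.chrom, lo, hi):
            a, b = max(t.start, lo), min(t.end, hi)
            seg = t.labels[a - t.start : b - t.start]
            cov[a - lo : b - lo] += 1
            nuc[a - lo : b - lo] += seg == NUCLEOSOMAL
        if row.strand == "-":
            nuc, cov = nuc[::-1], cov[::-1]
        covered = cov > 0
        if not covered.any():
            continue
        dens_sum[covered] += nuc[covered] / cov[covered]
        gene_n[covered] += 1
    with np.errstate(invalid="ignore"):
        density = np.where(gene_n > 0, dens_sum / np.maximum(gene_n, 1), np.nan)
    return pd.DataFrame(
        {"offset": np.arange(-flank, flank + 1), "density": density, "n_genes": gene_n}
    )


# --------------------------------------------------------------------------- #
# Heterogeneity
# --------------------------------------------------------------------------- #

def state_vector(track: StateTrack, tss: int, strand: str, flank: int = 300) -> np.ndarray:
    """Encode the TSS +/- flank window of a fully covering track, 5'->3'.

    accessible = 0, ambiguous = 0.5, nucleosomal = 1; length 2 * flank + 1.
    """
    lo, hi = tss - flank, tss + flank + 1
    if track.start > lo or track.end < hi:
        raise ValueError(
            f"{track.molecule_id} does not fully cover {track.chrom}:{lo}-{hi}"
        )
    seg = track.labels[lo - track.start : hi - track.start]
    vec = _ENCODING[seg]
    return vec[::-1].copy() if strand == "-" else vec


def _mean_pairwise_correlation(vectors: np.ndarray) -> tuple[float, int, int]:
    """(mean Pearson r over pairs, n_pairs used, n_pairs skipped).

    Pairs in which either vector is constant have an undefined correlation
    and are skipped.
    """
    n = vectors.shape[0]
    sd = vectors.std(axis=1)
    const = sd == 0
    total_pairs = n * (n - 1) // 2
    valid = np.flatnonzero(~const)
    if valid.size < 2:
        return float("nan"), 0, total_pairs
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vectors[valid])
    iu = np.triu_indices(valid.size, k=1)
    vals = r[iu]
    used = int(np.isfinite(vals).sum())
    skipped = total_pairs - used
    return float(np.nanmean(vals)), used, skipped


def heterogeneity_scores(
    tracks: Sequence[StateTrack],
    genes: pd.DataFrame,
    flank: int = 300,
    min_reads: int = 6,
) -> pd.DataFrame:
    """Per-gene nucleosome-position heterogeneity score.

    Qualifying reads fully cover TSS +/- flank and contain at least one
    accessible base inside the window (excluding molecules with too few m6A
    to segment).  Genes with fewer than ``min_reads`` qualifying reads are
    omitted.  Columns: gene_id, n_reads, n_pairs, n_skipped_pairs, het_score
    (mean pairwise Pearson r of the 0/0.5/1 state vectors).
    """
    by_chrom = _index_tracks(tracks)
    tss = tss_positions(genes)
    rows = []
    for i, row in enumerate(genes.itertuples(index=False)):
        t0 = int(tss[i])
        lo, hi = t0 - flank, t0 + flank + 1
        vectors = []
        for t in _overlapping(by_chrom, row.chrom, lo, hi):
            if t.start > lo or t.end < hi:
                continue
            seg = t.labels[lo - t.start : hi - t.start]
            if not np.any(seg == ACCESSIBLE):
                continue
            vectors.append(state_vector(t, t0, row.strand, flank))
        if len(vectors) < min_reads:
            continue
        het, n_pairs, n_skipped = _mean_pairwise_correlation(np.asarray(vectors))
        if n_skipped:
            logger.info("gene %s: %d constant-vector pairs skipped", row.gene_id, n_skipped)
        rows.append(
            {
                "gene_id": row.gene_id,
                "n_reads": len(vectors),
                "n_pairs": n_pairs,
                "n_skipped_pairs": n_skipped,
                "het_score": het,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_reads", "n_pairs", "n_skipped_pairs", "het_score"]
    )


def heterogeneity_histogram(scores: Iterable[float], bin_width: float = 0.05) -> pd.DataFrame:
    """Fixed-width histogram of heterogeneity scores over [-1, 1]."""
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    vals = np.asarray([s for s in scores if np.isfinite(s)], dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
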