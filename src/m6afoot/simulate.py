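"""Synthetic data with the statistical structure the footprint model assumes.

The generator emulates methyltransferase footprinting of a small yeast-like
genome: a random sequence at a configurable AT content, non-overlapping genes
with promoter nucleosome-depleted regions (NDRs), ~147-bp nucleosome
footprints separated by short linkers, per-molecule variation in m6A calling
efficiency, an optional AT-content / poly(A) calling bias, and a low residual
methylation (~1%) inside nucleosome footprints.

Two read generators are provided: a fully accessible control ("gDNA", every
adenine is a detection candidate) and nuclei-like reads in which nucleosomal
positions are detected at ``nucleosome_meth`` only.  For nuclei reads the
per-read draw from ``read_meth_distribution`` is the *target overall* read
methylation; the accessible-region detection probability is solved from the
mass balance ``f = nf * q + (1 - nf) * p_acc`` with ``nf`` the read's true
nucleosomal fraction and ``q = nucleosome_meth``.

A window-level in-silico validation (``insilico_window_test``) draws
independent 25-bp windows at set overall methylation and nucleosomal
fractions and scores the caller's window statistic against truth with
ROC/AUC.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .calibration import CalibrationTable, ThresholdPair, DEFAULT_THRESHOLDS
from .caller import bh_adjust
from .read_model import (
    ACCESSIBLE,
    AMBIGUOUS,
    NUCLEOSOMAL,
    MethylatedRead,
    ReferenceGenome,
    StateTrack,
)
from .windows import window_at_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generator.

    ``read_meth_distribution`` is a tuple: ``("fixed", v)``,
    ``("uniform", lo, hi)`` or ``("lognormal", median, sigma)``; the default
    lognormal(median 0.11, sigma 0.5) matches an overall read methylation of
    roughly 11 +/- 6%.  ``at_bias_model`` / ``polyA_bias_model`` map a
    window AT count / poly(A) run length to a detection-probability
    multiplier (None = no bias).  ``nucleosomal_fraction``, when set,
    overrides ``linker_mean`` so the footprint geometry realises that genome
    fraction (with ``ndr_length = 0``).
    """

    seed: int = 0
    genome_length: int = 200_000
    chrom_name: str = "simchr"
    at_content: float = 0.60
    at_content_sd: float = 0.0
    at_block: int = 300
    read_length_mean: float = 2000.0
    read_length_sd: float = 300.0
    read_meth_distribution: tuple = ("lognormal", 0.11, 0.5)
    nucleosome_footprint: int = 147
    linker_mean: float = 18.0
    linker_sd: float = 5.0
    min_linker: int = 5
    ndr_length: int = 120
    nucleosomal_fraction: float | None = None
    nucleosome_meth: float = 0.01
    at_bias_model: Callable[[np.ndarray], np.ndarray] | None = None
    polyA_bias_model: dict[int, float] | None = None
    quality_distribution: tuple = ("fixed", 99.0)
    jitter_sd: float = 15.0
    bias_window: int = 25
    gene_length_range: tuple[int, int] = (600, 1500)
    intergenic_range: tuple[int, int] = (250, 450)

    def __post_init__(self):
        for name in ("at_content", "nucleosome_meth"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nucleosomal_fraction is not None and not (
            0.0 < self.nucleosomal_fraction < 1.0
        ):
            raise ValueError("nucleosomal_fraction must lie in (0, 1)")

    def effective_linker_mean(self) -> float:
        if self.nucleosomal_fraction is None:
            return self.linker_mean
        f = self.nucleosomal_fraction
        return self.nucleosome_footprint * (1.0 - f) / f


def linear_at_bias(slope: float, pivot: int = 15) -> Callable[[np.ndarray], np.ndarray]:
    """Multiplier ``1 + slope * (N - pivot)``: detection declines linearly in
    window AT count for negative ``slope`` (the empirically observed bias)."""

    def bias(N: np.ndarray) -> np.ndarray:
        return 1.0 + slope * (np.asarray(N, dtype=float) - pivot)

    return bias


def _rng(config: SimConfig, tag: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base) % (2**31), tag])


def _draw_read_meth(dist: tuple, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(float(dist[1]), float(dist[2]), size=n)
    if kind == "lognormal":
        median, sigma = float(dist[1]), float(dist[2])
        vals = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
        return np.clip(vals, 1e-3, 0.95)
    raise ValueError(f"unknown read_meth_distribution kind {kind!r}")


def _draw_quality(dist: tuple, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "normal":
        return np.clip(rng.normal(float(dist[1]), float(dist[2]), size=n), 0, 100)
    raise ValueError(f"unknown quality_distribution kind {kind!r}")


# --------------------------------------------------------------------------- #
# Genome and annotation
# --------------------------------------------------------------------------- #

def simulate_genome(
    config: SimConfig, seed: int | None = None
) -> tuple[ReferenceGenome, pd.DataFrame]:
    """Random genome at the configured AT content plus a gene/TSS annotation.

    Genes are non-overlapping, at least 200 bp long, separated by intergenic
    gaps that leave every promoter at least 200 bp — the selection universe of
    the TSS-anchored analyses.  Returns (genome, BED6-style DataFrame with
    columns chrom/start/end/gene_id/score/strand).
    """
    rng = _rng(config, 1, seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    L = config.genome_length
    if config.at_content_sd > 0:
        # compositional heterogeneity: local AT content varies block to block
        # around the genome-wide mean, as in real genomes
        n_blocks = int(np.ceil(L / config.at_block))
        at_local = np.clip(
            rng.normal(config.at_content, config.at_content_sd, n_blocks), 0.05, 0.95
        )
        at_per_base = np.repeat(at_local, config.at_block)[:L]
    else:
        at_per_base = np.full(L, config.at_content)
    u = rng.random(L)
    v = rng.random(L)
    is_at = u < at_per_base
    seq = np.where(is_at, np.where(v < 0.5, bases[0], bases[3]),
                   np.where(v < 0.5, bases[1], bases[2]))
    genome = ReferenceGenome({config.chrom_name: seq.tobytes().decode("ascii")})

    genes = []
    glo, ghi = config.gene_length_range
    ilo, ihi = config.intergenic_range
    pos = int(rng.integers(ilo, ihi))
    i = 0
    while True:
        glen = int(rng.integers(glo, ghi + 1))
        if pos + glen + ilo >= config.genome_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            {
                "chrom": config.chrom_name,
                "start": pos,
                "end": pos + glen,
                "gene_id": f"gene{i:04d}",
                "score": 0,
                "strand": strand,
            }
        )
        pos += glen + int(rng.integers(ilo, ihi))
        i += 1
    return genome, pd.DataFrame(genes)


# --------------------------------------------------------------------------- #
# Detection-probability machinery
# --------------------------------------------------------------------------- #

class _DetectionModel:
    """Precomputed per-position detection multipliers for one chromosome."""

    def __init__(self, config: SimConfig, genome: ReferenceGenome, chrom: str):
        seq = genome.fetch_array(chrom, 0, genome.lengths[chrom])
        L = seq.size
        mult = np.ones(L)
        if config.at_bias_model is not None:
            w = config.bias_window
            n = window_at_counts(seq, w)  # window starting at i
            centered = np.ones(L) * n.mean()
            centered[w // 2 : w // 2 + n.size] = n
            mult *= config.at_bias_model(centered)
        self.mult_plus = mult.copy()
        self.mult_minus = mult.copy()
        if config.polyA_bias_model:
            from .calibration import _run_lengths

            max_run = max(config.polyA_bias_model)
            table = np.ones(max_run + 1)
            for rl, v in config.polyA_bias_model.items():
                table[rl] = v
            rp = np.minimum(_run_lengths(seq == ord("A")), max_run)
            rm = np.minimum(_run_lengths(seq == ord("T")), max_run)
            self.mult_plus *= table[rp]
            self.mult_minus *= table[rm]
        self.a_plus = np.flatnonzero(seq == ord("A"))
        self.a_minus = np.flatnonzero(seq == ord("T"))


def _read_adenines(model: _DetectionModel, start: int, end: int):
    lo, hi = np.searchsorted(model.a_plus, [start, end])
    a_plus = model.a_plus[lo:hi]
    lo, hi = np.searchsorted(model.a_minus, [start, end])
    a_minus = model.a_minus[lo:hi]
    return a_plus, a_minus


def _sample_spans(config, rng, genome_length: int, n_reads: int):
    lengths = np.maximum(
        50, np.round(rng.normal(config.read_length_mean, config.read_length_sd, n_reads))
    ).astype(int)
    lengths = np.minimum(lengths, genome_length)
    starts = rng.integers(0, genome_length - lengths + 1)
    return starts, lengths


def simulate_gdna_reads(
    config: SimConfig,
    genome: ReferenceGenome,
    n_reads: int,
    seed: int | None = None,
    id_prefix: str = "gdna",
) -> list[MethylatedRead]:
    """Fully accessible control reads (purified DNA treated with the enzyme).

    Every adenine is a detection candidate with probability
    ``read_fraction * at_bias * polyA_bias`` (clipped to [0, 1]).
    """
    rng = _rng(config, 2, seed)
    chrom = config.chrom_name
    model = _DetectionModel(config, genome, chrom)
    starts, lengths = _sample_spans(config, rng, genome.lengths[chrom], n_reads)
    fracs = _draw_read_meth(config.read_meth_distribution, rng, n_reads)
    quals = _draw_quality(config.quality_distribution, rng, n_reads)
    reads = []
    for i in range(n_reads):
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        a_plus, a_minus = _read_adenines(model, s, e)
        p_plus = np.clip(fracs[i] * model.mult_plus[a_plus], 0, 1)
        p_minus = np.clip(fracs[i] * model.mult_minus[a_minus], 0, 1)
        m6a_plus = a_plus[rng.random(a_plus.size) < p_plus]
        m6a_minus = a_minus[rng.random(a_minus.size) < p_minus]
        reads.append(
            MethylatedRead(
                f"{id_prefix}{i:06d}", chrom, s, e, float(quals[i]),
                a_plus, a_minus, m6a_plus, m6a_minus,
            )
        )
    return reads


def simulate_protected_reads(
    config: SimConfig,
    genome: ReferenceGenome,
    n_reads: int,
    seed: int | None = None,
    id_prefix: str = "prot",
) -> list[MethylatedRead]:
    """Fully nucleosome-protected reads: flat detection at nucleosome_meth.

    Used as the truth set for calibrating the accessible-call threshold (an
    accessible call on such a read is by construction a false positive).
    """
    rng = _rng(config, 3, seed)
    chrom = config.chrom_name
    model = _DetectionModel(config, genome, chrom)
    starts, lengths = _sample_spans(config, rng, genome.lengths[chrom], n_reads)
    quals = _draw_quality(config.quality_distribution, rng, n_reads)
    q = config.nucleosome_meth
    reads = []
    for i in range(n_reads):
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        a_plus, a_minus = _read_adenines(model, s, e)
        m6a_plus = a_plus[rng.random(a_plus.size) < q]
        m6a_minus = a_minus[rng.random(a_minus.size) < q]
        reads.append(
            MethylatedRead(
                f"{id_prefix}{i:06d}", chrom, s, e, float(quals[i]),
                a_plus, a_minus, m6a_plus, m6a_minus,
            )
        )
    return reads


# --------------------------------------------------------------------------- #
# Nuclei reads with nucleosome geometry
# --------------------------------------------------------------------------- #

def _chromatin_template(
    config: SimConfig, annotation: pd.DataFrame, genome_length: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Footprint intervals (starts, ends) tiled between promoter NDRs."""
    ndrs = []
    if config.ndr_length > 0 and len(annotation):
        for row in annotation.itertuples(index=False):
            if row.strand == "+":
                ndrs.append((max(0, row.start - config.ndr_length), row.start))
            else:
                ndrs.append((row.end, min(genome_length, row.end + config.ndr_length)))
    ndrs.sort()
    boundaries = [0]
    for s, e in ndrs:
        boundaries += [s, e]
    boundaries.append(genome_length)
    fp = config.nucleosome_footprint
    linker_mean = config.effective_linker_mean()
    starts, ends = [], []
    for i in range(0, len(boundaries) - 1, 2):
        seg_start, seg_end = boundaries[i], boundaries[i + 1]
        pos = seg_start
        while pos + fp <= seg_end:
            starts.append(pos)
            ends.append(pos + fp)
            linker = max(config.min_linker, int(round(rng.normal(linker_mean, config.linker_sd))))
            pos += fp + linker
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _truth_labels(fp_starts, fp_ends, shift: int, s: int, e: int) -> np.ndarray:
    labels = np.full(e - s, ACCESSIBLE, dtype=np.uint8)
    if fp_starts.size == 0:
        return labels
    starts = fp_starts + shift
    ends = fp_ends + shift
    lo = int(np.searchsorted(ends, s, side="right"))
    hi = int(np.searchsorted(starts, e, side="left"))
    for j in range(lo, hi):
        a, b = max(int(starts[j]), s), min(int(ends[j]), e)
        if b > a:
            labels[a - s : b - s] = NUCLEOSOMAL
    return labels


def simulate_nuclei_reads(
    config: SimConfig,
    genome: ReferenceGenome,
    annotation: pd.DataFrame,
    n_reads: int = 0,
    seed: int | None = None,
    anchor: str = "uniform",
    reads_per_gene: int = 0,
    id_prefix: str = "nuc",
) -> list[tuple[MethylatedRead, StateTrack]]:
    """Nuclei-like reads with ground-truth state tracks.

    Nucleosome footprints are tiled between promoter NDRs from a fixed
    chromosome template; each molecule shifts the whole template by a draw
    from Normal(0, ``jitter_sd``), modelling cell-to-cell variation in
    nucleosome position.  ``anchor="tss"`` centres ``reads_per_gene`` reads
    on every annotated TSS instead of sampling positions uniformly.
    """
    rng = _rng(config, 4, seed)
    chrom = config.chrom_name
    glen = genome.lengths[chrom]
    model = _DetectionModel(config, genome, chrom)
    fp_starts, fp_ends = _chromatin_template(config, annotation, glen, rng)

    if anchor == "tss":
        tss = np.where(
            annotation["strand"] == "+", annotation["start"], annotation["end"] - 1
        ).astype(int)
        centers = np.repeat(tss, reads_per_gene)
        lengths = np.maximum(
            50,
            np.round(
                rng.normal(config.read_length_mean, config.read_length_sd, centers.size)
            ),
        ).astype(int)
        starts = np.clip(centers - lengths // 2, 0, None)
        lengths = np.minimum(lengths, glen - starts)
        n_reads = centers.size
    elif anchor == "uniform":
        starts, lengths = _sample_spans(config, rng, glen, n_reads)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    fracs = _draw_read_meth(config.read_meth_distribution, rng, n_reads)
    quals = _draw_quality(config.quality_distribution, rng, n_reads)
    q = config.nucleosome_meth
    out = []
    for i in range(n_reads):
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        shift = int(round(rng.normal(0.0, config.jitter_sd))) if config.jitter_sd > 0 else 0
        labels = _truth_labels(fp_starts, fp_ends, shift, s, e)
        a_plus, a_minus = _read_adenines(model, s, e)
        nf = float(np.mean(labels == NUCLEOSOMAL)) if labels.size else 0.0
        if nf >= 1.0:
            p_acc = q
        else:
            p_acc = (fracs[i] - nf * q) / (1.0 - nf)
            p_acc = float(np.clip(p_acc, q, 0.99))
        nuc_plus = labels[a_plus - s] == NUCLEOSOMAL
        nuc_minus = labels[a_minus - s] == NUCLEOSOMAL
        p_plus = np.where(nuc_plus, q, np.clip(p_acc * model.mult_plus[a_plus], 0, 1))
        p_minus = np.where(nuc_minus, q, np.clip(p_acc * model.mult_minus[a_minus], 0, 1))
        m6a_plus = a_plus[rng.random(a_plus.size) < p_plus]
        m6a_minus = a_minus[rng.random(a_minus.size) < p_minus]
        mol = f"{id_prefix}{i:06d}"
        read = MethylatedRead(
            mol, chrom, s, e, float(quals[i]), a_plus, a_minus, m6a_plus, m6a_minus
        )
        out.append((read, StateTrack(mol, chrom, s, e, labels)))
    return out


# --------------------------------------------------------------------------- #
# In-silico window-level validation
# --------------------------------------------------------------------------- #

def insilico_window_test(
    m6a_fractions: Sequence[float] = (0.05, 0.10, 0.15),
    nuc_fractions: Sequence[float] = (0.6, 0.7, 0.8),
    n_windows: int = 100_000,
    at_content: float = 0.6,
    nucleosome_meth: float = 0.01,
    window_size: int = 25,
    table: CalibrationTable | None = None,
    thresholds: ThresholdPair = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Window-level validation of the binomial model with ROC/AUC.

    For every (overall m6A fraction, nucleosomal fraction) condition,
    ``n_windows`` independent windows are drawn: the window AT count is
    Binomial(window_size, at_content); nucleosomal windows are methylated at
    ``nucleosome_meth`` and accessible windows at the rate solving the mass
    balance for the set overall fraction.  The caller's lower-tail p-value
    scores each window (small = nucleosomal); the AUC sweeps that score, and a
    confusion table applies per-sample BH adjustment with the state
    thresholds.  Raises ValueError when the accessible rate solves outside
    (nucleosome_meth, 1].
    """
    if table is None:
        table = CalibrationTable.identity(window_size)
    rows = []
    for m in m6a_fractions:
        for f in nuc_fractions:
            p_acc = (m - f * nucleosome_meth) / (1.0 - f)
            if p_acc > 1.0 or p_acc <= nucleosome_meth:
                raise ValueError(
                    f"accessible methylation {p_acc:.3f} for overall {m} at "
                    f"nucleosomal fraction {f} is unattainable"
                )
            rng = np.random.default_rng(
                [int(seed) % (2**31), int(m * 1000), int(f * 1000)]
            )
            N = rng.binomial(window_size, at_content, size=n_windows)
            truth_nuc = rng.random(n_windows) < f
            p_true = np.where(truth_nuc, nucleosome_meth, p_acc)
            k = rng.binomial(N, p_true)
            testable = N >= 3
            Nt, kt, truth = N[testable], k[testable], truth_nuc[testable]
            p_exp = table.expected(Nt, m)
            p_low = stats.binom.cdf(kt, Nt, p_exp)
            p_high = stats.binom.sf(kt - 1, Nt, p_exp)
            auc = float(roc_auc_score(truth, -p_low))
            adj_low = bh_adjust(p_low)
            adj_high = bh_adjust(p_high)
            acc = adj_high < thresholds.threshold_accessible
            nuc = adj_low < thresholds.threshold_nucleosomal
            both = acc & nuc
            call = np.full(truth.size, AMBIGUOUS, dtype=np.uint8)
            call[acc & ~nuc] = ACCESSIBLE
            call[nuc & ~acc] = NUCLEOSOMAL
            call[both & (adj_high < adj_low)] = ACCESSIBLE
            call[both & (adj_low < adj_high)] = NUCLEOSOMAL
            rows.append(
                {
                    "m6a_fraction": m,
                    "nuc_fraction": f,
                    "accessible_meth": p_acc,
                    "n_windows": int(truth.size),
                    "auc": auc,
                    "true_nuc_called_nuc": int(np.sum(truth & (call == NUCLEOSOMAL))),
                    "true_nuc_called_acc": int(np.sum(truth & (call == ACCESSIBLE))),
                    "true_acc_called_acc": int(np.sum(~truth & (call == ACCESSIBLE))),
                    "true_acc_called_nuc": int(np.sum(~truth & (call == NUCLEOSOMAL))),
                    "ambiguous_fraction": float(np.mean(call == AMBIGUOUS)),
                }
            )
    return pd.DataFrame(rows)
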