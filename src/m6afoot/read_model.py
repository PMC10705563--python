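"""Domain types and I/O for single-molecule m6A footprinting reads.

A methyltransferase (M.EcoGII) methylates adenines in protein-free DNA; after
long-read sequencing, each consensus read carries a set of called m6A bases.
This module defines the in-memory representation of such reads
(:class:`MethylatedRead`), the per-base chromatin-state annotation produced by
the footprint caller (:class:`StateTrack`), a light reference-genome container,
and two on-disk dialects:

* a plain tab-separated interchange table (one read per row, m6A positions as
  ``pos:strand`` tokens), and
* an IGV-compatible annotated BAM in which each called m6A is encoded as a
  single-base insertion at its adenine (base ``A`` for Watson-strand m6A, ``T``
  for Crick-strand m6A, inserted immediately before the base), accessible
  regions as sequence matches, nucleosome footprints as mismatched
  (substituted) blocks, and ambiguous regions as deletions.

Coordinates are 0-based half-open throughout; the BAM writer converts to the
on-disk convention via pysam.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"

#: Integer chromatin-state labels used in :class:`StateTrack` arrays.
AMBIGUOUS = 0
ACCESSIBLE = 1
NUCLEOSOMAL = 2

STATE_NAMES = {AMBIGUOUS: "ambiguous", ACCESSIBLE: "accessible", NUCLEOSOMAL: "nucleosomal"}


class FormatError(ValueError):
    """A file does not conform to the declared tabular format."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (e.g. m6A at a non-adenine)."""


class DialectError(ValueError):
    """A BAM record does not conform to the annotated-BAM dialect."""


# --------------------------------------------------------------------------- #
# Reference genome
# --------------------------------------------------------------------------- #

class ReferenceGenome(Mapping):
    """Mapping ``chrom -> uppercase sequence`` with fast slicing.

    Sequences are stored as uint8 ASCII arrays so that window arithmetic in the
    caller and calibration modules can operate on numpy views without copies.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            arr = np.frombuffer(str(seq).upper().encode("ascii"), dtype=np.uint8).copy()
            self._seqs[str(chrom)] = arr

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._seqs.items():
                fh.write(f">{chrom}\n")
                s = arr.tobytes().decode("ascii")
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom].tobytes().decode("ascii")

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    # Convenience -----------------------------------------------------------
    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._seqs.items()}

    def fetch_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Return the uint8 ASCII array for ``[start, end)`` (no copy)."""
        arr = self._seqs[chrom]
        if start < 0 or end > len(arr) or start > end:
            raise ValidationError(
                f"{chrom}:{start}-{end} out of bounds (length {len(arr)})"
            )
        return arr[start:end]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.fetch_array(chrom, start, end).tobytes().decode("ascii")

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.fetch_array(chrom, pos, pos + 1)[0])


# --------------------------------------------------------------------------- #
# MethylatedRead
# --------------------------------------------------------------------------- #

def _as_sorted_int_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    return np.sort(arr)


def _is_subset(sub: np.ndarray, sup: np.ndarray) -> bool:
    """True if sorted array ``sub`` is a subset of sorted array ``sup``."""
    if sub.size == 0:
        return True
    idx = np.searchsorted(sup, sub)
    if np.any(idx >= sup.size):
        return False
    return bool(np.all(sup[idx] == sub))


@dataclass(frozen=True)
class MethylatedRead:
    """One sequenced DNA molecule with its called m6A bases.

    Adenine positions are strand-resolved genome coordinates: ``a_plus`` holds
    positions whose Watson base is ``A`` (an adenine on the + strand) and
    ``a_minus`` positions whose Watson base is ``T`` (an adenine on the -
    strand).  ``m6a_plus``/``m6a_minus`` are the called-methylated subsets.

    ``read_quality`` is the average per-base quality score of the consensus
    read in ``[0, 100]`` (taken from input metadata, never recomputed here);
    a NaN marks a read whose quality is unknown.
    """

    molecule_id: str
    chrom: str
    start: int
    end: int
    read_quality: float
    a_plus: np.ndarray
    a_minus: np.ndarray
    m6a_plus: np.ndarray
    m6a_minus: np.ndarray

    def __post_init__(self):
        for name in ("a_plus", "a_minus", "m6a_plus", "m6a_minus"):
            object.__setattr__(self, name, _as_sorted_int_array(getattr(self, name)))
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"{self.molecule_id}: bad span {self.start}-{self.end}")
        for name in ("a_plus", "a_minus"):
            arr = getattr(self, name)
            if arr.size and (arr[0] < self.start or arr[-1] >= self.end):
                raise ValidationError(
                    f"{self.molecule_id}: {name} positions outside [{self.start}, {self.end})"
                )
        if not _is_subset(self.m6a_plus, self.a_plus):
            raise ValidationError(f"{self.molecule_id}: m6a_plus not a subset of a_plus")
        if not _is_subset(self.m6a_minus, self.a_minus):
            raise ValidationError(f"{self.molecule_id}: m6a_minus not a subset of a_minus")
        q = float(self.read_quality)
        if not np.isnan(q) and not (0.0 <= q <= 100.0):
            raise ValidationError(f"{self.molecule_id}: read_quality {q} outside [0, 100]")

    @classmethod
    def from_m6a_set(
        cls,
        molecule_id: str,
        chrom: str,
        start: int,
        end: int,
        read_quality: float,
        m6a_positions: Iterable[tuple[int, str]],
        genome: ReferenceGenome,
    ) -> "MethylatedRead":
        """Build a read deriving adenine positions from the reference.

        Every m6A must sit on a reference adenine of its strand; otherwise a
        :class:`ValidationError` naming the offending position is raised.
        """
        seq = genome.fetch_array(chrom, start, end)
        a_plus = start + np.flatnonzero(seq == ord("A"))
        a_minus = start + np.flatnonzero(seq == ord("T"))
        m6a_p, m6a_m = [], []
        for pos, strand in m6a_positions:
            pos = int(pos)
            if pos < start or pos >= end:
                raise ValidationError(
                    f"{molecule_id}: m6A at {chrom}:{pos} outside read span"
                )
            base = chr(seq[pos - start])
            if strand == PLUS:
                if base != "A":
                    raise ValidationError(
                        f"{molecule_id}: m6A at {chrom}:{pos}:+ but reference base is {base}"
                    )
                m6a_p.append(pos)
            elif strand == MINUS:
                if base != "T":
                    raise ValidationError(
                        f"{molecule_id}: m6A at {chrom}:{pos}:- but reference base is {base}"
                    )
                m6a_m.append(pos)
            else:
                raise ValidationError(f"{molecule_id}: bad strand {strand!r} at {pos}")
        return cls(molecule_id, chrom, start, end, read_quality,
                   a_plus, a_minus, m6a_p, m6a_m)

    # Derived quantities ----------------------------------------------------
    def __len__(self) -> int:
        return self.end - self.start

    @property
    def n_adenines(self) -> int:
        return int(self.a_plus.size + self.a_minus.size)

    @property
    def n_m6a(self) -> int:
        return int(self.m6a_plus.size + self.m6a_minus.size)

    @property
    def avg_methylation(self) -> float:
        """Fraction of adenines called m6A; NaN if the read has no adenines."""
        if self.n_adenines == 0:
            return float("nan")
        return self.n_m6a / self.n_adenines

    @property
    def adenine_positions(self) -> frozenset[tuple[int, str]]:
        return frozenset(
            [(int(p), PLUS) for p in self.a_plus] + [(int(p), MINUS) for p in self.a_minus]
        )

    @property
    def m6a_positions(self) -> frozenset[tuple[int, str]]:
        return frozenset(
            [(int(p), PLUS) for p in self.m6a_plus] + [(int(p), MINUS) for p in self.m6a_minus]
        )

    @property
    def m6a_watson(self) -> np.ndarray:
        """Sorted genome positions of all m6A projected on the Watson strand.

        A +-strand m6A projects to its own position (Watson ``A``); a --strand
        m6A projects to the Watson ``T`` of the same base pair, also its own
        position.  The two sets cannot collide (a base is either A or T).
        """
        return np.sort(np.concatenate([self.m6a_plus, self.m6a_minus]))


# --------------------------------------------------------------------------- #
# StateTrack
# --------------------------------------------------------------------------- #

@dataclass
class StateTrack:
    """Per-base chromatin state labels for one read.

    ``labels`` is a uint8 array of length ``end - start`` over
    {AMBIGUOUS, ACCESSIBLE, NUCLEOSOMAL}.  ``p_adj_accessible`` /
    ``p_adj_nucleosomal`` hold the BH-adjusted p-values of the accessible
    (upper-tail) and nucleosomal (lower-tail) tests at each base; NaN where no
    complete window is centred (read edges, untestable windows).
    """

    molecule_id: str
    chrom: str
    start: int
    end: int
    labels: np.ndarray
    p_adj_accessible: np.ndarray | None = None
    p_adj_nucleosomal: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.size != self.end - self.start:
            raise ValidationError(
                f"{self.molecule_id}: labels length {self.labels.size} != span "
                f"{self.end - self.start}"
            )
        for name in ("p_adj_accessible", "p_adj_nucleosomal"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != self.labels.size:
                    raise ValidationError(f"{self.molecule_id}: {name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.end - self.start

    def runs(self) -> list[tuple[int, int, int]]:
        """Run-length encoding as ``(state, genome_start, genome_end)`` triples."""
        return [
            (int(self.labels[s]), self.start + s, self.start + e)
            for s, e in _run_bounds(self.labels)
        ]

    def state_fraction(self, state: int) -> float:
        return float(np.mean(self.labels == state)) if len(self) else float("nan")


def _run_bounds(labels: np.ndarray) -> list[tuple[int, int]]:
    """Boundaries of maximal equal-label runs, as local [start, end) offsets."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels.astype(np.int16)) != 0) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


# --------------------------------------------------------------------------- #
# Tabular interchange format
# --------------------------------------------------------------------------- #

INTERCHANGE_COLUMNS = ["molecule_id", "chrom", "start", "end", "read_quality", "m6a_positions"]


def _format_m6a(read: MethylatedRead) -> str:
    tokens = [f"{int(p)}:{PLUS}" for p in read.m6a_plus]
    tokens += [f"{int(p)}:{MINUS}" for p in read.m6a_minus]
    tokens.sort(key=lambda t: int(t.split(":")[0]))
    return ",".join(tokens)


def _parse_m6a(text: str, line_no: int) -> list[tuple[int, str]]:
    text = "" if text is None else str(text).strip()
    if text in ("", "nan", "."):
        return []
    out = []
    for token in text.split(","):
        parts = token.strip().split(":")
        if len(parts) != 2 or parts[1] not in (PLUS, MINUS):
            raise FormatError(f"line {line_no}: malformed m6A token {token!r}")
        try:
            out.append((int(parts[0]), parts[1]))
        except ValueError as exc:
            raise FormatError(f"line {line_no}: malformed m6A token {token!r}") from exc
    return out


def read_interchange_table(path: str | Path, genome: ReferenceGenome) -> list[MethylatedRead]:
    """Read the TSV interchange format, deriving adenines from the reference.

    Raises :class:`FormatError` for missing columns or malformed rows (with
    1-based line numbers) and :class:`ValidationError` for m6A positions that
    do not sit on an adenine of the stated strand.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INTERCHANGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    reads = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
            quality = float(row.read_quality)
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-numeric coordinate or quality") from exc
        m6a = _parse_m6a(row.m6a_positions, line_no)
        try:
            reads.append(
                MethylatedRead.from_m6a_set(
                    str(row.molecule_id), str(row.chrom), start, end, quality, m6a, genome
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
    return reads


def write_interchange_table(reads: Iterable[MethylatedRead], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "read_quality": r.read_quality,
            "m6a_positions": _format_m6a(r),
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=INTERCHANGE_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# Annotated BAM dialect
# --------------------------------------------------------------------------- #

_CIGAR_MATCH = 0      # M: plain aligned block (read without state annotation)
_CIGAR_INS = 1        # I: single-base insertion = one called m6A
_CIGAR_DEL = 2        # D: ambiguous region
_CIGAR_EQ = 7         # =: accessible region
_CIGAR_X = 8          # X: nucleosome footprint (mismatched block)

_STATE_TO_OP = {ACCESSIBLE: _CIGAR_EQ, NUCLEOSOMAL: _CIGAR_X, AMBIGUOUS: _CIGAR_DEL}
_OP_TO_STATE = {_CIGAR_MATCH: ACCESSIBLE, _CIGAR_EQ: ACCESSIBLE,
                _CIGAR_X: NUCLEOSOMAL, _CIGAR_DEL: AMBIGUOUS}

# Substitution map used to make nucleosomal blocks visible as mismatches.
_SUBST = bytes.maketrans(b"ACGT", b"CATG")

QUALITY_TAG = "XQ"   # float: average read quality score (0-100)
STATES_TAG = "ZS"    # int 1: record carries state annotation


def _encode_record(
    read: MethylatedRead,
    track: StateTrack | None,
    genome: ReferenceGenome,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    L = len(read)
    refseq = genome.fetch_array(read.chrom, read.start, read.end)
    if track is None:
        run_list = [(ACCESSIBLE, 0, L)]
        op_for = {ACCESSIBLE: _CIGAR_MATCH}
    else:
        if (track.chrom, track.start, track.end) != (read.chrom, read.start, read.end):
            raise ValidationError(f"{read.molecule_id}: track span differs from read span")
        run_list = [(st, s - read.start, e - read.start) for st, s, e in track.runs()]
        op_for = _STATE_TO_OP

    m6a = read.m6a_watson - read.start
    plus_set = set(int(p) for p in read.m6a_plus)
    cigar: list[tuple[int, int]] = []
    seq_parts: list[bytes] = []

    def emit_block(state: int, s: int, e: int) -> None:
        if e <= s:
            return
        op = op_for[state]
        cigar.append((op, e - s))
        if op in (_CIGAR_MATCH, _CIGAR_EQ):
            seq_parts.append(refseq[s:e].tobytes())
        elif op == _CIGAR_X:
            seq_parts.append(refseq[s:e].tobytes().translate(_SUBST))
        # deletions consume no query sequence

    for state, s, e in run_list:
        lo, hi = np.searchsorted(m6a, [s, e])
        pos = s
        for m in m6a[lo:hi]:
            emit_block(state, pos, int(m))
            base = b"A" if int(m) + read.start in plus_set else b"T"
            cigar.append((_CIGAR_INS, 1))
            seq_parts.append(base)
            pos = int(m)
        emit_block(state, pos, e)

    rec = pysam.AlignedSegment(header)
    rec.query_name = read.molecule_id
    rec.flag = 0
    rec.reference_name = read.chrom
    rec.reference_start = read.start
    rec.mapping_quality = 60
    rec.cigartuples = cigar
    rec.query_sequence = b"".join(seq_parts).decode("ascii")
    tags = [(QUALITY_TAG, float(read.read_quality), "f")]
    if track is not None:
        tags.append((STATES_TAG, 1, "i"))
    rec.set_tags(tags)
    return rec


def write_annotated_bam(
    items: Iterable[tuple[MethylatedRead, StateTrack | None]],
    path: str | Path,
    genome: ReferenceGenome,
    index: bool = True,
) -> None:
    """Write reads (optionally with state tracks) as a sorted, indexed BAM.

    Missing chromosomes raise :class:`ValidationError`; overlapping reads are
    legal (each molecule is an independent record).
    """
    lengths = genome.lengths
    chroms = list(lengths)
    header = pysam.AlignmentHeader.from_references(chroms, [lengths[c] for c in chroms])
    order = {c: i for i, c in enumerate(chroms)}
    items = list(items)
    for read, _ in items:
        if read.chrom not in order:
            raise ValidationError(f"chromosome {read.chrom!r} not in reference")
    items.sort(key=lambda it: (order[it[0].chrom], it[0].start, it[0].molecule_id))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for read, track in items:
            bam.write(_encode_record(read, track, genome, header))
    if index:
        pysam.index(str(path))


def read_annotated_bam(
    path: str | Path, genome: ReferenceGenome
) -> list[tuple[MethylatedRead, StateTrack | None]]:
    """Read the annotated-BAM dialect back into in-memory objects.

    Round-trips :func:`write_annotated_bam` bit-exactly on coordinates, m6A
    sets and state labels.  Adjusted p-values are not serialised in BAM and
    come back as ``None``.
    """
    out = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            out.append(_decode_record(rec, genome))
    return out


def _decode_record(
    rec: pysam.AlignedSegment, genome: ReferenceGenome
) -> tuple[MethylatedRead, StateTrack | None]:
    chrom = rec.reference_name
    start = rec.reference_start
    qseq = rec.query_sequence or ""
    ref_pos = start
    qpos = 0
    label_runs: list[tuple[int, int]] = []  # (state, length)
    m6a: list[tuple[int, str]] = []
    for op, length in rec.cigartuples or []:
        if op == _CIGAR_INS:
            if length != 1:
                raise DialectError(
                    f"{rec.query_name}: {length}-base insertion (m6A must be 1 base)"
                )
            base = qseq[qpos].upper()
            if base == "A":
                m6a.append((ref_pos, PLUS))
            elif base == "T":
                m6a.append((ref_pos, MINUS))
            else:
                raise DialectError(
                    f"{rec.query_name}: inserted base {base!r} at {chrom}:{ref_pos} "
                    "is neither A nor T"
                )
            qpos += 1
        elif op in _OP_TO_STATE:
            label_runs.append((_OP_TO_STATE[op], length))
            ref_pos += length
            if op != _CIGAR_DEL:
                qpos += length
        else:
            raise DialectError(f"{rec.query_name}: unknown CIGAR op {op}")
    end = ref_pos
    quality = float(rec.get_tag(QUALITY_TAG)) if rec.has_tag(QUALITY_TAG) else float("nan")
    read = MethylatedRead.from_m6a_set(
        rec.query_name, chrom, start, end, quality, m6a, genome
    )
    if rec.has_tag(STATES_TAG) and int(rec.get_tag(STATES_TAG)) == 1:
        labels = np.concatenate(
            [np.full(n, st, dtype=np.uint8) for st, n in label_runs]
        ) if label_runs else np.zeros(0, dtype=np.uint8)
        track = StateTrack(rec.query_name, chrom, start, end, labels)
    else:
        track = None
    return read, track


# --------------------------------------------------------------------------- #
# Read-level operations
# --------------------------------------------------------------------------- #

def filter_reads(
    reads: Iterable[MethylatedRead],
    min_quality: float = 90.0,
    min_adenines: int = 1,
) -> list[MethylatedRead]:
    """Keep reads with ``read_quality >= min_quality`` (inclusive) and at least
    ``min_adenines`` adenines.  Order-preserving and idempotent; reads with an
    unknown (NaN) quality are dropped whenever ``min_quality > 0``.
    """
    kept = []
    for r in reads:
        q = float(r.read_quality)
        ok_q = q >= min_quality if not np.isnan(q) else min_quality <= 0
        if ok_q and r.n_adenines >= min_adenines:
            kept.append(r)
    return kept


def inter_m6a_distances(
    reads: Iterable[MethylatedRead], per_strand: bool = False
) -> pd.Series:
    """Distances between consecutive m6A within each read, per million nt.

    Distances are computed on sorted genome positions within each read
    (strand-pooled by default, i.e. both strands projected on the Watson
    strand; ``per_strand=True`` computes them within each strand separately).
    Counts are divided by (total nucleotides across all input reads) / 1e6.
    """
    counts: dict[int, int] = {}
    total_nt = 0
    for r in reads:
        total_nt += len(r)
        if per_strand:
            pos_sets = [r.m6a_plus, r.m6a_minus]
        else:
            pos_sets = [r.m6a_watson]
        for pos in pos_sets:
            if pos.size >= 2:
                for d in np.diff(pos):
                    counts[int(d)] = counts.get(int(d), 0) + 1
    if total_nt == 0:
        return pd.Series(dtype=float, name="per_million_nt")
    divisor = total_nt / 1e6
    s = pd.Series(counts, dtype=float).sort_index() / divisor
    s.name = "per_million_nt"
    s.index.name = "distance_bp"
    return s
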