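"""Local alignment of reads to the padded small-RNA reference.

Smith-Waterman-style local alignment with affine gaps over the PADDED
reference sequence, where a read base aligned to a pad N scores 0 (neither
reward nor penalty). That lets non-templated end bases (5' G at -1 beyond a
gene-style entry, the TGIRT 5' T artifact, CCA beyond an entry lacking it)
sit in the pad instead of being penalised, which is the point of padding.
The DP engine is Bio.Align.PairwiseAligner; CIGAR construction, pad/soft
clip accounting, core-coordinate conversion, deterministic tie-breaking and
all-best-score primary selection are implemented here.

Conventions:

* a gap of length L costs gap_open + L * gap_extend;
* core coordinates are 0-based half-open on the unpadded core; read bases
  aligned into pads are folded into the soft-clip counts (``soft5``/
  ``soft3``) and never move the core span;
* every alignment tying the maximal score across reference entries is kept
  as primary with fractional counting weight 1/k ("all best score").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .reference import PaddedReference

MIN_READ_LENGTH = 15


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    match_score: float = 2.0
    mismatch_penalty: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 20.0
    length_partition_threshold: int = 50

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise AlignmentError("match_score must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("penalties must be <= 0")
        if self.length_partition_threshold <= 0:
            raise AlignmentError("length partition threshold must be positive")


DEFAULT_PARAMS = AlignParams()


@dataclass
class AlignmentRecord:
    read_id: str
    ref_id: str
    core_start: int
    core_end: int
    #: CIGAR over the read: S soft clip (includes pad-aligned bases),
    #: M aligned (match or mismatch), I insertion, D deletion.
    cigar: str
    mismatches: tuple[tuple[int, str], ...]
    score: float
    read_seq: str
    soft5: int
    soft3: int
    is_primary: bool = False
    weight: float = 1.0

    @property
    def read_len(self) -> int:
        return len(self.read_seq)

    @property
    def aligned_read_span_nt(self) -> int:
        return self.read_len - self.soft5 - self.soft3

    @property
    def core_span_nt(self) -> int:
        return self.core_end - self.core_start

    def cigar_ops(self) -> list[tuple[str, int]]:
        ops, n = [], ""
        for ch in self.cigar:
            if ch.isdigit():
                n += ch
            else:
                ops.append((ch, int(n)))
                n = ""
        return ops

    def rescore(self, core: str, params: AlignParams = DEFAULT_PARAMS) -> float:
        """Re-derive the alignment score from CIGAR + sequences.

        Pad-aligned (soft-clipped) bases contribute 0 by construction, so
        rescoring the core alignment reproduces the full padded-DP score.
        """
        score = 0.0
        t, q = self.core_start, 0  # leading soft clip is a CIGAR op
        for op, n in self.cigar_ops():
            if op == "S":
                q += n
            elif op == "M":
                for _ in range(n):
                    score += (
                        params.match_score
                        if self.read_seq[q] == core[t]
                        else params.mismatch_penalty
                    )
                    t += 1
                    q += 1
            elif op == "I":
                score += params.gap_open + n * params.gap_extend
                q += n
            elif op == "D":
                score += params.gap_open + n * params.gap_extend
                t += n
            else:  # pragma: no cover
                raise AlignmentError(f"bad CIGAR op {op}")
        return score


def _make_engine(params: AlignParams) -> Align.PairwiseAligner:
    m = np.full((5, 5), params.mismatch_penalty)
    np.fill_diagonal(m, params.match_score)
    m[4, :] = 0.0  # N row/column: neutral
    m[:, 4] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array("ACGTN", dims=2, data=m)
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _blocks(coordinates: np.ndarray) -> list[tuple[str, int, int, int]]:
    """Alignment path as (op, length, target_start, query_start) runs."""
    out = []
    t, q = coordinates[:, 0]
    for k in range(1, coordinates.shape[1]):
        t1, q1 = coordinates[:, k]
        dt, dq = t1 - t, q1 - q
        if dt and dq:
            out.append(("M", int(dt), int(t), int(q)))
        elif dt:
            out.append(("D", int(dt), int(t), int(q)))
        elif dq:
            out.append(("I", int(dq), int(t), int(q)))
        t, q = t1, q1
    return out


def _parse_alignment(
    aln, read_id: str, read: str, ref_id: str, core: str, pad: int
) -> AlignmentRecord | None:
    """Convert a padded-coordinate DP alignment into a core-coordinate record.

    Read bases aligned to pad Ns (and indels adjacent to them) fold into the
    soft clips; the core span covers exactly the core-aligned columns.
    """
    core_len = len(core)
    cols: list[tuple[str, int | None, int | None]] = []
    for op, n, t, q in _blocks(aln.coordinates):
        for k in range(n):
            if op == "M":
                cols.append(("M", t + k, q + k))
            elif op == "I":
                cols.append(("I", None, q + k))
            else:
                cols.append(("D", t + k, None))
    core_m = [
        i for i, (op, t, _) in enumerate(cols) if op == "M" and 0 <= t - pad < core_len
    ]
    if not core_m:
        return None  # alignment entirely within pads
    first, last = core_m[0], core_m[-1]
    q_lo, q_hi = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
    soft5 = q_lo + sum(1 for _, _, q in cols[:first] if q is not None)
    soft3 = (len(read) - q_hi) + sum(1 for _, _, q in cols[last + 1 :] if q is not None)
    core_start = cols[first][1] - pad
    core_end = cols[last][1] - pad + 1
    ops: list[tuple[str, int]] = []
    mismatches: list[tuple[int, str]] = []
    for op, t, q in cols[first : last + 1]:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
        if op == "M" and read[q] != core[t - pad]:
            mismatches.append((t - pad, read[q]))
    cigar_parts: list[tuple[str, int]] = []
    if soft5:
        cigar_parts.append(("S", soft5))
    cigar_parts.extend(ops)
    if soft3:
        cigar_parts.append(("S", soft3))
    cigar = "".join(f"{n}{o}" for o, n in cigar_parts)
    return AlignmentRecord(
        read_id=read_id,
        ref_id=ref_id,
        core_start=int(core_start),
        core_end=int(core_end),
        cigar=cigar,
        mismatches=tuple(mismatches),
        score=float(aln.score),
        read_seq=read,
        soft5=int(soft5),
        soft3=int(soft3),
    )


def align_read(
    read: str,
    ref: PaddedReference,
    params: AlignParams = DEFAULT_PARAMS,
    read_id: str = "read",
    engine: Align.PairwiseAligner | None = None,
    n_tiebreak: int = 4,
) -> list[AlignmentRecord]:
    """Best local alignment of one read against every reference entry.

    Returns one record per entry whose best score reaches ``min_score``,
    sorted by descending score. Equal-score tracebacks within an entry are
    broken deterministically: smaller core_start, then shorter CIGAR, then
    lexicographic CIGAR (evaluated over the first ``n_tiebreak`` co-optimal
    tracebacks).
    """
    if len(read) < MIN_READ_LENGTH:
        raise AlignmentError(f"read shorter than {MIN_READ_LENGTH} nt (too_short)")
    if not ref.entries:
        raise AlignmentError("empty reference set")
    if engine is None:
        engine = _make_engine(params)
    records = []
    for ref_id in ref.entries:
        core = ref.core(ref_id)
        padded = ref.padded_sequence(ref_id)
        alns = engine.align(padded, read)
        try:
            score = alns.score
        except (ValueError, AttributeError):
            continue
        if score < params.min_score:
            continue
        parsed = [
            rec
            for aln in itertools.islice(alns, n_tiebreak)
            if (rec := _parse_alignment(aln, read_id, read, ref_id, core, ref.pad_len))
        ]
        if not parsed:
            continue
        best = min(parsed, key=lambda r: (r.core_start, len(r.cigar_ops()), r.cigar))
        records.append(best)
    records.sort(key=lambda r: (-r.score, r.ref_id))
    return records


def select_primary(candidates: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep every record tying the maximal score, weight 1/k ("all best score")."""
    if not candidates:
        return []
    read_ids = {r.read_id for r in candidates}
    if len(read_ids) != 1:
        raise AlignmentError("select_primary expects records from a single read")
    top = max(r.score for r in candidates)
    primaries = [r for r in candidates if r.score == top]
    w = 1.0 / len(primaries)
    return [replace(r, is_primary=True, weight=w) for r in primaries]


def align_library(
    reads: Iterable[tuple[str, str]],
    ref: PaddedReference,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[list[AlignmentRecord], list[tuple[str, str]]]:
    """Align a library and select primaries; returns (records, rejected).

    Alignment is cached per unique read sequence, so deeply duplicated
    libraries (the common case for short RNAs) align quickly.
    """
    engine = _make_engine(params)
    cache: dict[str, list[AlignmentRecord]] = {}
    records: list[AlignmentRecord] = []
    rejected: list[tuple[str, str]] = []
    for read_id, seq in reads:
        if len(seq) < MIN_READ_LENGTH:
            rejected.append((read_id, "too_short"))
            continue
        if seq not in cache:
            cache[seq] = select_primary(
                align_read(seq, ref, params, read_id="_", engine=engine)
            )
        hits = cache[seq]
        if not hits:
            rejected.append((read_id, "unaligned"))
            continue
        records.extend(replace(r, read_id=read_id) for r in hits)
    return records, rejected


def partition_by_length(
    records: Sequence[AlignmentRecord], threshold: int = 50
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Split records into read length > threshold vs <= threshold."""
    if threshold <= 0:
        raise AlignmentError("threshold must be positive")
    long = [r for r in records if r.read_len > threshold]
    short = [r for r in records if r.read_len <= threshold]
    return long, short


# ---------------------------------------------------------------------------
# I/O: TSV mirror and SAM (padded coordinates, core offsets in tags).

TSV_COLUMNS = [
    "read_id",
    "ref_id",
    "core_start",
    "core_end",
    "cigar",
    "mismatches",
    "score",
    "is_primary",
    "weight",
    "soft5",
    "soft3",
    "read_seq",
]


def records_to_frame(records: Sequence[AlignmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "read_id": r.read_id,
            "ref_id": r.ref_id,
            "core_start": r.core_start,
            "core_end": r.core_end,
            "cigar": r.cigar,
            "mismatches": ";".join(f"{i}:{b}" for i, b in r.mismatches),
            "score": r.score,
            "is_primary": int(r.is_primary),
            "weight": r.weight,
            "soft5": r.soft5,
            "soft3": r.soft3,
            "read_seq": r.read_seq,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_tsv(records: Sequence[AlignmentRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        mism = tuple(
            (int(p.split(":")[0]), p.split(":")[1])
            for p in str(row.mismatches).split(";")
            if p
        )
        out.append(
            AlignmentRecord(
                read_id=str(row.read_id),
                ref_id=str(row.ref_id),
                core_start=int(row.core_start),
                core_end=int(row.core_end),
                cigar=str(row.cigar),
                mismatches=mism,
                score=float(row.score),
                read_seq=str(row.read_seq),
                soft5=int(row.soft5),
                soft3=int(row.soft3),
                is_primary=bool(row.is_primary),
                weight=float(row.weight),
            )
        )
    return out


def write_sam(records: Sequence[AlignmentRecord], ref: PaddedReference, path) -> None:
    """SAM in the padded coordinate system (1-based POS per SAM spec).

    Optional tags: ZC:i unpadded core start, ZW:f primary counting weight.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": rid, "LN": ref.padded_length(rid)} for rid in ref.entries
        ],
    }
    tid = {rid: i for i, rid in enumerate(ref.entries)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.query_sequence = r.read_seq
            a.reference_id = tid[r.ref_id]
            a.reference_start = r.core_start + ref.pad_len
            a.mapping_quality = 255
            a.flag = 0 if r.is_primary else 256
            a.cigarstring = r.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * r.read_len)
            a.set_tag("ZC", r.core_start, "i")
            a.set_tag("ZW", float(r.weight), "f")
            a.set_tag("AS", int(r.score), "i")
            fh.write(a)
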