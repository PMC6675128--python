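"""Base-modification signatures from TGIRT read-through behaviour.

TGIRT reads through Watson-Crick-face methylations and leaves diagnostic
traces instead of dropping the template: m1A produces misincorporation with
a T/G-dominated read-base spectrum, m1G produces both misincorporation and
premature stops (5'-truncated reads piling up at the roadblock). This
module builds per-position pileup spectra, an RT-stop profile from the
short-read partition, calls modified sites from those two signals, and
detects the non-templated end marks (5' G at -1, 3' CCA, TGIRT's
non-templated 5' T) that identify mature-tRNA-derived reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import AlignmentRecord
from .reference import PaddedReference, TrnaAnnotation

BASES = ("A", "C", "G", "T")


@dataclass
class PositionSpectrum:
    ref_id: str
    core_index: int
    ref_base: str
    base_counts: dict[str, float]  # keys A,C,G,T,del
    depth: float = 0.0

    @property
    def mismatch_fraction(self) -> float:
        if self.depth == 0:
            return 0.0
        wrong = sum(
            c for b, c in self.base_counts.items() if b != self.ref_base
        )
        return wrong / self.depth

    @property
    def tg_share(self) -> float:
        """(T+G) / all mismatching substitutions (deletions excluded)."""
        subs = sum(
            c for b, c in self.base_counts.items() if b != self.ref_base and b != "del"
        )
        if subs == 0:
            return 0.0
        tg = sum(
            self.base_counts[b] for b in ("T", "G") if b != self.ref_base
        )
        return tg / subs


def _walk_core_columns(record: AlignmentRecord):
    """Yield (core_index, read_base or None-for-deletion) over core M/D ops."""
    t, q = record.core_start, 0  # leading soft clip is part of the CIGAR
    for op, n in record.cigar_ops():
        if op == "S":
            q += n
        elif op == "M":
            for _ in range(n):
                yield t, record.read_seq[q]
                t += 1
                q += 1
        elif op == "D":
            for _ in range(n):
                yield t, None
                t += 1
        elif op == "I":
            q += n


def misincorporation_spectra(
    records: Sequence[AlignmentRecord], ref: PaddedReference, ref_id: str
) -> list[PositionSpectrum]:
    """Primary-weighted per-position pileup; soft clips excluded."""
    core = ref.core(ref_id)
    spectra = [
        PositionSpectrum(
            ref_id=ref_id,
            core_index=i,
            ref_base=core[i],
            base_counts={b: 0.0 for b in (*BASES, "del")},
        )
        for i in range(len(core))
    ]
    for r in records:
        if r.ref_id != ref_id:
            continue
        for ci, base in _walk_core_columns(r):
            s = spectra[ci]
            s.base_counts[base if base is not None else "del"] += r.weight
            s.depth += r.weight
    return spectra


@dataclass(frozen=True)
class ModificationThresholds:
    min_depth: float = 50.0
    min_mismatch: float = 0.05
    min_tg_share: float = 0.6
    min_stop: float = 0.1


@dataclass(frozen=True)
class ModificationCall:
    core_index: int
    kind_guess: str  # m1A-like | m1G-like
    mismatch_fraction: float
    tg_share: float
    stop_fraction: float


@dataclass
class RtStopProfile:
    """5'-truncation landscape of the short (<=50 nt) read partition."""

    ref_id: str
    counts: dict[int, float]
    n_reads: float

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_reads == 0:
            return {}
        return {i: c / self.n_reads for i, c in self.counts.items()}

    def fraction_at(self, core_index: int) -> float:
        return self.fractions.get(core_index, 0.0)


def rt_stop_profile(
    short_records: Sequence[AlignmentRecord], ref_id: str
) -> RtStopProfile:
    """Where do short reads start? A premature RT stop at a roadblock base
    makes the sense read begin at that core index, so stop sites appear as
    5'-end peaks in the short partition."""
    counts: dict[int, float] = {}
    total = 0.0
    for r in short_records:
        if r.ref_id != ref_id:
            continue
        counts[r.core_start] = counts.get(r.core_start, 0.0) + r.weight
        total += r.weight
    return RtStopProfile(ref_id=ref_id, counts=counts, n_reads=total)


def call_modification_sites(
    spectra: Sequence[PositionSpectrum],
    stop_profile: RtStopProfile | None = None,
    thresholds: ModificationThresholds = ModificationThresholds(),
) -> list[ModificationCall]:
    """Call m1A-like and m1G-like sites from spectra + stop signal.

    m1A-like: reference base A, mismatch fraction >= min_mismatch and a
    T/G-dominated substitution spectrum. m1G-like: reference base G with
    either elevated mismatch or an RT-stop fraction >= min_stop. Positions
    below min_depth are skipped.
    """
    calls: list[ModificationCall] = []
    for s in spectra:
        if s.depth < thresholds.min_depth:
            continue
        stop = stop_profile.fraction_at(s.core_index) if stop_profile else 0.0
        if (
            s.ref_base == "A"
            and s.mismatch_fraction >= thresholds.min_mismatch
            and s.tg_share >= thresholds.min_tg_share
        ):
            calls.append(
                ModificationCall(s.core_index, "m1A-like", s.mismatch_fraction, s.tg_share, stop)
            )
        elif s.ref_base == "G" and (
            s.mismatch_fraction >= thresholds.min_mismatch or stop >= thresholds.min_stop
        ):
            calls.append(
                ModificationCall(s.core_index, "m1G-like", s.mismatch_fraction, s.tg_share, stop)
            )
    return calls


@dataclass(frozen=True)
class EndFlags:
    g_minus1: bool
    cca: bool
    nt_5p_T: bool


def detect_nontemplated_ends(
    record: AlignmentRecord,
    ref: PaddedReference,
    ann: TrnaAnnotation | None = None,
) -> EndFlags:
    """Non-templated end evidence for one primary alignment.

    * ``g_minus1``: the read covers the mature G(-1) (core index 0 on an
      entry annotated with it) with base G, or places a G immediately 5' of
      the core on an entry lacking the G(-1).
    * ``cca``: the read's last aligned/clipped bases spell CCA at the core
      3' boundary (templated CCA for mature-tRNA entries, clip-derived
      otherwise).
    * ``nt_5p_T``: exactly one 5' soft-clipped/pad base, and it is T.
    """
    core = ref.core(record.ref_id)
    read = record.read_seq
    has_g1 = bool(ann and ann.has_g_minus1)
    if has_g1:
        g_minus1 = record.core_start == 0 and _base_at(record, 0) == "G"
    else:
        g_minus1 = (
            record.core_start == 0
            and record.soft5 >= 1
            and read[record.soft5 - 1] == "G"
        )
    if core.endswith("CCA"):
        n = len(core)
        g = [_base_at(record, i) for i in (n - 3, n - 2, n - 1)]
        cca = g == ["C", "C", "A"]
    else:
        cca = (
            record.core_end == len(core)
            and record.soft3 >= 3
            and read[record.soft5 + _read_consumed(record) :][:3] == "CCA"
        )
    nt5pt = record.soft5 == 1 and read[0] == "T"
    return EndFlags(g_minus1=g_minus1, cca=cca, nt_5p_T=nt5pt)


def _read_consumed(record: AlignmentRecord) -> int:
    return sum(n for op, n in record.cigar_ops() if op in "MI")


def _base_at(record: AlignmentRecord, core_index: int) -> str | None:
    """Read base aligned at a core index (None if uncovered or deleted)."""
    if not record.core_start <= core_index < record.core_end:
        return None
    for ci, base in _walk_core_columns(record):
        if ci == core_index:
            return base
    return None


def spectra_to_frame(spectra: Sequence[PositionSpectrum]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "core_index": s.core_index,
                "ref_base": s.ref_base,
                "depth": s.depth,
                **{b: s.base_counts[b] for b in (*BASES, "del")},
                "mismatch_fraction": s.mismatch_fraction,
                "tg_share": s.tg_share,
            }
            for s in spectra
        ]
    )


def position_frequency_matrix(
    spectra: Sequence[PositionSpectrum],
) -> pd.DataFrame:
    """Logo input: per-position read-base frequencies, header row A,C,G,T."""
    rows = []
    for s in spectra:
        subs = {b: s.base_counts[b] for b in BASES}
        total = sum(subs.values())
        rows.append(
            {b: (subs[b] / total if total else 0.0) for b in BASES}
        )
    return pd.DataFrame(rows, columns=list(BASES))
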