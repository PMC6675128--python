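"""Padded small-RNA reference construction and annotation.

The analysis maps reads against a custom reference of short RNA sequences
(tRNAs, miRNAs, background RNAs) in which every entry is padded on both ends
with N characters so that non-templated end additions (the tRNA-His 5' G at
position -1, the universal 3' CCA, TGIRT's non-templated 5' T artifact) can
align without penalty instead of being clipped or mis-scored.

All internal coordinates are 0-based, half-open, on the UNPADDED core
sequence; padded coordinates exist only inside the aligner. Display (field
convention) positions are produced by sparse anchors plus linear
interpolation: tRNA-His numbering starts at G(-1) and skips one position in
the variable loop, so core index 58 displays as position 57.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("tRNA", "miRNA", "rRNA", "piRNA", "other")
ALPHABET = frozenset("ACGT")

#: Synthetic mature tRNA-His-GUG, 76 nt, stored in the DNA alphabet: the
#: non-templated G(-1) at core index 0, anticodon GTG at core 34-36, m1G at
#: core 37, m1A at core 58 (display position 57) and the 3' CCA tail.
TRNA_HIS_ID = "tRNA-His-GTG"
TRNA_HIS_CORE = (
    "GGCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACCTCGGTTCGTAT"
    "CCGAGTCACGGCACCA"
)
TRNA_HIS_M1G_INDEX = 37
TRNA_HIS_M1A_INDEX = 58

MIR4454_ID = "hsa-miR-4454"
MIR4454_LENGTH = 21

# Fixed arbitrary background entries so enrichment analysis has a null set.
BACKGROUND_ENTRIES = (
    ("bg-snRNA-like", "rRNA",
     "ACCCTGTAAACTGTCCAACGCGACGGACTCCGGAGAGCATCGTAATTGGATTCCAAACTATG"
     "TTTCCGTGCATTCAGAAGGAGTAGCTAAGGACCATCTAGGACTT"),
    ("bg-hairpin-like", "other",
     "CTCGAACACTCCGAATCCGGACAAAGATCATATGCTTGAGATCTCCGAGCTCCCTTTACCGCTAACAC"),
    ("bg-mirna-like", "miRNA", "TGAAAGGGACCCTGCCAATCTT"),
)


class AlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,T}."""


class ReferenceError(ValueError):
    """Malformed reference set (duplicate ids, bad pad length, ...)."""


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    if not ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - ALPHABET)
        raise AlphabetError(f"non-ACGT characters: {bad}")
    return seq


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    sequence: str
    category: str = "other"

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PaddedReference:
    """Reference entries plus the N-pad convention (default 10 per end)."""

    entries: dict[str, ReferenceEntry]
    pad_len: int = 10

    def __post_init__(self) -> None:
        if self.pad_len < 0:
            raise ReferenceError("pad_len must be >= 0")

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self.entries

    def ids(self) -> list[str]:
        return list(self.entries)

    def core(self, entry_id: str) -> str:
        return self.entries[entry_id].sequence

    def padded_sequence(self, entry_id: str) -> str:
        pad = "N" * self.pad_len
        return pad + self.entries[entry_id].sequence + pad

    def padded_length(self, entry_id: str) -> int:
        return len(self.entries[entry_id]) + 2 * self.pad_len

    def strip(self, padded: str) -> str:
        """Recover a core from a padded sequence (round-trip of padding)."""
        if self.pad_len == 0:
            return padded
        return padded[self.pad_len : -self.pad_len]


@dataclass(frozen=True)
class TrnaAnnotation:
    entry_id: str
    has_g_minus1: bool = False
    has_cca: bool = False
    modification_sites: tuple[tuple[int, str], ...] = ()
    #: (core_index, display position as an integer) sparse anchors.
    display_anchors: tuple[tuple[int, int], ...] = ()

    def validate(self, core: str) -> None:
        if self.has_cca and not core.endswith("CCA"):
            raise ValueError(f"{self.entry_id}: has_cca but core does not end CCA")
        if self.has_g_minus1 and not core.startswith("G"):
            raise ValueError(f"{self.entry_id}: has_g_minus1 but core[0] != G")
        for idx, kind in self.modification_sites:
            if not 0 <= idx < len(core):
                raise ValueError(f"{self.entry_id}: modification index {idx} out of core")
            if kind not in ("m1A", "m1G"):
                raise ValueError(f"unknown modification kind {kind!r}")


@dataclass(frozen=True)
class MirnaAnnotation:
    entry_id: str
    mature_sequence: str
    parent_trna_id: str | None = None
    #: Core start of the mature window on the parent tRNA (0-based).
    offset_from_trna_3p: int | None = None

    def __post_init__(self) -> None:
        if len(self.mature_sequence) < 15:
            raise ValueError("mature miRNA sequence shorter than 15 nt")


def maturate_trna(body: str, add_g_minus1: bool, add_cca: bool) -> str:
    """Build a mature tRNA sequence from a gene-encoded body.

    Mature tRNAs carry a non-templated 3' CCA; tRNA-His additionally carries
    a non-templated 5' G at position -1.
    """
    _check_sequence(body)
    return ("G" if add_g_minus1 else "") + body + ("CCA" if add_cca else "")


def build_padded_reference(
    entries: Iterable[ReferenceEntry | tuple], pad_len: int = 10
) -> PaddedReference:
    """Assemble a padded reference; ids must be unique, pad_len >= 0."""
    table: dict[str, ReferenceEntry] = {}
    for e in entries:
        if not isinstance(e, ReferenceEntry):
            e = ReferenceEntry(*e)
        if e.id in table:
            raise ReferenceError(f"duplicate entry id {e.id!r}")
        table[e.id] = e
    return PaddedReference(entries=table, pad_len=pad_len)


def to_display_position(ann: TrnaAnnotation, core_index: int, core_len: int | None = None) -> str:
    """Map a 0-based core index to the field's display numbering.

    Piecewise-linear interpolation between the annotation's sparse anchors;
    outside the anchored range the nearest segment's slope is extended. Only
    the anchored positions themselves are guaranteed exact.
    """
    if core_len is not None and not 0 <= core_index < core_len:
        raise IndexError(f"core index {core_index} out of range")
    anchors = sorted(ann.display_anchors)
    if not anchors:
        return str(core_index)
    if core_index < 0:
        raise IndexError(f"core index {core_index} out of range")
    if len(anchors) == 1:
        return str(anchors[0][1] + (core_index - anchors[0][0]))
    # pick the segment whose span contains the index, else the nearest one
    seg = None
    for (i0, v0), (i1, v1) in zip(anchors, anchors[1:]):
        seg = (i0, v0, i1, v1)
        if core_index <= i1:
            break
    i0, v0, i1, v1 = seg
    x = v0 + (core_index - i0) * (v1 - v0) / (i1 - i0)
    import math

    return str(int(math.floor(x + 0.5)))


def derive_mirna_from_trna(
    trna_entry: ReferenceEntry,
    trna_ann: TrnaAnnotation,
    length: int,
    mirna_id: str = MIR4454_ID,
) -> MirnaAnnotation:
    """Reconstruct the annotated-miRNA decoy from the tRNA 3' end.

    The annotated miRNA is identical to the mature tRNA 3' window (CCA
    included) except that it templates G where the tRNA carries m1A; without
    that substitution inside the window the decoy is undefined.
    """
    core = trna_entry.sequence
    if length > len(core):
        raise ValueError("window longer than tRNA core")
    m1a_sites = [i for i, k in trna_ann.modification_sites if k == "m1A"]
    if not m1a_sites:
        raise ValueError("tRNA annotation has no m1A site")
    m1a = m1a_sites[0]
    start = len(core) - length
    if m1a < start:
        raise ValueError(
            f"3' window of {length} nt excludes the m1A index {m1a}; decoy undefined"
        )
    window = list(core[start:])
    window[m1a - start] = "G"
    return MirnaAnnotation(
        entry_id=mirna_id,
        mature_sequence="".join(window),
        parent_trna_id=trna_entry.id,
        offset_from_trna_3p=start,
    )


def trna_his_annotation() -> TrnaAnnotation:
    ann = TrnaAnnotation(
        entry_id=TRNA_HIS_ID,
        has_g_minus1=True,
        has_cca=True,
        modification_sites=((TRNA_HIS_M1G_INDEX, "m1G"), (TRNA_HIS_M1A_INDEX, "m1A")),
        # G(-1) at index 0; m1G37 at index 37; the variable-loop skip makes
        # core index 58 display as A57.
        display_anchors=((0, -1), (37, 37), (58, 57)),
    )
    ann.validate(TRNA_HIS_CORE)
    return ann


def default_reference(pad_len: int = 10) -> tuple[
    PaddedReference, dict[str, TrnaAnnotation], dict[str, MirnaAnnotation]
]:
    """The packaged reference: tRNA-His, its miRNA decoy, background RNAs."""
    trna = ReferenceEntry(TRNA_HIS_ID, TRNA_HIS_CORE, "tRNA")
    t_ann = trna_his_annotation()
    m_ann = derive_mirna_from_trna(trna, t_ann, MIR4454_LENGTH)
    entries = [
        trna,
        ReferenceEntry(MIR4454_ID, m_ann.mature_sequence, "miRNA"),
        *(ReferenceEntry(i, s, c) for i, c, s in BACKGROUND_ENTRIES),
    ]
    ref = build_padded_reference(entries, pad_len=pad_len)
    return ref, {TRNA_HIS_ID: t_ann}, {MIR4454_ID: m_ann}


# ---------------------------------------------------------------------------
# I/O: multi-FASTA (60-column wrap) and the annotation sidecar TSV.

def write_fasta(ref: PaddedReference, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description=e.category)
        for e in ref.entries.values()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: str | os.PathLike, pad_len: int = 10) -> PaddedReference:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        category = parts[1] if len(parts) > 1 and parts[1] in CATEGORIES else "other"
        entries.append(ReferenceEntry(rec.id, str(rec.seq).upper(), category))
    if not entries:
        raise ReferenceError(f"no FASTA records in {path}")
    return build_padded_reference(entries, pad_len=pad_len)


def write_annotation_tsv(
    ref: PaddedReference,
    trna_anns: dict[str, TrnaAnnotation],
    path: str | os.PathLike,
) -> None:
    rows = []
    for e in ref.entries.values():
        ann = trna_anns.get(e.id)
        rows.append(
            {
                "entry_id": e.id,
                "category": e.category,
                "has_g_minus1": bool(ann and ann.has_g_minus1),
                "has_cca": bool(ann and ann.has_cca),
                "mod_sites": ";".join(
                    f"{i}:{k}" for i, k in (ann.modification_sites if ann else ())
                ),
                "display_anchors": ";".join(
                    f"{i}:{v}" for i, v in (ann.display_anchors if ann else ())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | os.PathLike) -> dict[str, TrnaAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    anns: dict[str, TrnaAnnotation] = {}
    for row in df.itertuples(index=False):
        if not (row.has_g_minus1 or row.has_cca or row.mod_sites or row.display_anchors):
            continue
        mods = tuple(
            (int(p.split(":")[0]), p.split(":")[1])
            for p in str(row.mod_sites).split(";")
            if p
        )
        anchors = tuple(
            (int(p.split(":")[0]), int(p.split(":")[1]))
            for p in str(row.display_anchors).split(";")
            if p
        )
        anns[row.entry_id] = TrnaAnnotation(
            entry_id=row.entry_id,
            has_g_minus1=bool(row.has_g_minus1),
            has_cca=bool(row.has_cca),
            modification_sites=mods,
            display_anchors=anchors,
        )
    return anns
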