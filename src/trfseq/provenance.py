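"""Fragment-origin classification and abundance quantification.

An annotated miRNA whose sequence nearly duplicates a tRNA 3' end (here the
miR-4454 decoy vs the tRNA-His 3' window) cannot be told apart by naive
counting. Individual reads can, using three kinds of tRNA-supporting
evidence:

* the read extends 5' of the miRNA annotation and the extension matches
  the tRNA sequence;
* the read carries the tRNA base (A) at the discriminating position where
  the miRNA templates G;
* the read carries T or C there - explainable only by TGIRT
  misincorporation at m1A on the tRNA template, since the miRNA locus
  templates an unmodified G faithfully.

A read showing G at the site, no 5' extension and otherwise consistent
with the decoy is called an annotated-miRNA read; G is the one
non-discriminating observation (an m1A can also be misread as G), so such
calls are only as strong as the decoy model. Reads with no evidence either
way stay ambiguous.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .modification import _base_at
from .reference import MirnaAnnotation, PaddedReference, TrnaAnnotation

VERDICTS = ("trna_3p_fragment", "annotated_mirna", "ambiguous")


class ProvenanceError(ValueError):
    pass


@dataclass(frozen=True)
class ProvenanceCall:
    read_id: str
    verdict: str
    five_prime_beyond_mirna: bool = False
    mismatch_matches_trna: bool = False
    m1a_spectrum_at_site: bool = False
    has_cca: bool = False
    has_nontemplated_5pT: bool = False

    @property
    def score(self) -> int:
        """Number of tRNA-supporting (discriminating) flags."""
        return sum(
            (self.five_prime_beyond_mirna, self.mismatch_matches_trna, self.m1a_spectrum_at_site)
        )


def classify_fragment_provenance(
    read_records: Sequence[AlignmentRecord],
    ref: PaddedReference,
    trna_ann: TrnaAnnotation,
    mirna_ann: MirnaAnnotation,
    max_decoy_mismatches: int = 2,
) -> ProvenanceCall:
    """Classify one read's origin: tRNA 3' fragment vs annotated miRNA.

    ``read_records`` are the read's alignments (to the tRNA, the decoy, or
    both); evidence is evaluated in tRNA coordinates via the tRNA alignment
    when present, else mapped through the decoy offset. With
    ``max_decoy_mismatches=0`` the annotated-miRNA verdict requires a
    mismatch-free decoy alignment.
    """
    if not read_records:
        raise ProvenanceError("read aligns to neither the tRNA nor the decoy")
    trna_id = trna_ann.entry_id
    decoy_id = mirna_ann.entry_id
    by_ref = {r.ref_id: r for r in read_records if r.ref_id in (trna_id, decoy_id)}
    if not by_ref:
        raise ProvenanceError("no alignment to the tRNA or its decoy")
    read_id = read_records[0].read_id
    offset = mirna_ann.offset_from_trna_3p
    site = next(i for i, k in trna_ann.modification_sites if k == "m1A")
    core = ref.core(trna_id)

    trna_rec = by_ref.get(trna_id)
    decoy_rec = by_ref.get(decoy_id)
    if trna_rec is not None:
        start = trna_rec.core_start
        base = _site_base(trna_rec, site)
        anchor = trna_rec
    else:
        start = offset + decoy_rec.core_start
        base = _site_base(decoy_rec, site - offset)
        anchor = decoy_rec

    beyond = False
    if trna_rec is not None and start < offset:
        ext = [_base_at(trna_rec, i) for i in range(start, offset)]
        beyond = all(b == core[i] for b, i in zip(ext, range(start, offset)) if b is not None)
    a_at_site = base == "A"
    tc_at_site = base in ("T", "C")
    n = len(core)
    g = [_base_at(anchor, i) if anchor is trna_rec else None for i in (n - 3, n - 2, n - 1)]
    if anchor is decoy_rec:
        dn = len(ref.core(decoy_id))
        g = [_base_at(decoy_rec, i) for i in (dn - 3, dn - 2, dn - 1)]
    has_cca = g == ["C", "C", "A"]
    nt5pt = anchor.soft5 == 1 and anchor.read_seq[0] == "T"

    if beyond or a_at_site or tc_at_site:
        verdict = "trna_3p_fragment"
    elif base == "G" and not beyond and _decoy_consistent(
        decoy_rec, ref.core(decoy_id), max_decoy_mismatches
    ):
        verdict = "annotated_mirna"
    else:
        verdict = "ambiguous"
    return ProvenanceCall(
        read_id=read_id,
        verdict=verdict,
        five_prime_beyond_mirna=beyond,
        mismatch_matches_trna=a_at_site,
        m1a_spectrum_at_site=tc_at_site,
        has_cca=has_cca,
        has_nontemplated_5pT=nt5pt,
    )


def _site_base(record: AlignmentRecord, site: int) -> str | None:
    """Read base at the discriminating site, in the record's coordinates.

    A fragment starting exactly at the site whose first base was
    misincorporated gets that terminal mismatch soft-clipped by the local
    aligner; the single clipped base immediately 5' of an alignment
    starting at site+1 occupies the site position, so it is recovered here.
    """
    base = _base_at(record, site)
    if base is None and record.core_start == site + 1 and record.soft5 >= 1:
        base = record.read_seq[record.soft5 - 1]
    return base


def _decoy_consistent(
    decoy_rec: AlignmentRecord | None, decoy_core: str, max_mismatches: int
) -> bool:
    if decoy_rec is None:
        return False
    if max_mismatches == 0:
        # strict: perfect full-length decoy match
        return (
            decoy_rec.core_start == 0
            and decoy_rec.core_end == len(decoy_core)
            and not decoy_rec.mismatches
        )
    return len(decoy_rec.mismatches) <= max_mismatches


def classify_library(
    records: Sequence[AlignmentRecord],
    ref: PaddedReference,
    trna_ann: TrnaAnnotation,
    mirna_ann: MirnaAnnotation,
    **kwargs,
) -> list[ProvenanceCall]:
    """Group primary records by read and classify each read."""
    grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
    relevant = (trna_ann.entry_id, mirna_ann.entry_id)
    for r in records:
        if r.ref_id in relevant:
            grouped[r.read_id].append(r)
    return [
        classify_fragment_provenance(recs, ref, trna_ann, mirna_ann, **kwargs)
        for recs in grouped.values()
    ]


def calls_to_frame(calls: Sequence[ProvenanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "verdict": c.verdict,
                "five_prime_beyond_mirna": int(c.five_prime_beyond_mirna),
                "mismatch_matches_trna": int(c.mismatch_matches_trna),
                "m1a_spectrum_at_site": int(c.m1a_spectrum_at_site),
                "has_cca": int(c.has_cca),
                "has_nontemplated_5pT": int(c.has_nontemplated_5pT),
                "score": c.score,
            }
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# Abundance: per-feature counts, RPM normalisation, enrichment.

def feature_counts(records: Sequence[AlignmentRecord]) -> pd.Series:
    """Primary-weighted read count per reference feature."""
    acc: dict[str, float] = defaultdict(float)
    for r in records:
        acc[r.ref_id] += r.weight
    return pd.Series(acc, dtype=float).sort_index()


def trf3p_fragment_count(
    records: Sequence[AlignmentRecord],
    trna_ann: TrnaAnnotation,
    mirna_ann: MirnaAnnotation,
    min_core_start: int = 50,
) -> float:
    """Primary-weighted count of tRNA 3'-fragment reads.

    A read counts when its primary alignment hits the miRNA decoy, or hits
    the tRNA with core_start >= ``min_core_start`` (inside the 3'/TPsiC
    window); RT-stop reads start further 5' and are excluded.
    """
    total = 0.0
    for r in records:
        if r.ref_id == mirna_ann.entry_id:
            total += r.weight
        elif r.ref_id == trna_ann.entry_id and r.core_start >= min_core_start:
            total += r.weight
    return total


def rpm_table(counts_per_sample: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Reads-per-million table: features x samples.

    Each sample's RPM column sums to 1e6 (count * 1e6 / total mapped
    primary weight). Zero totals are an error.
    """
    frames = {}
    for sample, counts in counts_per_sample.items():
        total = float(counts.sum())
        if total <= 0:
            raise ProvenanceError(f"sample {sample!r} has zero mapped reads")
        frames[sample] = counts * 1e6 / total
    return pd.DataFrame(frames).fillna(0.0)


def relative_levels(
    rpm: pd.DataFrame, baseline_samples: Sequence[str]
) -> pd.DataFrame:
    """Per-feature RPM relative to the mean of the baseline samples."""
    base = rpm[list(baseline_samples)].mean(axis=1)
    return rpm.div(base.replace(0.0, np.nan), axis=0)


def fold_change_summary(
    rpm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Mean, SEM and A/B fold change across replicate columns."""
    a, b = rpm[list(group_a)], rpm[list(group_b)]
    out = pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "sem_a": a.sem(axis=1),
            "mean_b": b.mean(axis=1),
            "sem_b": b.sem(axis=1),
        }
    )
    out["fold_change"] = out["mean_a"] / out["mean_b"].replace(0.0, np.nan)
    return out


def enrichment(
    ip_counts: pd.Series,
    control_counts: pd.Series,
    min_fc: float = 4.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Flag features enriched in the pulldown over the control.

    A pseudocount is added to the raw counts before RPM conversion so that
    features absent from one library get a finite fold change; features
    with IP/control RPM fold change >= ``min_fc`` are flagged enriched,
    the rest are background.
    """
    features = sorted(set(ip_counts.index) | set(control_counts.index))
    ip = ip_counts.reindex(features, fill_value=0.0) + pseudocount
    ctl = control_counts.reindex(features, fill_value=0.0) + pseudocount
    ip_rpm = ip * 1e6 / ip.sum()
    ctl_rpm = ctl * 1e6 / ctl.sum()
    fc = ip_rpm / ctl_rpm
    return pd.DataFrame(
        {
            "ip_rpm": ip_rpm,
            "control_rpm": ctl_rpm,
            "fold_change": fc,
            "enriched": fc >= min_fc,
        }
    )
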