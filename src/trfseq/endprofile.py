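"""Read end-position profiles, full-length quantification, Dicer cut calls.

The Dicer assay analysis looks at where reads END rather than at read
lengths, which is robust to RT stops and incomplete chemical synthesis: a
mock-treated library of an intact tRNA has nearly all 3' ends at the
terminal CCA base, while endonucleolytic cuts create discrete new 3'-end
peaks. Comparing a Dicer-treated profile against mock yields cut-site
calls; comparing 5'P against 5'Pme2 substrates classifies each cut's
sensitivity to 5' phospho-methylation.

Full-length molecules are quantified as primary-weighted reads whose
aligned core span is at least ``min_span_nt`` (default 74, i.e. ">73 nt")
among reads mapped to the entry. The packaged workflow feeds the >50 nt
length partition to these functions so that short cleavage products and
RT-stop reads do not inflate the denominator; under that convention the
treated/mock full-length ratio estimates 1 - c for per-molecule cleavage
probability c.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .reference import TrnaAnnotation, to_display_position

WHICH_ENDS = ("three_prime", "five_prime")


class ProfileError(ValueError):
    pass


@dataclass
class EndProfile:
    ref_id: str
    which_end: str
    counts: dict[int, float]
    n_reads: float

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_reads == 0:
            return {}
        return {i: c / self.n_reads for i, c in self.counts.items()}

    def fraction_at(self, core_index: int) -> float:
        return self.fractions.get(core_index, 0.0)


def end_distribution(
    records: Sequence[AlignmentRecord], ref_id: str, which_end: str = "three_prime"
) -> EndProfile:
    """Primary-weighted distribution of aligned read end positions.

    Soft-clipped and pad-aligned bases never move the end: the 3' end is the
    last core-aligned position (core_end - 1), the 5' end the first
    (core_start). Zero reads yield an empty profile, not an error.
    """
    if which_end not in WHICH_ENDS:
        raise ProfileError(f"which_end must be one of {WHICH_ENDS}")
    counts: dict[int, float] = {}
    total = 0.0
    for r in records:
        if r.ref_id != ref_id:
            continue
        pos = r.core_end - 1 if which_end == "three_prime" else r.core_start
        counts[pos] = counts.get(pos, 0.0) + r.weight
        total += r.weight
    return EndProfile(ref_id=ref_id, which_end=which_end, counts=counts, n_reads=total)


def profile_to_frame(
    profile: EndProfile, mock: EndProfile | None = None, ann: TrnaAnnotation | None = None
) -> pd.DataFrame:
    idx = sorted(set(profile.counts) | set(mock.counts if mock else ()))
    rows = []
    for i in idx:
        row = {
            "core_index": i,
            "display_position": to_display_position(ann, i) if ann else str(i),
            "count": profile.counts.get(i, 0.0),
            "fraction": profile.fraction_at(i),
        }
        if mock is not None:
            row["mock_fraction"] = mock.fraction_at(i)
            row["delta"] = row["fraction"] - row["mock_fraction"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FullLengthStat:
    min_span_nt: int
    treated_fractions: list[float]
    mock_fractions: list[float]
    ratios: list[float]
    mock_ratios: list[float]
    ratio_mean: float
    ratio_sd: float
    test_p: float | None


def _full_fraction(records: Sequence[AlignmentRecord], ref_id: str, min_span: int) -> float:
    num = den = 0.0
    for r in records:
        if r.ref_id != ref_id:
            continue
        den += r.weight
        if r.core_span_nt >= min_span:
            num += r.weight
    if den == 0:
        raise ProfileError(f"no reads mapped to {ref_id}")
    return num / den


def full_length_ratio(
    treated_reps: Sequence[Sequence[AlignmentRecord]],
    mock_reps: Sequence[Sequence[AlignmentRecord]],
    ref_id: str,
    min_span_nt: int = 74,
) -> FullLengthStat:
    """Per-replicate full-length fraction, normalised to the mean mock.

    With >=2 replicates per condition a two-tailed Welch t-test compares the
    treated and mock per-replicate ratios.
    """
    if min_span_nt < 1:
        raise ProfileError("min_span_nt must be >= 1")
    if not treated_reps or not mock_reps:
        raise ProfileError("need at least one replicate per condition")
    treated_fracs = [_full_fraction(r, ref_id, min_span_nt) for r in treated_reps]
    mock_fracs = [_full_fraction(r, ref_id, min_span_nt) for r in mock_reps]
    mock_mean = float(np.mean(mock_fracs))
    if mock_mean == 0:
        raise ProfileError("mock full-length fraction is zero; ratio undefined")
    ratios = [f / mock_mean for f in treated_fracs]
    mock_ratios = [f / mock_mean for f in mock_fracs]
    p = None
    if len(ratios) >= 2 and len(mock_ratios) >= 2:
        p = float(stats.ttest_ind(ratios, mock_ratios, equal_var=False).pvalue)
    return FullLengthStat(
        min_span_nt=min_span_nt,
        treated_fractions=treated_fracs,
        mock_fractions=mock_fracs,
        ratios=ratios,
        mock_ratios=mock_ratios,
        ratio_mean=float(np.mean(ratios)),
        ratio_sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
        test_p=p,
    )


def welch_p(ratios_a: Sequence[float], ratios_b: Sequence[float]) -> float:
    """Two-tailed Welch t-test between two sets of per-replicate ratios."""
    return float(stats.ttest_ind(list(ratios_a), list(ratios_b), equal_var=False).pvalue)


@dataclass
class CutSiteCall:
    cut_after_core_index: int
    treated_fraction: float
    mock_fraction: float
    is_called: bool = True
    methyl_ratio: float | None = None
    methyl_class: str | None = None

    @property
    def delta(self) -> float:
        return self.treated_fraction - self.mock_fraction


def call_cut_sites(
    treated: EndProfile,
    mock: EndProfile,
    min_delta: float = 0.01,
    min_frac: float = 0.02,
) -> list[CutSiteCall]:
    """Call cut sites as treated-over-mock excesses of read ends.

    A position is a candidate when its treated fraction exceeds mock by at
    least ``min_delta`` and reaches ``min_frac``; runs of adjacent candidate
    indices merge into a single call at the local delta maximum. For 3'-end
    profiles the reported index is the 5' product's last base, i.e. the
    position the endonuclease cut after.
    """
    if treated.ref_id != mock.ref_id or treated.which_end != mock.which_end:
        raise ProfileError("treated and mock profiles must share ref and end type")
    tf, mf = treated.fractions, mock.fractions
    cand = sorted(
        i
        for i in tf
        if tf[i] - mf.get(i, 0.0) >= min_delta and tf[i] >= min_frac
    )
    calls: list[CutSiteCall] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        best = max(run, key=lambda i: (tf[i] - mf.get(i, 0.0), -i))
        calls.append(
            CutSiteCall(
                cut_after_core_index=best,
                treated_fraction=tf[best],
                mock_fraction=mf.get(best, 0.0),
            )
        )

    for i in cand:
        if run and i == run[-1] + 1:
            run.append(i)
        else:
            flush()
            run = [i]
    flush()
    return calls


def methylation_sensitivity(
    calls_5p: Sequence[CutSiteCall],
    calls_5pme2: Sequence[CutSiteCall],
    sensitive_max: float = 0.5,
    insensitive_min: float = 0.8,
) -> list[CutSiteCall]:
    """Classify each cut site's response to 5' phospho-methylation.

    methyl_ratio = delta(Pme2) / delta(P) per matched site (exact index,
    else +-1): <= sensitive_max -> "sensitive", >= insensitive_min ->
    "insensitive", between -> "indeterminate". Sites present in only one
    call set are reported as indeterminate.
    """
    me2_by_idx = {c.cut_after_core_index: c for c in calls_5pme2}
    out: list[CutSiteCall] = []
    matched_me2: set[int] = set()
    for c in calls_5p:
        partner = me2_by_idx.get(c.cut_after_core_index)
        if partner is None:
            for off in (-1, 1):
                partner = me2_by_idx.get(c.cut_after_core_index + off)
                if partner is not None:
                    break
        if partner is None or c.delta <= 0:
            out.append(replace(c, methyl_ratio=None, methyl_class="indeterminate"))
            continue
        matched_me2.add(partner.cut_after_core_index)
        ratio = partner.delta / c.delta
        if ratio <= sensitive_max:
            cls = "sensitive"
        elif ratio >= insensitive_min:
            cls = "insensitive"
        else:
            cls = "indeterminate"
        out.append(replace(c, methyl_ratio=ratio, methyl_class=cls))
    for c in calls_5pme2:
        if c.cut_after_core_index not in matched_me2:
            out.append(replace(c, methyl_ratio=None, methyl_class="indeterminate"))
    return out


def calls_to_frame(calls: Sequence[CutSiteCall], ann: TrnaAnnotation | None = None) -> pd.DataFrame:
    rows = [
        {
            "core_index": c.cut_after_core_index,
            "display_position": (
                to_display_position(ann, c.cut_after_core_index) if ann else str(c.cut_after_core_index)
            ),
            "fraction": c.treated_fraction,
            "mock_fraction": c.mock_fraction,
            "delta": c.delta,
            "methyl_ratio": c.methyl_ratio,
            "class": c.methyl_class,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
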