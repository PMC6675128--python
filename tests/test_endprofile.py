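"""End profiles, full-length quantification, cut-site calling & methyl classes."""

import numpy as np
import pytest

from trfseq import align as al
from trfseq import endprofile as ep
from trfseq import reference as rf
from conftest import make_library
from test_align import stub

TRNA = rf.TRNA_HIS_ID
C_TOTAL = 0.54  # default per-molecule cleavage probability, 5'P substrate


def long_partition(lib):
    return al.partition_by_length(lib[0])[0]


class TestEndDistribution:
    def test_weighted_fractions(self):
        recs = [stub(read_id=str(i), start=0, end=76, weight=1.0) for i in range(9)]
        recs.append(stub(read_id="x", start=0, end=58))
        prof = ep.end_distribution(recs, TRNA)
        assert prof.fraction_at(75) == pytest.approx(0.9)
        assert prof.fraction_at(57) == pytest.approx(0.1)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_mock_terminal_three_prime_dominates(self, mock_lib):
        prof = ep.end_distribution(long_partition(mock_lib), TRNA)
        assert prof.fraction_at(75) >= 0.90

    def test_soft_clipped_t_does_not_move_five_prime_end(self, ref):
        read = "T" + rf.TRNA_HIS_CORE[:20]
        recs = al.select_primary(al.align_read(read, ref))
        prof = ep.end_distribution(recs, TRNA, "five_prime")
        assert prof.fraction_at(0) == 1.0

    def test_zero_reads_is_empty_not_error(self):
        prof = ep.end_distribution([], TRNA)
        assert prof.n_reads == 0 and prof.fractions == {}

    def test_weight_conservation_across_partitions(self, mock_lib):
        records = mock_lib[0]
        long, short = al.partition_by_length(records)
        total = ep.end_distribution(records, TRNA).n_reads
        assert total == pytest.approx(
            ep.end_distribution(long, TRNA).n_reads
            + ep.end_distribution(short, TRNA).n_reads
        )


class TestFullLength:
    def test_self_ratio_is_one(self, mock_lib):
        long = long_partition(mock_lib)
        stat = ep.full_length_ratio([long], [long], TRNA)
        assert stat.ratio_mean == pytest.approx(1.0)

    def test_ratio_recovers_one_minus_cleavage_probability(self, mock_lib, dicer_5p_lib):
        stat = ep.full_length_ratio(
            [long_partition(dicer_5p_lib)], [long_partition(mock_lib)], TRNA
        )
        n = len(long_partition(dicer_5p_lib))
        se = np.sqrt(C_TOTAL * (1 - C_TOTAL) / n)
        assert abs(stat.ratio_mean - (1 - C_TOTAL)) < 3 * se + 0.01

    def test_monotone_in_cleavage_probability(self, ref, mock_lib):
        from dataclasses import replace
        from trfseq import simulate as sim

        mock_long = long_partition(mock_lib)
        ratios = []
        for k, c in enumerate((0.1, 0.3, 0.5, 0.7)):
            scale = c / 0.54
            cuts = sim.CutModel(
                tuple(
                    replace(s, base_probability=s.base_probability * scale)
                    for s in sim.DEFAULT_CUT_MODEL.sites
                )
            )
            lib = make_library("dicer_5p", 2500, 40 + k, ref, cut_model=cuts)
            stat = ep.full_length_ratio([long_partition(lib)], [mock_long], TRNA)
            ratios.append(stat.ratio_mean)
        assert ratios == sorted(ratios, reverse=True)

    def test_zero_mock_fraction_is_error(self):
        short = [stub(read_id="a", start=58, end=76, seq="A" * 51)]
        with pytest.raises(ep.ProfileError):
            ep.full_length_ratio([short], [short], TRNA)

    def test_welch_p_with_replicates(self, mock_lib, dicer_5p_lib):
        m = long_partition(mock_lib)
        d = long_partition(dicer_5p_lib)
        half = len(m) // 2
        stat = ep.full_length_ratio(
            [d[: len(d) // 2], d[len(d) // 2 :]], [m[:half], m[half:]], TRNA
        )
        assert stat.test_p is not None and stat.test_p < 0.05


class TestCutSites:
    def test_identical_profiles_yield_no_calls(self, mock_lib):
        prof = ep.end_distribution(long_partition(mock_lib), TRNA)
        assert ep.call_cut_sites(prof, prof) == []

    def test_default_simulation_recovers_planted_sites(self, mock_lib, dicer_5p_lib):
        treated = ep.end_distribution(long_partition(dicer_5p_lib), TRNA)
        mock = ep.end_distribution(long_partition(mock_lib), TRNA)
        calls = ep.call_cut_sites(treated, mock)
        assert [c.cut_after_core_index for c in calls] == [54, 57, 60]

    def test_adjacent_candidates_merge_to_local_maximum(self):
        treated = ep.EndProfile(TRNA, "three_prime", {54: 30.0, 55: 60.0, 70: 910.0}, 1000.0)
        mock = ep.EndProfile(TRNA, "three_prime", {70: 1000.0}, 1000.0)
        calls = ep.call_cut_sites(treated, mock)
        assert [c.cut_after_core_index for c in calls] == [55]

    def test_18mer_fragments_imply_cut_after_57(self):
        # an 18-nt 3' product population leaves 5' products ending at 57
        treated = ep.EndProfile(TRNA, "three_prime", {57: 300.0, 75: 700.0}, 1000.0)
        mock = ep.EndProfile(TRNA, "three_prime", {75: 1000.0}, 1000.0)
        (call,) = ep.call_cut_sites(treated, mock)
        assert call.cut_after_core_index == 57 == 76 - 18 - 1

    def test_mismatched_profiles_rejected(self, mock_lib):
        p3 = ep.end_distribution(long_partition(mock_lib), TRNA, "three_prime")
        p5 = ep.end_distribution(long_partition(mock_lib), TRNA, "five_prime")
        with pytest.raises(ep.ProfileError):
            ep.call_cut_sites(p3, p5)


class TestMethylationSensitivity:
    def test_identical_deltas_are_insensitive(self):
        calls = [ep.CutSiteCall(57, 0.2, 0.0)]
        out = ep.methylation_sensitivity(calls, calls)
        assert out[0].methyl_ratio == pytest.approx(1.0)
        assert out[0].methyl_class == "insensitive"

    def test_simulated_classes_stem_sensitive_loop_insensitive(
        self, mock_lib, dicer_5p_lib, dicer_5pme2_lib
    ):
        mock = ep.end_distribution(long_partition(mock_lib), TRNA)
        c5p = ep.call_cut_sites(ep.end_distribution(long_partition(dicer_5p_lib), TRNA), mock)
        cme2 = ep.call_cut_sites(
            ep.end_distribution(long_partition(dicer_5pme2_lib), TRNA), mock
        )
        classes = {
            c.cut_after_core_index: c.methyl_class
            for c in ep.methylation_sensitivity(c5p, cme2)
        }
        assert classes == {54: "sensitive", 57: "sensitive", 60: "insensitive"}

    def test_unmatched_site_is_indeterminate(self):
        out = ep.methylation_sensitivity([ep.CutSiteCall(57, 0.2, 0.0)], [])
        assert out[0].methyl_class == "indeterminate"
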