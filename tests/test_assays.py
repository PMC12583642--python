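"""Assay arithmetic, double normalisation and the combined locus summary."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpcrkit import (
    AssayPanelConfig,
    ConfigurationError,
    InputError,
    aneuploidy_summary,
    combine_summary,
    double_normalise,
    edge_summary,
    flanking_summary,
    ti_summary,
)
from dpcrkit.assays import (
    AssayEntry,
    edge_from_fractions,
    flanking_from_fractions,
)

from conftest import expected_count_well


class TestDoubleNormalise:
    def test_mock_against_itself_is_unity(self):
        nf = double_normalise(9000, [9000, 9000], 9000, [9000, 9000])
        assert nf.value == pytest.approx(1.0)

    def test_reference_and_mock_ratios_combine(self):
        nf = double_normalise(4000, [8000, 8000], 9000, [9000, 9000])
        assert nf.value == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "assay,refs,mock,mock_refs",
        [
            (100, [], 100, [100]),
            (100, [100], 0, [100]),
            (100, [0], 100, [100]),
            (-5, [100], 100, [100]),
        ],
    )
    def test_degenerate_inputs_rejected(self, assay, refs, mock, mock_refs):
        with pytest.raises(InputError):
            double_normalise(assay, refs, mock, mock_refs)

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        assay=st.floats(min_value=0.0, max_value=5e4),
        ref=st.floats(min_value=10.0, max_value=5e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, scale, assay, ref):
        """Multiplying every copy number in a sample by a constant leaves
        the normalised fraction unchanged (ratios are volume-invariant)."""
        base = double_normalise(assay, [ref], 9000, [9100]).value
        scaled = double_normalise(
            assay * scale, [ref * scale], 9000, [9100]
        ).value
        assert scaled == pytest.approx(base, rel=1e-9)


class TestEdgeAssay:
    def test_fraction_arithmetic(self):
        out = edge_from_fractions(0.30, 0.80)
        assert out["wt"] == pytest.approx(30.0)
        assert out["indel"] == pytest.approx(50.0)
        assert out["other"] == pytest.approx(20.0)

    def test_mock_vs_mock_is_pure_wildtype(self):
        lam = 0.5
        mock_edge = expected_count_well(lam, 0.0, 0.0)
        ref = expected_count_well(0.0, lam, 0.0)
        out = edge_summary(mock_edge, [ref], mock_edge, [ref])
        assert out["wt"] == pytest.approx(100.0, abs=1e-9)
        assert out["indel"] == pytest.approx(0.0, abs=1e-9)
        assert out["other"] == pytest.approx(0.0, abs=1e-9)

    def test_expected_count_mixture(self):
        """wt 15% / indel 40% / ablated 45% at the locus, from exact
        expected droplet counts."""
        lam = 0.6
        edge = expected_count_well(0.15 * lam, 0.0, 0.40 * lam)
        ref = expected_count_well(0.0, lam, 0.0)
        mock_edge = expected_count_well(lam, 0.0, 0.0)
        out = edge_summary(edge, [ref], mock_edge, [ref])
        assert out["wt"] == pytest.approx(15.0, abs=1e-9)
        assert out["indel"] == pytest.approx(40.0, abs=1e-9)
        assert out["other"] == pytest.approx(45.0, abs=1e-9)


class TestFlankingAssay:
    def test_fraction_arithmetic_mean_rule(self):
        out = flanking_from_fractions(0.90, 0.85, 0.60, "mean")
        assert out["trim5"] == pytest.approx(10.0)
        assert out["trim3"] == pytest.approx(15.0)
        assert out["dsb"] == pytest.approx(27.5)

    def test_fraction_arithmetic_copresent_rule(self):
        # both-sides-present fraction = f5 + f3 - 1
        out = flanking_from_fractions(0.90, 1.00, 0.65, "copresent")
        assert out["dsb"] == pytest.approx(25.0)

    def test_unedited_mock_fully_linked(self):
        lam = 0.5
        mock = expected_count_well(lam, 0.0, 0.0)
        ref = expected_count_well(0.0, lam, 0.0)
        out = flanking_summary(mock, mock, [ref], mock, mock, [ref])
        assert out["trim5"] == pytest.approx(0.0, abs=1e-9)
        assert out["trim3"] == pytest.approx(0.0, abs=1e-9)
        assert out["dsb"] == pytest.approx(0.0, abs=1e-9)
        assert out["linked"] == pytest.approx(100.0, abs=1e-9)

    def test_dsb_and_one_sided_deletion_mixture(self):
        """25% unresolved DSBs + 10% 5'-side large deletions from exact
        expected counts: the co-presence statistic is unbiased."""
        lam = 0.5
        dsb, ld5 = 0.25, 0.10
        intact = 1 - dsb - ld5
        flank = expected_count_well(intact * lam, dsb * lam, (dsb + ld5) * lam)
        ref = expected_count_well(0.0, lam, 0.0)
        mock = expected_count_well(lam, 0.0, 0.0)
        out = flanking_summary(flank, flank, [ref], mock, mock, [ref])
        assert out["dsb"] == pytest.approx(25.0, abs=1e-6)
        assert out["trim5"] == pytest.approx(10.0, abs=1e-6)
        assert out["trim3"] == pytest.approx(0.0, abs=1e-6)

    def test_split_wells_cannot_give_dsb(self):
        lam = 0.5
        a = expected_count_well(lam, 0, 0, well_id="w1")
        b = expected_count_well(lam, 0, 0, well_id="w2")
        ref = expected_count_well(0.0, lam, 0.0)
        with pytest.raises(ConfigurationError):
            flanking_summary(a, b, [ref], a, a, [ref])


class TestAneuploidyAssay:
    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (0.95, -5.0),
                                                 (0.90, -10.0), (1.08, 8.0)])
    def test_signed_arm_change(self, factor, expected):
        lam = 0.5
        aneu = expected_count_well(0.0, factor * lam, factor * lam)
        mock = expected_count_well(0.0, lam, lam)
        ref = expected_count_well(0.0, lam, 0.0)
        out = aneuploidy_summary(aneu, [ref], mock, [ref])
        assert out["aneu_p_change"] == pytest.approx(expected, abs=1e-6)
        assert out["aneu_q_change"] == pytest.approx(expected, abs=1e-6)


class TestTiAssay:
    def test_junction_over_locus_copies(self):
        n = 1e6
        ref = expected_count_well(0.0, 1000 / n, 0.0, n_total=n)
        ti = expected_count_well(0.0, 530 / n, 0.0, n_total=n)
        donor = expected_count_well(0.0, 50000 / n, 0.0, n_total=n)
        out = ti_summary(ti, donor, [ref], ploidy=2)
        assert out["targeted_integration"] == pytest.approx(53.0, rel=1e-6)
        assert out["vcn"] == pytest.approx(100.0, rel=1e-6)
        # nearly all donor copies are episomal, not integrated
        assert out["episomal_copies"] / 50000 > 0.98

    def test_equal_digested_vcn_means_no_concatemers(self):
        n = 1e6
        ref = expected_count_well(0.0, 1000 / n, 0.0, n_total=n)
        ti = expected_count_well(0.0, 100 / n, 0.0, n_total=n)
        donor = expected_count_well(0.0, 2000 / n, 0.0, n_total=n)
        out = ti_summary(ti, donor, [ref], ploidy=2, digested_donor_well=donor)
        assert out["concatemer_ratio"] == pytest.approx(1.0, rel=1e-9)


class TestCombineSummary:
    def test_disjoint_stacking(self):
        edge = {"wt": 15.0, "indel": 40.0, "other": 45.0}
        flanking = {"trim5": 10.0, "trim3": 0.0, "dsb": 25.0, "linked": 65.0}
        s = combine_summary(edge, flanking, sample_id="s1", distance_bp=120)
        assert s.large_del == pytest.approx(10.0)
        assert s.other_aberration == pytest.approx(10.0)
        assert s.total == pytest.approx(100.0)
        assert not s.flag

    def test_mock_is_all_wildtype(self):
        edge = {"wt": 100.0, "indel": 0.0, "other": 0.0}
        flanking = {"trim5": 0.0, "trim3": 0.0, "dsb": 0.0, "linked": 100.0}
        s = combine_summary(edge, flanking, sample_id="mock", distance_bp=120)
        assert s.wt == 100.0
        assert s.indel == s.large_del == s.dsb == s.other_aberration == 0.0

    def test_short_distance_assay_reports_trimming_not_large_deletion(self):
        edge = {"wt": 80.0, "indel": 10.0, "other": 10.0}
        flanking = {"trim5": 5.0, "trim3": 2.0, "dsb": 3.0, "linked": 90.0}
        s = combine_summary(edge, flanking, sample_id="s1", distance_bp=20)
        assert s.large_del == 0.0
        assert s.trim5 == pytest.approx(5.0)

    def test_overlap_clamp_never_negative(self):
        edge = {"wt": 80.0, "indel": 10.0, "other": 5.0}
        flanking = {"trim5": 4.0, "trim3": 1.0, "dsb": 4.0, "linked": 91.0}
        s = combine_summary(edge, flanking, sample_id="s1", distance_bp=120)
        assert s.other_aberration == 0.0

    def test_out_of_range_total_flagged(self):
        edge = {"wt": 60.0, "indel": 10.0, "other": 5.0}
        s = combine_summary(edge, None, sample_id="s1")
        assert s.flag


class TestPanelValidation:
    def test_reference_required(self):
        with pytest.raises(ConfigurationError):
            AssayPanelConfig(
                locus="L",
                assays=[AssayEntry("e", "edge",
                                   {"fam": "cleavage", "hex": "distal"})],
            )

    def test_edge_needs_both_channels(self):
        with pytest.raises(ConfigurationError):
            AssayPanelConfig(
                locus="L",
                assays=[
                    AssayEntry("e", "edge", {"fam": "cleavage"}),
                    AssayEntry("r", "reference", {"fam": "ref"}),
                ],
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(ConfigurationError):
            AssayEntry("x", "mystery", {})


def test_noiseless_conservation_through_full_arithmetic():
    """For a representable mixture on exact expected counts, the stacked
    classes sum to 100 to numerical precision."""
    lam = 0.5
    wt, indel, ld5, dsb, other = 0.15, 0.40, 0.10, 0.25, 0.10
    n = 1e7
    edge = expected_count_well(wt * lam, 0.0, indel * lam, n_total=n)
    intact = wt + indel + other
    flank = expected_count_well(
        intact * lam, (dsb) * lam, (dsb + ld5) * lam, n_total=n
    )
    ref = expected_count_well(0.0, lam, 0.0, n_total=n)
    mock_edge = expected_count_well(lam, 0.0, 0.0, n_total=n)
    e = edge_summary(edge, [ref], mock_edge, [ref])
    f = flanking_summary(flank, flank, [ref], mock_edge, mock_edge, [ref])
    s = combine_summary(e, f, sample_id="s", distance_bp=120)
    assert abs(s.total - 100.0) < 1e-6
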