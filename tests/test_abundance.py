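"""Normalization, master-protein selection, phospho grouping and adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hnsomics.abundance import (
    AnnotationScore,
    PhosphopeptideRecord,
    adjust_phosphopeptides,
    annotation_score,
    compute_normalization_factors,
    group_phosphopeptides,
    groups_to_matrix,
    normalize_log2,
    select_master_protein,
)
from hnsomics.core_io import AbundanceMatrix, ValidationError


def raw_matrix(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=features, columns=samples), scale="raw")


class TestNormalizationFactors:
    def test_two_sample_worked_example(self):
        m = raw_matrix([[100, 200]], samples=["A", "B"])
        f = compute_normalization_factors(m)
        assert f["A"] == 1.5 and f["B"] == 0.75

    def test_equal_totals_give_unit_factors(self):
        m = raw_matrix([[50, 50], [50, 50]])
        f = compute_normalization_factors(m)
        assert all(v == 1.0 for v in f.factors.values())

    def test_four_sample_worked_example_and_postcondition(self):
        m = raw_matrix([[100, 100, 100, 500]])
        f = compute_normalization_factors(m)
        assert list(f.factors.values()) == [2.0, 2.0, 2.0, 0.4]
        scaled_totals = m.data.sum(axis=0) * pd.Series(f.factors)
        assert np.allclose(scaled_totals, 200.0, rtol=1e-9)

    def test_zero_total_names_sample(self):
        m = raw_matrix([[1, 0]], samples=["ok", "dead"])
        with pytest.raises(ValidationError, match="dead"):
            compute_normalization_factors(m)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scaled_totals_equal_property(self, seed):
        rng = np.random.default_rng(seed)
        m = raw_matrix(rng.lognormal(8, 2, size=(30, 6)))
        f = compute_normalization_factors(m)
        scaled = m.data.to_numpy() * np.array([f[s] for s in m.sample_ids])
        totals = scaled.sum(axis=0)
        assert np.allclose(totals, totals[0], rtol=1e-9)


class TestNormalizeLog2:
    def test_simple_values(self):
        m = raw_matrix([[4.0, 0.0], [100.0, 8.0]], samples=["A", "B"])
        f = compute_normalization_factors(raw_matrix([[1.0, 1.0]], samples=["A", "B"]))
        out = normalize_log2(m, f)
        assert out.scale == "log2"
        assert out.data.loc["F0", "A"] == 2.0
        assert np.isnan(out.data.loc["F0", "B"])  # raw zero -> missing

    def test_factor_applied_before_log(self):
        m = raw_matrix([[100.0]], samples=["A"])
        f = compute_normalization_factors(m)
        f.factors["A"] = 1.5
        out = normalize_log2(m, f)
        assert out.data.loc["F0", "A"] == pytest.approx(np.log2(150.0), abs=1e-12)

    def test_missing_factor_rejected(self):
        m = raw_matrix([[1.0, 2.0]], samples=["A", "B"])
        f = compute_normalization_factors(m)
        del f.factors["B"]
        with pytest.raises(ValidationError, match="B"):
            normalize_log2(m, f)


class TestMasterProtein:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([("P1", 3), ("P2", 5)], "P2"),
            ([("P9", 2), ("P2", 2)], "P2"),  # tie -> lexicographically smallest
            ([("Q1", 0)], "Q1"),
        ],
    )
    def test_selection_rule(self, scores, expected):
        group = [AnnotationScore(a, s) for a, s in scores]
        assert select_master_protein(group) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            select_master_protein([])

    def test_annotation_score_counts_populated_fields(self):
        assert annotation_score("P1", "Avp", None, "vasopressin").score == 2


def psm(psm_id, seq, acc, sites, conf, values, samples=("s1", "s2")):
    return PhosphopeptideRecord(
        psm_id, seq, acc, tuple(sites), conf,
        pd.Series(np.asarray(values, dtype=float), index=list(samples)),
    )


class TestGrouping:
    def test_same_sequence_site_high_confidence_summed(self):
        recs = [
            psm("a", "AKSLR", "P1", [("S", 3)], 90, [10, 20]),
            psm("b", "AKSLR", "P1", [("S", 3)], 85, [1, 2]),
        ]
        groups = group_phosphopeptides(recs)
        assert len(groups) == 1
        g = groups[0]
        assert g.localized and g.n_psms == 2
        assert list(g.abundances) == [11.0, 22.0]

    def test_confidence_70_is_not_localized(self):
        groups = group_phosphopeptides([psm("a", "AKSLR", "P1", [("S", 3)], 70, [1, 1])])
        assert not groups[0].localized
        assert groups[0].group_key == ("AKSLR", 1)

    def test_distinct_sites_distinct_groups(self):
        recs = [
            psm("a", "ASTSR", "P1", [("S", 2)], 90, [1, 1]),
            psm("b", "ASTSR", "P1", [("S", 4)], 95, [1, 1]),
        ]
        assert len(group_phosphopeptides(recs)) == 2

    def test_localized_and_unlocalized_do_not_mix(self):
        recs = [
            psm("a", "ASTSR", "P1", [("S", 2)], 90, [1, 1]),
            psm("b", "ASTSR", "P1", [("S", 2)], 50, [1, 1]),
        ]
        groups = group_phosphopeptides(recs)
        assert len(groups) == 2
        assert sorted(g.localized for g in groups) == [False, True]

    def test_conflicting_parent_rejected(self):
        recs = [
            psm("a", "AKSLR", "P1", [("S", 3)], 90, [1, 1]),
            psm("b", "AKSLR", "P2", [("S", 3)], 90, [1, 1]),
        ]
        with pytest.raises(ValidationError, match="conflicting"):
            group_phosphopeptides(recs)

    def test_missing_values_propagate_through_sum(self):
        recs = [
            psm("a", "AKSLR", "P1", [("S", 3)], 90, [np.nan, 2]),
            psm("b", "AKSLR", "P1", [("S", 3)], 90, [np.nan, 3]),
        ]
        g = group_phosphopeptides(recs)[0]
        assert np.isnan(g.abundances.iloc[0]) and g.abundances.iloc[1] == 5.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_grouping_conserves_per_sample_signal(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["AKSLR", "TTSPR", "GGSYK"]
        recs = []
        for i in range(30):
            seq = seqs[rng.integers(0, 3)]
            offs = [j + 1 for j, ch in enumerate(seq) if ch in "STY"]
            off = int(rng.choice(offs))
            recs.append(
                psm(f"p{i}", seq, f"A_{seq}", [(seq[off - 1], off)],
                    float(rng.uniform(40, 100)), rng.lognormal(3, 1, size=2))
            )
        groups = group_phosphopeptides(recs)
        total_in = sum(r.abundances for r in recs)
        total_out = sum(g.abundances for g in groups)
        assert np.allclose(total_in, total_out, rtol=1e-12)
        assert sum(g.n_psms for g in groups) == len(recs)


class TestAdjustment:
    def two_tables(self):
        samples = ["c1", "c2", "w1", "w2"]
        prot = AbundanceMatrix(
            pd.DataFrame([[4.5, 4.5, 4.5, 4.5]], index=["P1"], columns=samples), scale="log2"
        )
        ph = AbundanceMatrix(
            pd.DataFrame([[6.0, 6.0, 6.0, 6.0]], index=["pep1"], columns=samples), scale="log2"
        )
        return ph, prot, {"pep1": "P1"}

    def test_simple_subtraction(self):
        ph, prot, parent = self.two_tables()
        adj, flagged = adjust_phosphopeptides(ph, prot, parent)
        assert adj.scale == "log2_adjusted"
        assert (adj.data.loc["pep1"] == 1.5).all()
        assert flagged == []

    def test_missing_protein_value_propagates(self):
        ph, prot, parent = self.two_tables()
        prot.data.loc["P1", "c1"] = np.nan
        adj, _ = adjust_phosphopeptides(ph, prot, parent)
        assert np.isnan(adj.data.loc["pep1", "c1"])
        assert adj.data.loc["pep1", "c2"] == 1.5

    def test_absent_parent_passthrough_flagged(self):
        ph, prot, _ = self.two_tables()
        adj, flagged = adjust_phosphopeptides(ph, prot, {"pep1": "P_UNKNOWN"})
        assert flagged == ["pep1"]
        assert (adj.data.loc["pep1"] == 6.0).all()

    def test_sample_mismatch_rejected(self):
        ph, prot, parent = self.two_tables()
        prot2 = AbundanceMatrix(prot.data.rename(columns={"c1": "other"}), scale="log2")
        with pytest.raises(ValidationError, match="sample"):
            adjust_phosphopeptides(ph, prot2, parent)

    def test_constant_shift_cancels(self):
        # a protein-level shift mirrored in its peptides leaves adjusted values unchanged
        ph, prot, parent = self.two_tables()
        base, _ = adjust_phosphopeptides(ph, prot, parent)
        shift = pd.Series([0.0, 0.0, 1.0, 1.0], index=prot.sample_ids)
        prot_s = AbundanceMatrix(prot.data.add(shift, axis=1), scale="log2")
        ph_s = AbundanceMatrix(ph.data.add(shift, axis=1), scale="log2")
        shifted, _ = adjust_phosphopeptides(ph_s, prot_s, parent)
        pd.testing.assert_frame_equal(shifted.data, base.data)

    def test_requires_log2_scales(self):
        ph, prot, parent = self.two_tables()
        raw = AbundanceMatrix(2 ** prot.data, scale="raw")
        with pytest.raises(ValidationError, match="log2"):
            adjust_phosphopeptides(ph, raw, parent)


def test_groups_to_matrix_shape_and_keys():
    recs = [
        psm("a", "AKSLR", "P1", [("S", 3)], 90, [1, 2]),
        psm("b", "TTSPR", "P2", [("T", 1)], 50, [3, 4]),
    ]
    groups = group_phosphopeptides(recs)
    m = groups_to_matrix(groups, ["s1", "s2"])
    assert m.scale == "raw"
    assert set(m.feature_ids) == {"AKSLR|S3", "TTSPR|1p"}
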