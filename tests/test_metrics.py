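"""Compositional core and per-sample accuracy metrics.

The CLR / multiplicative-replacement / Aitchison-distance implementation
is cross-checked against scikit-bio (independent implementation of the
same transforms) and against direct formula evaluation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.composition import clr as skbio_clr
from skbio.stats.composition import multi_replace as skbio_multi_replace

from taxabench import (
    DegenerateInputError,
    ExpectedComposition,
    TaxonRecord,
    ValidationError,
    aitchison_distance,
    clr,
    closure,
    evaluate_sample,
    filter_low_fp,
    fpra,
    heatmap_export,
    join_profiles,
    multiplicative_replacement,
    sensitivity,
    unclassified_pct,
)
from tests.conftest import make_profile

compositions = st.lists(
    st.floats(min_value=1e-4, max_value=1.0), min_size=2, max_size=20
).map(lambda v: np.asarray(v) / np.sum(v))


def joined(expected_rows, observed_rows):
    exp = ExpectedComposition(
        "c", [TaxonRecord(f"sp{t}", t, a) for t, a in expected_rows.items()]
    )
    obs = make_profile([(f"sp{t}", t, a) for t, a in observed_rows.items()])
    return join_profiles(exp, obs)


class TestJoin:
    def test_union_with_zeros(self):
        j = joined({1: 60, 2: 40}, {1: 70, 3: 30})
        rows = j.rows.set_index("taxid")
        assert rows.loc[1].expected_pct == 60 and rows.loc[1].observed_pct == 70
        assert rows.loc[2].expected_pct == 40 and rows.loc[2].observed_pct == 0
        assert rows.loc[3].expected_pct == 0 and rows.loc[3].observed_pct == 30

    def test_identical_sides(self):
        j = joined({1: 60, 2: 40}, {1: 60, 2: 40})
        assert (j.rows.expected_pct == j.rows.observed_pct).all()

    def test_duplicate_taxid_rejected(self, simple_expected):
        obs = make_profile([("A", 562, 50.0), ("A bis", 562, 50.0)])
        with pytest.raises(ValidationError, match="duplicate"):
            join_profiles(simple_expected, obs)


class TestFilterLowFP:
    def test_faint_false_positive_removed(self):
        j = filter_low_fp(joined({1: 100}, {1: 99.995, 2: 0.005}), 0.01)
        assert list(j.rows.taxid) == [1]

    def test_false_positive_above_threshold_retained(self):
        j = filter_low_fp(joined({1: 100}, {1: 99.98, 2: 0.02}), 0.01)
        assert set(j.rows.taxid) == {1, 2}

    def test_expected_taxon_never_removed(self):
        j = filter_low_fp(joined({1: 99, 2: 1}, {1: 99.995, 2: 0.005}), 0.01)
        assert set(j.rows.taxid) == {1, 2}


class TestMultiplicativeReplacement:
    def test_no_zeros_identity(self):
        out = multiplicative_replacement([0.5, 0.5])
        assert out.tolist() == [0.5, 0.5]

    def test_zero_imputed_with_explicit_delta(self):
        out = multiplicative_replacement([0.5, 0.5, 0.0], delta=1 / 9)
        assert out == pytest.approx([4 / 9, 4 / 9, 1 / 9])
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    @given(compositions, st.integers(min_value=0, max_value=5))
    @settings(max_examples=100, derandomize=True)
    def test_closure_preserved(self, comp, n_zeros):
        comp = np.concatenate([comp, np.zeros(n_zeros)])
        comp = comp / comp.sum()
        out = multiplicative_replacement(comp)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out > 0).all()

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            comp = rng.random(8)
            comp[rng.random(8) < 0.3] = 0.0
            if comp.sum() == 0:
                continue
            comp = comp / comp.sum()
            delta = (1 / len(comp)) ** 2
            ours = multiplicative_replacement(comp, delta)
            theirs = skbio_multi_replace(comp, delta)
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_too_many_zeros_for_delta(self):
        with pytest.raises(ValueError, match="delta"):
            multiplicative_replacement([1.0, 0.0, 0.0], delta=0.6)


class TestCLR:
    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(clr([0.25] * 4), np.zeros(4), atol=1e-12)

    def test_derived_value(self):
        np.testing.assert_allclose(
            clr([0.1, 0.3, 0.6]), [-0.9635, 0.1352, 0.8283], atol=1e-3
        )

    @given(compositions, st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_zero_and_scale_invariant(self, comp, scale):
        out = clr(comp)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(out, clr(scale * comp), atol=1e-9)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            comp = closure(rng.random(6) + 1e-3)
            np.testing.assert_allclose(clr(comp), skbio_clr(comp), atol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            clr([0.5, 0.5, 0.0])


class TestAitchisonDistance:
    def test_identical_is_zero(self):
        assert aitchison_distance([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_hand_derived_value(self):
        got = aitchison_distance([0.7, 0.2, 0.1], [0.1, 0.2, 0.7])
        assert got == pytest.approx(math.sqrt(2) * math.log(7), abs=1e-3)

    @given(compositions.filter(lambda c: len(c) >= 3))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_permutation_invariant(self, x):
        rng = np.random.default_rng(0)
        y = closure(rng.random(len(x)) + 1e-3)
        d = aitchison_distance(x, y)
        assert d == pytest.approx(aitchison_distance(y, x), abs=1e-12)
        perm = rng.permutation(len(x))
        assert d == pytest.approx(aitchison_distance(x[perm], y[perm]), abs=1e-9)

    def test_scale_invariance(self):
        x, y = [70.0, 20.0, 10.0], [10.0, 20.0, 70.0]
        d_pct = aitchison_distance(x, y)
        d_prop = aitchison_distance(np.asarray(x) / 100, np.asarray(y) / 100)
        assert d_pct == pytest.approx(d_prop, abs=1e-12)

    def test_oracle_equivalence_on_random_pairs(self):
        """AD == Euclidean(clr) with an independent implementation."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            d = rng.integers(3, 12)
            x, y = closure(rng.random(d) + 1e-4), closure(rng.random(d) + 1e-4)
            ours = aitchison_distance(x, y)
            oracle = float(np.linalg.norm(skbio_clr(x) - skbio_clr(y)))
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_appending_false_positive_increases_ad(self):
        """AD must be penalized for extraneous observed species."""
        exp = [60.0, 40.0]
        obs = [60.0, 40.0]
        base = aitchison_distance(exp, obs)
        with_fp = aitchison_distance(exp + [0.0], [54.0, 36.0, 10.0])
        assert with_fp > base

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            aitchison_distance([0.5, 0.5], [1.0])


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "n_found, n_expected, pct",
        [(7, 12, 58.33), (37, 38, 97.37), (15, 19, 78.95), (5, 5, 100.0)],
    )
    def test_sensitivity(self, n_found, n_expected, pct):
        exp = {i + 1: 100.0 / n_expected for i in range(n_expected)}
        obs = {i + 1: 100.0 / n_found for i in range(n_found)}
        assert sensitivity(joined(exp, obs)) == pytest.approx(pct, abs=5e-3)

    def test_sensitivity_no_expected_taxa(self):
        j = joined({1: 100.0}, {1: 100.0})
        j.rows.loc[:, "expected_pct"] = 0.0
        with pytest.raises(DegenerateInputError):
            sensitivity(j)

    def test_fpra_no_false_positives(self):
        assert fpra(joined({1: 60, 2: 40}, {1: 70, 2: 30})) == 0.0

    def test_fpra_overestimation_not_penalized(self):
        # an expected species reported at 100% is not a false positive
        assert fpra(joined({1: 10, 2: 90}, {1: 100.0})) == 0.0

    def test_fpra_direct(self):
        assert fpra(joined({1: 50, 2: 50}, {1: 50, 2: 30, 3: 20})) == pytest.approx(20.0)

    def test_unclassified_absent_and_mean(self):
        marker = make_profile([("A", 1, 100.0)])
        assert unclassified_pct(marker) is None
        reps = [
            make_profile([("A", 1, 100.0)], unclassified=4.0),
            make_profile([("A", 1, 100.0)], unclassified=6.0),
        ]
        assert unclassified_pct(reps) == pytest.approx(5.0)


class TestEvaluateSample:
    def test_zero_corruption(self, simple_expected):
        obs = make_profile([(r.name, r.taxid, r.rel_abund) for r in simple_expected.records])
        m = evaluate_sample(simple_expected, obs)
        assert m.ad == pytest.approx(0.0, abs=1e-12)
        assert m.sensitivity_pct == 100.0
        assert m.fpra_pct == 0.0

    def test_fp_filter_applied_before_metrics(self, simple_expected):
        obs = make_profile(
            [("Escherichia coli", 562, 59.995), ("Salmonella enterica", 28901, 40.0),
             ("Faint contaminant", 999, 0.005)]
        )
        m = evaluate_sample(simple_expected, obs)
        assert m.fpra_pct == 0.0  # sub-threshold FP removed before FPRA

    def test_heatmap_export_shape(self, simple_expected):
        obs = make_profile([("Escherichia coli", 562, 80.0)], pipeline_id="p1")
        table = heatmap_export(simple_expected, [obs])
        assert list(table.columns) == ["taxid", "name", "expected", "p1"]
        assert np.isnan(table.set_index("taxid").loc[28901, "p1"])  # zero -> empty
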