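"""Synthetic-data generator: designs, corruption bookkeeping, dialects."""

import io

import numpy as np
import pytest

from taxabench import (
    DIALECTS,
    SimulationConfig,
    ValidationError,
    annotate_taxids,
    build_taxonomy_index,
    evaluate_sample,
    generate_expected,
    generate_mini_taxdump,
    generate_panel,
    parse_profile,
    render_dialect,
    simulate_observed,
    write_bundle,
)
from tests.conftest import make_profile


class TestExpectedDesigns:
    def test_even_is_uniform(self):
        comp = generate_expected(SimulationConfig(seed=1, n_species=20, design="even"))
        assert all(r.rel_abund == pytest.approx(5.0) for r in comp.records)
        comp.validate()

    def test_staggered_spans_four_orders(self):
        comp = generate_expected(
            SimulationConfig(seed=1, n_species=12, design="staggered")
        )
        values = [r.rel_abund for r in comp.records]
        assert max(values) / min(values) >= 1e4
        assert comp.total() == pytest.approx(100.0)

    def test_panel_design_structure(self):
        panel = generate_panel(SimulationConfig(seed=1, n_species=15, design="latin_square_panel"))
        assert len(panel) == 5
        taxa_by_sample = {s: {r.taxid for r in c.records} for s, c in panel.items()}
        all_taxa = set().union(*taxa_by_sample.values())
        control = set.intersection(*taxa_by_sample.values())
        assert control  # a control block is present in every sample
        for taxid in all_taxa - control:
            absent_in = [s for s, taxa in taxa_by_sample.items() if taxid not in taxa]
            assert len(absent_in) == 1  # each non-control organism absent exactly once
            assert absent_in[0] != "EG"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            generate_expected(SimulationConfig(n_species=1))
        with pytest.raises(ValidationError):
            generate_expected(SimulationConfig(dropout_prob=1.0))
        with pytest.raises(ValidationError):
            generate_expected(SimulationConfig(design="latin_square_panel"))

    def test_large_community_supported(self):
        comp = generate_expected(SimulationConfig(seed=0, n_species=200, design="even"))
        assert len(comp.records) == 200
        taxids = [r.taxid for r in comp.records]
        assert len(set(taxids)) == 200


class TestSimulateObserved:
    def test_identity_corruption(self):
        config = SimulationConfig(
            seed=2, n_species=10, dropout_prob=0.0, n_false_positives=0,
            fp_mass_pct=0.0, noise_sigma=0.0,
        )
        expected = generate_expected(config)
        profiles, truth = simulate_observed(expected, config)
        m = evaluate_sample(expected, profiles[0])
        assert m.ad == pytest.approx(0.0, abs=1e-12)
        assert m.sensitivity_pct == 100.0
        assert m.fpra_pct == 0.0
        assert truth.predicted_sensitivity(0) == 100.0
        assert truth.predicted_fpra(0) == 0.0

    def test_fp_mass_recovered_exactly_before_noise(self):
        config = SimulationConfig(
            seed=3, n_species=10, dropout_prob=0.0, n_false_positives=4,
            fp_mass_pct=20.0, noise_sigma=0.0,
        )
        expected = generate_expected(config)
        profiles, truth = simulate_observed(expected, config)
        m = evaluate_sample(expected, profiles[0])
        assert m.fpra_pct == pytest.approx(20.0, abs=1e-9)
        assert truth.predicted_fpra(0) == pytest.approx(20.0, abs=1e-9)

    def test_metrics_match_truth_bookkeeping(self):
        config = SimulationConfig(
            seed=4, n_species=20, dropout_prob=0.3, n_false_positives=3,
            fp_mass_pct=10.0, noise_sigma=0.0, n_replicates=5,
        )
        expected = generate_expected(config)
        profiles, truth = simulate_observed(expected, config)
        for i, profile in enumerate(profiles):
            m = evaluate_sample(expected, profile)
            assert m.sensitivity_pct == pytest.approx(truth.predicted_sensitivity(i))
            assert m.fpra_pct == pytest.approx(truth.predicted_fpra(i), abs=1e-9)

    def test_same_seed_identical_output(self):
        config = SimulationConfig(seed=5, n_species=12, noise_sigma=0.3, n_replicates=3)
        expected = generate_expected(config)
        a, _ = simulate_observed(expected, config)
        b, _ = simulate_observed(expected, config)
        for pa, pb in zip(a, b):
            assert pa.records == pb.records


class TestMiniTaxdump:
    def test_duplicate_taxid_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate"):
            generate_mini_taxdump(
                [(1, "A a"), (1, "B b")], tmp_path / "n", tmp_path / "o"
            )

    def test_empty_warns(self, tmp_path):
        with pytest.warns(UserWarning):
            generate_mini_taxdump([], tmp_path / "n", tmp_path / "o")
        assert (tmp_path / "n").read_text() == ""

    def test_decorated_names_round_trip(self, tmp_path):
        taxa = [
            (101, "Marinobacter sp. LV10R510-8"),
            (102, "[Clostridium] innocuum"),
            (103, "Bifidobacterium longum subsp. longum"),
        ]
        generate_mini_taxdump(taxa, tmp_path / "names.dmp", tmp_path / "nodes.dmp")
        index = build_taxonomy_index(tmp_path / "names.dmp", tmp_path / "nodes.dmp")
        resolved = annotate_taxids([n for _, n in taxa], index)
        assert resolved == {n: t for t, n in taxa}


class TestDialectRoundTrips:
    PCTS = [40.0, 25.5, 15.25, 10.0, 5.125, 2.0625, 1.03125, 0.5, 0.25, 0.28125]

    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_round_trip_exact(self, dialect):
        # count_report reports percent-of-classified (sums to 100) with the
        # unclassified fraction on its own line; long_table abundances are
        # percent-of-total, so classified + unclassified close to 100 there
        if dialect == "long_table":
            scale, unclassified = 0.965, 3.5
        elif dialect == "count_report":
            scale, unclassified = 1.0, 3.5
        else:
            scale, unclassified = 1.0, None
        profile = make_profile(
            [(f"Genus species-{i}", 100 + i, p * scale) for i, p in enumerate(self.PCTS)],
            unclassified=unclassified,
        )
        text = render_dialect(profile, dialect)
        parsed = parse_profile(io.StringIO(text), dialect)
        got = sorted(r.rel_abund for r in parsed.records)
        want = sorted(r.rel_abund for r in profile.records)
        assert got == pytest.approx(want, abs=1e-9)
        if dialect in ("count_report", "long_table"):
            assert parsed.unclassified_pct == pytest.approx(3.5, abs=1e-9)

    def test_count_report_unclassified(self):
        profile = make_profile([("A b", 1, 100.0)], unclassified=5.0)
        parsed = parse_profile(
            io.StringIO(render_dialect(profile, "count_report")), "count_report"
        )
        assert parsed.unclassified_pct == 5.0

    def test_marker_profile_keeps_species_rows_only(self):
        profile = make_profile([("Escherichia coli", 562, 100.0)])
        text = render_dialect(profile, "marker_profile")
        assert "s__Escherichia_coli" in text
        parsed = parse_profile(io.StringIO(text), "marker_profile")
        assert parsed.records[0].name == "Escherichia_coli"

    def test_unsupported_dialect(self):
        with pytest.raises(ValueError):
            render_dialect(make_profile([("A b", 1, 100.0)]), "biom")


class TestBundle:
    def test_bundle_deterministic_and_resolvable(self, tmp_path):
        config = SimulationConfig(
            seed=6, n_species=10, n_replicates=2, noise_sigma=0.2,
            name_corruption=("strain_suffix", "brackets", "subspecies", "spelling_variant"),
        )
        d1 = write_bundle(config, tmp_path / "a")
        d2 = write_bundle(config, tmp_path / "b")
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

        index = build_taxonomy_index(d1 / "names.dmp", d1 / "nodes.dmp")
        profile = parse_profile(d1 / "observed-rep0.long_table.tsv", "long_table")
        resolved = annotate_taxids([r.name for r in profile.records], index)
        for r in profile.records:
            assert resolved[r.name] == r.taxid

    def test_sensitivity_recovery_under_dropout(self):
        """Mean sensitivity over replicates ~= 100*(1-p) within binomial error."""
        p = 0.25
        config = SimulationConfig(
            seed=7, n_species=200, dropout_prob=p, n_false_positives=0,
            fp_mass_pct=0.0, noise_sigma=0.0, n_replicates=100,
        )
        expected = generate_expected(config)
        profiles, truth = simulate_observed(expected, config)
        sens = [truth.predicted_sensitivity(i) for i in range(100)]
        se = 100 * np.sqrt(p * (1 - p) / (200 * 100))
        assert np.mean(sens) == pytest.approx(75.0, abs=3 * se)
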