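"""Synthetic bundle generation: determinism, schema validity, and exact
planted-overlap bookkeeping."""

from __future__ import annotations

import pytest

from tomspace import (
    AssociationKind,
    ModuleRole,
    RunConfig,
    SyntheticConfig,
    generate_dataset,
    generate_universe,
    is_cyp,
    load_admet_table,
    load_association_table,
    load_modules_table,
    run,
    write_dataset,
)


class TestGenerateUniverse:
    def test_scale_and_distinctness(self):
        uni = generate_universe(3000, seed=0)
        assert len(uni.genes) == 3000

    def test_single_symbol(self):
        assert len(generate_universe(1, seed=0).genes) == 1

    def test_deterministic_under_seed(self):
        assert generate_universe(500, seed=4).genes == generate_universe(500, seed=4).genes

    def test_cyp_salting_matches_fraction_and_pattern(self):
        uni = generate_universe(200, seed=1, cyp_fraction=0.1)
        cyps = {g for g in uni.genes if is_cyp(g)}
        assert len(cyps) == 20
        assert len(uni.genes) == 200


class TestConfigValidation:
    def test_planted_overlap_exceeding_module_size_rejected(self):
        cfg = SyntheticConfig(module_sizes=(10,), planted_overlaps=(11,))
        with pytest.raises(ValueError, match="planted overlap"):
            generate_dataset(cfg)

    def test_universe_too_small_rejected(self):
        cfg = SyntheticConfig(universe_size=100, module_sizes=(84, 50), planted_overlaps=(10, 10))
        with pytest.raises(ValueError, match="universe too small"):
            generate_dataset(cfg)

    def test_mismatched_lengths_rejected(self):
        cfg = SyntheticConfig(module_sizes=(84,), planted_overlaps=(10, 5))
        with pytest.raises(ValueError, match="equal length"):
            generate_dataset(cfg)


class TestBundleStructure:
    def test_deterministic_under_seed(self):
        a = generate_dataset(SyntheticConfig(seed=5, toxic_fraction=0.2, cyp_fraction=0.05))
        b = generate_dataset(SyntheticConfig(seed=5, toxic_fraction=0.2, cyp_fraction=0.05))
        assert a.compound_target.edges == b.compound_target.edges
        assert a.truth == b.truth

    def test_written_files_pass_all_loaders(self, bundle_dir):
        fh = load_association_table(bundle_dir["formula_herb.tsv"], AssociationKind.FORMULA_HERB)
        hc = load_association_table(bundle_dir["herb_compound.tsv"], AssociationKind.HERB_COMPOUND)
        ct = load_association_table(bundle_dir["compound_target.tsv"], AssociationKind.COMPOUND_TARGET)
        dt = load_association_table(bundle_dir["drug_target.tsv"], AssociationKind.DRUG_TARGET)
        mods = load_modules_table(bundle_dir["modules.tsv"])
        anns = load_admet_table(bundle_dir["admet.tsv"])
        assert fh.sources and hc.edges and ct.edges and dt.edges
        assert sum(1 for m in mods if m.role == ModuleRole.MAIN) == 1
        assert {a.compound_id for a in anns} == hc.targets

    def test_main_module_mirrors_curated_scale(self, noisy_bundle):
        main = noisy_bundle.modules[0]
        space_genes = {g for d, g in noisy_bundle.drug_target.edges if d in set(main.drug_ids)}
        assert len(space_genes) == 84
        assert len(main.drug_ids) == 38
        n_assoc = sum(1 for d, _ in noisy_bundle.drug_target.edges if d in set(main.drug_ids))
        assert n_assoc == 88  # duplicate associations on top of 84 distinct targets

    def test_formula_space_size_as_planted(self, clean_bundle):
        for fid, entry in clean_bundle.truth["formulas"].items():
            assert entry["formula_space_size"] == clean_bundle.truth["config"]["formula_space_size"]


def run_bundle(bundle, tmp_path, **overrides):
    paths = write_dataset(bundle, tmp_path / "data")
    cfg = RunConfig(
        formula_herb=str(paths["formula_herb.tsv"]),
        herb_compound=str(paths["herb_compound.tsv"]),
        compound_target=str(paths["compound_target.tsv"]),
        drug_target=str(paths["drug_target.tsv"]),
        modules=str(paths["modules.tsv"]),
        admet=str(paths["admet.tsv"]),
        null_enabled=False,
        out_dir=str(tmp_path / "out"),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return run(cfg)


class TestEndToEndRecovery:
    def test_clean_bundle_supports_equal_planted_ratios_exactly(self, clean_bundle, tmp_path):
        result = run_bundle(clean_bundle, tmp_path)
        truth = clean_bundle.truth["formulas"]
        for score in result.scores:
            entries = truth[score.formula_id]["modules"]
            assert score.main_support == entries[0]["expected_support"]
            for (mid, value), entry in zip(score.side_supports, entries[1:]):
                assert mid == entry["module_id"]
                assert value == entry["expected_support"]

    def test_filters_shift_supports_exactly_as_ledger_predicts(self, noisy_bundle, tmp_path):
        result = run_bundle(noisy_bundle, tmp_path)
        truth = noisy_bundle.truth["formulas"]
        for score in result.scores:
            entries = truth[score.formula_id]["modules"]
            assert score.main_support == entries[0]["expected_support_admet_and_cyp"]
            for (_, value), entry in zip(score.side_supports, entries[1:]):
                assert value == entry["expected_support_admet_and_cyp"]

    def test_cyp_exclusion_shift_matches_planted_cyp_counts(self, noisy_bundle, tmp_path):
        kept_cyp = run_bundle(noisy_bundle, tmp_path, exclude_cyp=False, admet=None,
                              out_dir=str(tmp_path / "o1"))
        truth = noisy_bundle.truth["formulas"]
        for score in kept_cyp.scores:
            entry = truth[score.formula_id]["modules"][0]
            assert score.main_support == entry["planted_overlap"] / entry["module_size"]
        excl = run_bundle(noisy_bundle, tmp_path, admet=None, out_dir=str(tmp_path / "o2"))
        for score in excl.scores:
            entry = truth[score.formula_id]["modules"][0]
            assert score.main_support == (
                entry["overlap_cyp_excluded"] / entry["module_size_cyp_excluded"]
            )

    def test_no_cyp_planted_makes_exclusion_a_no_op(self, clean_bundle, tmp_path):
        on = run_bundle(clean_bundle, tmp_path, out_dir=str(tmp_path / "a"))
        off = run_bundle(clean_bundle, tmp_path, exclude_cyp=False, out_dir=str(tmp_path / "b"))
        assert [s.weighted_average for s in on.scores] == [s.weighted_average for s in off.scores]

    def test_all_compounds_toxic_exercises_empty_space_path(self, tmp_path, caplog):
        bundle = generate_dataset(SyntheticConfig(seed=13, n_formulas=1, toxic_fraction=1.0))
        with caplog.at_level("WARNING"):
            result = run_bundle(bundle, tmp_path)
        assert result.scores[0].main_support == 0.0
        assert any("empty target space" in r.message for r in caplog.records)
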