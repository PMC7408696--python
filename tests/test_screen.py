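"""End-to-end screen orchestration, case-by-case tests, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import depscreen as ds
from depscreen.cli import main as cli_main


@pytest.fixture(scope="module")
def planted_screen(planted_bundle):
    bundle, truth, cohort = planted_bundle
    query = ds.ScreenQuery(mode="all", cohort=cohort)
    return bundle, cohort, ds.run_screen(bundle, query, seed=1)


class TestRunScreen:
    def test_planted_pair_ranks_first_and_is_mutant_sensitive(self, planted_screen):
        _, _, result = planted_screen
        top = result.ranked.iloc[0]
        assert (top["target"], top["biomarker"]) == ("T0003", "B0002")
        assert top["direction"] == "mutant-sensitive"
        assert top["delta_ess"] < 0
        assert top["p_value"] < 0.01

    def test_ranking_is_sorted_by_lfdr_then_p(self, planted_screen):
        _, _, result = planted_screen
        r = result.ranked
        assert (r["lfdr"].diff().dropna() >= -1e-12).all()

    def test_manifest_records_run(self, planted_screen):
        _, cohort, result = planted_screen
        man = result.manifest
        assert man["cohort_size"] == cohort.size
        assert man["n_pairs_tested"] == len(result.all_pairs)
        assert man["seed"] == 1
        assert man["params"]["max_lfdr"] == 0.5

    def test_query_restriction_consistency_all_modes(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        full = ds.run_screen(bundle, ds.ScreenQuery(mode="all", cohort=cohort)).ranked
        target = "T0003"
        drugs_of_target = sorted(
            set(bundle.dti.loc[bundle.dti["target"] == target, "drug_id"])
        )
        cases = [
            ("targets", [target], full[full["target"] == target]),
            ("mutations", ["B0002"], full[full["biomarker"] == "B0002"]),
        ]
        if drugs_of_target:
            cases.append(
                ("drugs", drugs_of_target[:1], full[full["target"] == target])
            )
        for mode, items, expected in cases:
            got = ds.run_screen(
                bundle, ds.ScreenQuery(mode=mode, cohort=cohort, items=items)
            ).ranked
            pd.testing.assert_frame_equal(
                got.reset_index(drop=True), expected.reset_index(drop=True)
            )

    def test_unknown_query_items_error(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        with pytest.raises(ValueError, match="NOPE"):
            ds.run_screen(
                bundle, ds.ScreenQuery(mode="targets", cohort=cohort, items=["NOPE"])
            )

    def test_global_null_screen_is_empty(self):
        cfg = ds.SyntheticConfig(
            n_panel=150, n_cohort=22, n_targets=100, n_biomarkers=15, seed=31
        )
        bundle, _ = ds.generate_bundle(cfg)
        cohort = ds.select_cohort(bundle.annotation, tumor_type="cohort")
        result = ds.run_screen(bundle, ds.ScreenQuery(mode="all", cohort=cohort))
        assert len(result.ranked) == 0

    def test_tightening_thresholds_never_adds_rows(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        query = ds.ScreenQuery(mode="all", cohort=cohort)
        loose = ds.run_screen(bundle, query, ds.ScreenParams(max_lfdr=0.8)).ranked
        tight = ds.run_screen(
            bundle, query, ds.ScreenParams(max_lfdr=0.2, min_abs_delta_ess=3.0)
        ).ranked
        loose_keys = set(zip(loose["target"], loose["biomarker"]))
        tight_keys = set(zip(tight["target"], tight["biomarker"]))
        assert tight_keys <= loose_keys


class TestTestPair:
    def test_planted_pair_statistics(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        row = ds.test_pair(bundle, cohort, "T0003", "B0002")
        assert row["p_value"] < 0.01
        assert row["delta_ess"] < 0
        assert row["direction"] == "mutant-sensitive"

    def test_matches_screen_row_when_pair_survives(self, planted_screen):
        bundle, cohort, result = planted_screen
        screen_row = result.ranked.iloc[0]
        row = ds.test_pair(bundle, cohort, "T0003", "B0002")
        for col in ("delta_ess", "p_value", "lfdr", "n_mut", "n_wt"):
            assert row[col] == pytest.approx(screen_row[col], abs=1e-12)

    def test_prefilter_is_bypassed_for_case_by_case(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        result = ds.run_screen(bundle, ds.ScreenQuery(mode="all", cohort=cohort))
        failed = result.prefilter_report.index[~result.prefilter_report["pass"]][0]
        row = ds.test_pair(bundle, cohort, failed, "B0002")
        assert 0.0 <= row["lfdr"] <= 1.0

    def test_zero_mutant_biomarker_reports_group_too_small(self, planted_bundle):
        bundle, _, cohort = planted_bundle
        M = bundle.mutations.copy()
        M.loc["B_empty"] = 0
        bundle2 = ds.AlignedBundle(
            essentiality=bundle.essentiality,
            mutations=M,
            expression=bundle.expression,
            annotation=bundle.annotation,
            dti=bundle.dti,
            interactions=bundle.interactions,
        )
        with pytest.raises(ds.GroupTooSmall, match="group too small"):
            ds.test_pair(bundle2, cohort, "T0003", "B_empty")


class TestDrugsAndInteractions:
    def test_drug_mapping_deduplicates_and_sorts(self):
        dti = pd.DataFrame(
            {
                "drug_id": ["volasertib", "BI2536", "volasertib"],
                "target": ["PLK1", "PLK1", "PLK1"],
            }
        )
        mapping = ds.map_targets_to_drugs(["PLK1", "AURKA"], dti)
        assert mapping["PLK1"] == ["BI2536", "volasertib"]
        assert mapping["AURKA"] == []

    def test_mapping_matches_scan_oracle(self, rng):
        dti = pd.DataFrame(
            {
                "drug_id": [f"d{rng.integers(30)}" for _ in range(100)],
                "target": [f"t{rng.integers(10)}" for _ in range(100)],
            }
        )
        targets = [f"t{i}" for i in range(12)]
        mapping = ds.map_targets_to_drugs(targets, dti)
        for t in targets:
            expected = sorted(
                {d for d, tt in zip(dti["drug_id"], dti["target"]) if tt == t}
            )
            assert mapping[t] == expected

    def test_interaction_membership_is_unordered(self):
        pairs = pd.DataFrame(
            {"target": ["PLK1", "YY2"], "biomarker": ["CREBBP", "TRRAP"]}
        )
        inter = {frozenset(("CREBBP", "PLK1"))}
        annotated = ds.interaction_filter(pairs, inter, require_interaction=False)
        assert list(annotated["interaction_supported"]) == [True, False]
        kept = ds.interaction_filter(pairs, inter, require_interaction=True)
        assert list(kept["target"]) == ["PLK1"]
        assert len(ds.interaction_filter(pairs, set(), require_interaction=True)) == 0


class TestCooccurrence:
    def test_perfect_cooccurrence_exact_fisher_p(self):
        g = [1] * 5 + [0] * 5
        M = pd.DataFrame(
            [g, g], index=["A", "B"], columns=[f"c{i}" for i in range(10)]
        )
        table = ds.mutation_cooccurrence(M, "A")
        # 2 of the C(10,5)=252 tables are as extreme: p = 2/252 = 1/126
        assert table.iloc[0]["fisher_p"] == pytest.approx(1 / 126, rel=1e-9)
        assert "A" not in set(table["gene"])

    def test_independent_mutations_show_no_signal(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            M = pd.DataFrame(
                rng.integers(0, 2, size=(20, 30)),
                index=[f"g{i}" for i in range(20)],
                columns=[f"c{i}" for i in range(30)],
            )
            table = ds.mutation_cooccurrence(M, "g0")
            if (table["fisher_p"] < 0.05 / 19).any():
                hits += 1
        assert hits == 0

    def test_gene_absent_errors(self):
        M = pd.DataFrame(np.zeros((2, 5), dtype=int), index=["a", "b"])
        with pytest.raises(ValueError):
            ds.mutation_cooccurrence(M, "zzz")


class TestCliDeterminism:
    def test_screen_runs_are_byte_identical(self, planted_bundle, tmp_path):
        bundle, _, _ = planted_bundle
        data = tmp_path / "data"
        ds.write_bundle(bundle, data)
        runner = CliRunner()
        outs = []
        for name in ("a.tsv", "b.tsv"):
            out = tmp_path / name
            res = runner.invoke(
                cli_main,
                [
                    "screen",
                    "--essentiality", str(data / "essentiality.tsv"),
                    "--mutations", str(data / "mutations.tsv"),
                    "--expression", str(data / "expression.tsv"),
                    "--annotation", str(data / "annotation.tsv"),
                    "--dti", str(data / "dti.tsv"),
                    "--interactions", str(data / "interactions.tsv"),
                    "--tumor-type", "cohort",
                    "--out", str(out),
                    "--seed", "7",
                ],
            )
            assert res.exit_code == 0, res.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]
        ranked = pd.read_csv(tmp_path / "a.tsv", sep="\t")
        assert ranked.iloc[0]["target"] == "T0003"
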