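"""End-to-end pipelines: ontogeny run, detection summaries, game JND report."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from camopipe import (
    DataError,
    default_detection_effects,
    detection_analysis,
    game_jnd_report,
    generate_detection_log,
    load_mapping,
    load_receptor_set,
    run_ontogeny_pipeline,
    small_ontogeny_config,
    synthetic_game_tables,
)


def _trial_rows(rows):
    df = pd.DataFrame(
        rows,
        columns=["game_id", "first_play", "crab_origin", "background_habitat", "latency_ms", "hit"],
    )
    df["vision_mode"] = "trichromat"
    return df


class TestDetectionAnalysis:
    def test_three_identical_hits_give_exact_cell_summary(self):
        trials = _trial_rows(
            [("g1", True, "mudflat", "mudflat", 2000, True)] * 3
        )
        res = detection_analysis(trials)
        cell = res.cells.iloc[0]
        assert cell["mean_latency_s"] == pytest.approx(2.0)
        assert cell["sd_latency_s"] == pytest.approx(0.0)
        assert cell["hit_proportion"] == 1.0
        assert cell["n"] == 3

    def test_miss_excluded_from_latency_mean_but_counted_in_proportion(self):
        trials = _trial_rows(
            [
                ("g1", True, "mudflat", "mudflat", 2000, True),
                ("g1", True, "mudflat", "mudflat", 4000, True),
                ("g1", True, "mudflat", "mudflat", None, False),
            ]
        )
        res = detection_analysis(trials)
        cell = res.cells.iloc[0]
        assert cell["mean_latency_s"] == pytest.approx(3.0)  # miss not averaged in
        assert cell["hit_proportion"] == pytest.approx(2 / 3)
        assert cell["n"] == 3

    def test_malformed_rows_counted_and_excluded(self):
        trials = _trial_rows(
            [
                ("g1", True, "mudflat", "mudflat", 2000, True),
                ("g1", True, "mudflat", "mudflat", None, True),     # hit without latency
                ("g1", True, "atlantis", "mudflat", 1500, True),    # unknown habitat
            ]
        )
        with pytest.warns(UserWarning, match="2 malformed"):
            res = detection_analysis(trials)
        assert res.n_malformed == 2
        assert res.n_used == 1

    def test_first_play_filter_and_cell_totals(self):
        log = generate_detection_log(default_detection_effects(), n_games=80, seed=6)
        res = detection_analysis(log, first_play_only=True)
        assert res.cells["n"].sum() == res.n_used
        assert res.n_used + res.n_filtered_out == len(log)
        res_all = detection_analysis(log, first_play_only=False)
        assert res_all.n_used == len(log)

    def test_split_by_vision_mode(self):
        log = generate_detection_log(default_detection_effects(), n_games=120, seed=8)
        res = detection_analysis(log, split_by_vision=True)
        assert "vision_mode" in res.cells.columns
        assert res.cells["n"].sum() == res.n_used

    def test_injected_habitat_ordering_recovered(self):
        # rockpool slowest, musselbed intermediate, mudflat fastest
        log = generate_detection_log(default_detection_effects(), n_games=2000, seed=10)
        res = detection_analysis(log)
        by_bg = res.by_background.set_index("background_habitat")["mean_latency_s"]
        assert by_bg["rockpool"] > by_bg["musselbed"] > by_bg["mudflat"]


class TestOntogenyPipeline:
    def test_zero_rates_give_flat_trajectories(self, tmp_path):
        cfg = small_ontogeny_config(2)
        cfg["rates"] = {
            "darkening_rate": 0.0, "greening_rate": 0.0,
            "pattern_decay_rate": 0.0, "noise_sd": 0.0,
        }
        res = run_ontogeny_pipeline(cfg, out_dir=tmp_path / "flat", seed=1)
        for specimen, df in res["jnd"].groupby("specimen_id"):
            assert df["luminance_jnd"].std() == pytest.approx(0.0, abs=1e-9)
            assert df["chromatic_jnd"].std() == pytest.approx(0.0, abs=1e-9)
        for specimen, df in res["colour"].groupby("specimen_id"):
            assert df["pc_colour"].std() == pytest.approx(0.0, abs=1e-6)

    def test_rerun_with_same_seed_is_bit_identical(self, tmp_path):
        cfg = small_ontogeny_config(2)
        run_ontogeny_pipeline(cfg, out_dir=tmp_path / "a", seed=3)
        run_ontogeny_pipeline(cfg, out_dir=tmp_path / "b", seed=3)
        for f in sorted((tmp_path / "a").iterdir()):
            assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f.name

    def test_never_overwrites_a_non_empty_directory(self, tmp_path):
        out = tmp_path / "run"
        out.mkdir()
        (out / "precious.txt").write_text("keep me")
        with pytest.raises(DataError, match="refusing to overwrite"):
            run_ontogeny_pipeline(small_ontogeny_config(1), out_dir=out, seed=0)
        assert (out / "precious.txt").read_text() == "keep me"

    def test_expected_output_files_and_labels(self, tmp_path):
        out = tmp_path / "demo"
        res = run_ontogeny_pipeline(small_ontogeny_config(2), out_dir=out, seed=5)
        for name in (
            "colour.csv", "pattern.csv", "jnd_trajectories.csv", "trajectory_summary.csv",
            "pca_colour_loadings.csv", "pca_colour_variance.csv", "metadata.json",
        ):
            assert (out / name).exists(), name
        cells = set(map(tuple, res["jnd"][["shade", "background"]].drop_duplicates().values))
        assert cells == {
            ("dark", "mudflat"), ("dark", "rockpool"),
            ("pale", "mudflat"), ("pale", "rockpool"),
        }


class TestGameJndReport:
    def test_crab_identical_to_background_scores_zero(self, human_set, human_mapping):
        crabs = pd.DataFrame(
            [{"crab_id": "c1", "crab_origin": "mudflat",
              "uv": 0.1, "b": 0.2, "g": 0.3, "r": 0.4}]
        )
        patches = pd.DataFrame(
            [{"patch_id": "p1", "background_habitat": "mudflat",
              "uv": 0.1, "b": 0.2, "g": 0.3, "r": 0.4}]
        )
        report = game_jnd_report(crabs, patches, human_set, human_mapping)
        assert report.loc[0, "chromatic_jnd_mean"] == pytest.approx(0.0, abs=1e-12)
        assert report.loc[0, "luminance_jnd_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_crab_and_background_roles_gives_identical_jnds(
        self, human_set, human_mapping
    ):
        crabs = pd.DataFrame(
            [{"crab_id": "c1", "crab_origin": "mudflat",
              "uv": 0.05, "b": 0.18, "g": 0.25, "r": 0.3}]
        )
        patches = pd.DataFrame(
            [{"patch_id": "p1", "background_habitat": "rockpool",
              "uv": 0.14, "b": 0.35, "g": 0.33, "r": 0.36}]
        )
        fwd = game_jnd_report(crabs, patches, human_set, human_mapping)
        swapped = game_jnd_report(
            patches.rename(columns={"patch_id": "crab_id",
                                    "background_habitat": "crab_origin"}),
            crabs.rename(columns={"crab_id": "patch_id",
                                  "crab_origin": "background_habitat"}),
            human_set, human_mapping,
        )
        assert fwd.loc[0, "chromatic_jnd_mean"] == pytest.approx(
            swapped.loc[0, "chromatic_jnd_mean"]
        )
        assert fwd.loc[0, "luminance_jnd_mean"] == pytest.approx(
            swapped.loc[0, "luminance_jnd_mean"]
        )

    def test_luminance_tuned_crab_has_lowest_luminance_jnd_everywhere(
        self, human_set, human_mapping
    ):
        # backgrounds with distinct luminances; the "tuned" crab sits at their
        # geometric mean, the other two crabs well away from it
        patches = pd.DataFrame(
            [
                {"patch_id": f"p{i}", "background_habitat": h,
                 "uv": 0.1, "b": v, "g": v, "r": v}
                for i, (h, v) in enumerate(
                    [("mudflat", 0.15), ("musselbed", 0.25), ("rockpool", 0.4)]
                )
            ]
        )
        tuned = float(np.exp(np.mean(np.log([0.15, 0.25, 0.4]))))
        crabs = pd.DataFrame(
            [
                {"crab_id": "tuned", "crab_origin": "mudflat",
                 "uv": 0.1, "b": tuned, "g": tuned, "r": tuned},
                {"crab_id": "dark", "crab_origin": "musselbed",
                 "uv": 0.1, "b": 0.06, "g": 0.06, "r": 0.06},
                {"crab_id": "bright", "crab_origin": "rockpool",
                 "uv": 0.1, "b": 0.85, "g": 0.85, "r": 0.85},
            ]
        )
        report = game_jnd_report(crabs, patches, human_set, human_mapping)
        pivot = report.pivot(
            index="crab_origin", columns="background_habitat", values="luminance_jnd_mean"
        )
        for habitat in pivot.columns:
            assert pivot.loc["mudflat", habitat] == pivot[habitat].min()

    def test_synthetic_game_tables_cover_the_three_by_three_design(self):
        crabs, patches = synthetic_game_tables(seed=0, n_crabs_per_origin=3,
                                               n_patches_per_habitat=2)
        report = game_jnd_report(
            crabs, patches,
            load_receptor_set("human_trichromat"), load_mapping("human_mapping"),
        )
        assert len(report) == 9
        assert (report["n"] == 6).all()  # 3 crabs x 2 patches per cell
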