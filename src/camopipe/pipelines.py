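"""End-to-end pipelines: the common-garden ontogeny study and the
detection-game analysis.

The ontogeny pipeline rears a synthetic cohort (two shade classes on two
gravel backgrounds, photographed weekly), extracts region colour and
granularity pattern statistics, reduces each to principal components, and
scores weekly crab-vs-own-background discriminability (chromatic and
luminance JNDs) under the pollack dichromat model. The detection pipeline
summarises search-game trial logs (per-cell n, mean/SD latency over hits,
hit proportion) and predicts per-cell camouflage with the human trichromat
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .calibration import extract_region
from .errors import ConfigurationError, DataError
from .granularity import build_bands, granularity_spectrum, pattern_table
from .io import load_background_style, load_mapping, load_receptor_set, write_json
from .summarise import pca_reduce, trajectory_summary
from .synthetic import generate_background, generate_crab_series, generate_detection_log
from .types import (
    CrabPhenotype,
    DetectionEffects,
    HABITATS,
    OntogenyParams,
    RegionColour,
)
from .vision import achromatic_jnd, chromatic_jnd, luminance_from_catches, match_trajectory
from .calibration import to_cone_catches

__all__ = [
    "default_ontogeny_config",
    "small_ontogeny_config",
    "simulate_ontogeny_cohort",
    "run_ontogeny_pipeline",
    "ontogeny_start_end",
    "default_detection_effects",
    "detection_analysis",
    "DetectionResult",
    "game_jnd_report",
    "synthetic_game_tables",
]

COLOUR_VARIABLES = ["brightness", "r", "g", "b", "uv"]
PATTERN_VARIABLES = ["max_power", "proportional_power", "total_power", "mean_power"]

# Canonical demo cohort: 17 dark-mud, 16 dark-rock, 13 pale-mud, 14 pale-rock.
DEFAULT_COHORT = {
    ("dark", "mudflat"): 17,
    ("dark", "rockpool"): 16,
    ("pale", "mudflat"): 13,
    ("pale", "rockpool"): 14,
}


def default_ontogeny_config() -> dict:
    """Default synthetic common-garden configuration.

    Rates emulate the observed ontogenetic trend — all crabs darken, shift
    toward green and lose pattern contrast over 10 weeks — at magnitudes
    chosen so the initially dark crabs converge on the mudflat background
    while initially pale crabs diverge from the rockpool background.
    """
    return {
        "cohort": {f"{s}:{b}": n for (s, b), n in DEFAULT_COHORT.items()},
        "weeks": 10,
        "carapace_width_px": 48,
        "background_px": 96,
        "n_bands": 5,
        "rates": {
            "darkening_rate": 0.05,
            "greening_rate": 0.008,
            "pattern_decay_rate": 0.12,
            "noise_sd": 0.005,
        },
        "phenotypes": {
            "dark": {
                "base_reflectance": [0.05, 0.22, 0.28, 0.34],
                "pattern_contrast": 0.18,
                "marking_size_px": 6,
            },
            "pale": {
                "base_reflectance": [0.10, 0.33, 0.35, 0.37],
                "pattern_contrast": 0.25,
                "marking_size_px": 6,
            },
        },
        "phenotype_jitter_sd": 0.01,
        "receptor_set": "pollack_dichromat",
        "mapping": "pollack_mapping",
    }


def small_ontogeny_config(n_per_treatment: int = 3) -> dict:
    """Scaled-down cohort (same rates/palettes) for repeated-seed checks."""
    cfg = default_ontogeny_config()
    cfg["cohort"] = {f"{s}:{b}": n_per_treatment for (s, b) in DEFAULT_COHORT}
    cfg["carapace_width_px"] = 32
    cfg["background_px"] = 64
    cfg["n_bands"] = 4
    return cfg


def _sample_phenotypes(cfg: dict, rng: np.random.Generator) -> list[tuple[str, str, str, CrabPhenotype]]:
    """(specimen_id, shade, background, phenotype) for the whole cohort."""
    jitter = cfg.get("phenotype_jitter_sd", 0.0)
    crabs = []
    idx = 0
    for key, n in cfg["cohort"].items():
        shade, background = key.split(":")
        pheno_cfg = cfg["phenotypes"][shade]
        for _ in range(int(n)):
            idx += 1
            base = np.clip(
                np.asarray(pheno_cfg["base_reflectance"], dtype=float)
                + rng.normal(0.0, jitter, size=4),
                0.0, 1.0,
            )
            crabs.append(
                (
                    f"crab{idx:03d}",
                    shade,
                    background,
                    CrabPhenotype(
                        base_reflectance=base,
                        pattern_contrast=float(pheno_cfg["pattern_contrast"]),
                        marking_size_px=int(pheno_cfg["marking_size_px"]),
                        shade_class=shade,
                        carapace_width_px=int(cfg["carapace_width_px"]),
                    ),
                )
            )
    # generation-time invariant: the pale class is brighter than the dark class
    by_class: dict[str, list[float]] = {"pale": [], "dark": []}
    for _, shade, _, ph in crabs:
        vis = ph.base_reflectance[1:]  # b, g, r
        by_class[shade].append(float(vis.mean()))
    if by_class["pale"] and by_class["dark"]:
        if not np.mean(by_class["pale"]) > np.mean(by_class["dark"]):
            raise ConfigurationError(
                "pale phenotype class must have higher mean base reflectance than dark"
            )
    return crabs


def simulate_ontogeny_cohort(
    config: dict | None = None,
    seed: int = 0,
    pattern_weeks: list[int] | None = None,
) -> dict:
    """Generate the cohort and compute every per-specimen-week table.

    Returns a dict with ``colour`` (normalized camera responses),
    ``pattern`` (granularity statistics; restricted to ``pattern_weeks``
    when given), and ``jnd`` (weekly crab-vs-own-background chromatic and
    luminance JNDs) DataFrames, each labelled by shade × background
    treatment.
    """
    cfg = config or default_ontogeny_config()
    rng = np.random.default_rng(seed)
    receptors = load_receptor_set(cfg["receptor_set"])
    mapping = load_mapping(cfg["mapping"])
    params = OntogenyParams(weeks=int(cfg["weeks"]), **cfg["rates"])
    crabs = _sample_phenotypes(cfg, rng)

    styles = {b: load_background_style(b) for b in {bg for _, _, bg, _ in crabs}}
    bg_px = int(cfg["background_px"])

    colour_rows, pattern_records, jnd_records = [], [], []
    labels = {}
    bank = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping warnings from extreme jitter draws
        for specimen_id, shade, background, phenotype in crabs:
            labels[specimen_id] = (shade, background)
            bg_seed = int(rng.integers(0, 2**31 - 1))
            series_seed = int(rng.integers(0, 2**31 - 1))
            bg_image = generate_background(styles[background], bg_px, bg_px, bg_seed)
            bg_colour = extract_region(bg_image, np.ones(bg_image.shape, dtype=bool))
            series = generate_crab_series(phenotype, params, series_seed)
            if bank is None:
                bank = build_bands(series[0][1].shape, int(cfg["n_bands"]))
            pair_records = []
            for week, image, mask in series:
                crab_colour = extract_region(image, mask)
                colour_rows.append(
                    {
                        "specimen_id": specimen_id, "shade": shade,
                        "background": background, "week": week,
                        "brightness": crab_colour.brightness,
                        "r": crab_colour.r_mean, "g": crab_colour.g_mean,
                        "b": crab_colour.b_mean, "uv": crab_colour.uv_mean,
                        "hue": crab_colour.hue,
                    }
                )
                if pattern_weeks is None or week in pattern_weeks:
                    pattern_records.append((specimen_id, week, image, mask))
                pair_records.append((specimen_id, week, crab_colour, bg_colour))
            jnd_records.append(match_trajectory(pair_records, receptors, mapping))

    colour = pd.DataFrame(colour_rows)
    pattern, pattern_errors = pattern_table(pattern_records, bank)
    if pattern_errors:
        warnings.warn(f"{len(pattern_errors)} pattern records failed: {pattern_errors[:3]}")
    jnd = pd.concat(jnd_records, ignore_index=True)
    for df in (pattern, jnd):
        df.insert(1, "shade", df["specimen_id"].map(lambda s: labels[s][0]))
        df.insert(2, "background", df["specimen_id"].map(lambda s: labels[s][1]))
    return {"colour": colour, "pattern": pattern, "jnd": jnd, "config": cfg}


def run_ontogeny_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> dict:
    """Run the full common-garden pipeline and (optionally) write its CSVs.

    Stages: synthetic cohort → colour table → pattern table → colour and
    pattern PCA → JND trajectories → treatment × week trajectory summaries.
    When ``out_dir`` is given it must be empty or absent (reruns never
    overwrite silently); every stage's CSV is written there with a JSON
    metadata record of the seed and parameters.
    """
    tables = simulate_ontogeny_cohort(config, seed)
    cfg = tables.pop("config")

    colour, pattern, jnd = tables["colour"], tables["pattern"], tables["jnd"]
    pca_colour = pca_reduce(colour, standardize=True, columns=COLOUR_VARIABLES)
    colour = colour.assign(pc_colour=pca_colour.scores[:, 0])
    pca_pattern = pca_reduce(pattern, standardize=True, columns=PATTERN_VARIABLES)
    pattern = pattern.assign(pc_pattern=pca_pattern.scores[:, 0])

    summary = pd.concat(
        [
            trajectory_summary(jnd, ["chromatic_jnd", "luminance_jnd"]),
            trajectory_summary(colour, ["pc_colour", "brightness", "hue"]),
            trajectory_summary(pattern, ["pc_pattern", "total_power", "proportional_power"]),
        ],
        ignore_index=True,
    )

    results = {
        "colour": colour,
        "pattern": pattern,
        "jnd": jnd,
        "trajectory_summary": summary,
        "pca_colour": pca_colour,
        "pca_pattern": pca_pattern,
    }
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()):
            raise DataError(f"output directory {out} is not empty; refusing to overwrite")
        out.mkdir(parents=True, exist_ok=True)
        colour.to_csv(out / "colour.csv", index=False)
        pattern.to_csv(out / "pattern.csv", index=False)
        jnd.to_csv(out / "jnd_trajectories.csv", index=False)
        summary.to_csv(out / "trajectory_summary.csv", index=False)
        for name, pca in (("colour", pca_colour), ("pattern", pca_pattern)):
            pd.DataFrame(
                pca.loadings,
                index=pca.variables,
                columns=[f"pc{k + 1}" for k in range(len(pca.variables))],
            ).to_csv(out / f"pca_{name}_loadings.csv")
            pd.DataFrame(
                {
                    "component": [f"pc{k + 1}" for k in range(len(pca.eigenvalues))],
                    "eigenvalue": pca.eigenvalues,
                    "variance_explained": pca.variance_explained,
                }
            ).to_csv(out / f"pca_{name}_variance.csv", index=False)
        write_json(
            {
                "seed": seed,
                "config": cfg,
                "camopipe_version": _version,
                "pca_colour_retained_kaiser": pca_colour.n_retained_kaiser,
                "pca_pattern_retained_kaiser": pca_pattern.n_retained_kaiser,
                "pca_standardized": True,
                "pca_sign_convention": "largest-magnitude loading positive",
            },
            out / "metadata.json",
        )
    return results


def ontogeny_start_end(config: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """First-vs-final-week treatment means for the trajectory metrics.

    Computes, per shade × background treatment, the cohort mean luminance
    JND, chromatic JND and granularity total power at week 0 and the final
    week (pattern statistics are only evaluated at those two weeks). Used
    for direction-of-change (sign) checks across seeds.
    """
    cfg = config or small_ontogeny_config()
    weeks = int(cfg["weeks"])
    tables = simulate_ontogeny_cohort(cfg, seed, pattern_weeks=[0, weeks])
    rows = []
    for (shade, background), _ in DEFAULT_COHORT.items():
        if f"{shade}:{background}" not in cfg["cohort"]:
            continue
        jnd = tables["jnd"].query("shade == @shade and background == @background")
        pat = tables["pattern"].query("shade == @shade and background == @background")
        for metric, df, col in (
            ("luminance_jnd", jnd, "luminance_jnd"),
            ("chromatic_jnd", jnd, "chromatic_jnd"),
            ("pattern_total_power", pat, "total_power"),
        ):
            rows.append(
                {
                    "shade": shade,
                    "background": background,
                    "metric": metric,
                    "start_mean": df.loc[df["week"] == 0, col].mean(),
                    "end_mean": df.loc[df["week"] == weeks, col].mean(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection-game analysis
# ---------------------------------------------------------------------------


def default_detection_effects() -> DetectionEffects:
    """Generator defaults emulating the reported detection-time structure.

    Background effects are the log ratios of the reported per-habitat mean
    search times (mudflat fastest, rockpool slowest) and origin effects the
    log ratios of the per-origin means (mudflat-origin crabs hardest to
    find); miss probability matches an overall hit rate of roughly 93%.
    The baseline is set so the mudflat-background mean latency, averaged
    over origins with the log-normal mean correction exp(sd²/2), lands on
    the reported 2.08 s.
    """
    sd = 0.75
    origin_effects = {
        "mudflat": float(np.log(3.11 / 2.31)),
        "musselbed": float(np.log(2.45 / 2.31)),
        "rockpool": 0.0,
    }
    baseline = (
        float(np.log(2.08))
        - sd**2 / 2.0
        - float(np.log(np.mean([np.exp(v) for v in origin_effects.values()])))
    )
    return DetectionEffects(
        baseline_log_latency=baseline,
        background_effects={
            "mudflat": 0.0,
            "musselbed": float(np.log(2.47 / 2.08)),
            "rockpool": float(np.log(3.24 / 2.08)),
        },
        crab_origin_effects=origin_effects,
        interaction_terms={},
        miss_probability=0.07,
        latency_sd_log=sd,
        time_limit_s=30.0,
    )


@dataclass
class DetectionResult:
    """Detection-experiment summaries at cell and marginal level."""

    cells: pd.DataFrame
    by_background: pd.DataFrame
    by_origin: pd.DataFrame
    n_used: int
    n_malformed: int
    n_filtered_out: int


def _summarize_cells(trials: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    def agg(group: pd.DataFrame) -> pd.Series:
        lat_s = group.loc[group["hit"], "latency_ms"].astype(float) / 1000.0
        return pd.Series(
            {
                "n": len(group),
                "hit_proportion": float(group["hit"].mean()),
                "mean_latency_s": float(lat_s.mean()) if len(lat_s) else np.nan,
                "sd_latency_s": float(lat_s.std(ddof=1)) if len(lat_s) > 1 else
                (0.0 if len(lat_s) == 1 else np.nan),
            }
        )

    out = (
        trials.groupby(keys, sort=True)[trials.columns.tolist()]
        .apply(agg)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def detection_analysis(
    trials: pd.DataFrame,
    first_play_only: bool = True,
    split_by_vision: bool = False,
) -> DetectionResult:
    """Summarise a detection-trial log.

    Misses are excluded from latency means but included in hit-proportion
    denominators (the reported Ns accompany found-target means; this reading
    is the default and both filters are explicit). Malformed rows — a hit
    with no latency, a latency at/over the 30-s limit, an unknown habitat —
    are counted and reported, never silently dropped. Vision modes are
    pooled unless ``split_by_vision``.
    """
    required = {"crab_origin", "background_habitat", "latency_ms", "hit", "first_play"}
    missing = required - set(trials.columns)
    if missing:
        raise DataError(f"trial table missing columns: {sorted(missing)}")
    df = trials.copy()
    df["latency_ms"] = pd.to_numeric(df["latency_ms"], errors="coerce")
    df["hit"] = df["hit"].astype(bool)

    bad = (
        (df["hit"] & df["latency_ms"].isna())
        | (df["hit"] & (df["latency_ms"] >= 30_000).fillna(False))
        | (df["latency_ms"] <= 0).fillna(False)
        | ~df["crab_origin"].isin(HABITATS)
        | ~df["background_habitat"].isin(HABITATS)
    ).astype(bool)
    n_malformed = int(bad.sum())
    if n_malformed:
        warnings.warn(f"excluding {n_malformed} malformed trial rows", stacklevel=2)
    df = df[~bad]

    n_before_filter = len(df)
    if first_play_only:
        df = df[df["first_play"].astype(bool)]
    n_filtered_out = n_before_filter - len(df)
    if df.empty:
        raise DataError("no trials left after filtering")

    cell_keys = ["crab_origin", "background_habitat"]
    if split_by_vision:
        cell_keys.append("vision_mode")
    return DetectionResult(
        cells=_summarize_cells(df, cell_keys),
        by_background=_summarize_cells(df, ["background_habitat"]),
        by_origin=_summarize_cells(df, ["crab_origin"]),
        n_used=len(df),
        n_malformed=n_malformed,
        n_filtered_out=n_filtered_out,
    )


def game_jnd_report(
    crab_colours: pd.DataFrame,
    background_colours: pd.DataFrame,
    receptors=None,
    mapping=None,
) -> pd.DataFrame:
    """Per-cell chromatic and luminance JNDs for the detection game.

    ``crab_colours`` has one row per crab (``crab_id, crab_origin, uv, b,
    g, r``); ``background_colours`` one row per background patch
    (``patch_id, background_habitat, uv, b, g, r``). Every crab is scored
    against every patch under the (default human trichromat) observer and
    summarised per origin × habitat cell as mean ± SE.
    """
    receptors = receptors or load_receptor_set("human_trichromat")
    mapping = mapping or load_mapping("human_mapping")
    rows = []
    for _, crab in crab_colours.iterrows():
        crab_rc = RegionColour.from_channel_means(
            r=crab["r"], g=crab["g"], b=crab["b"], uv=crab["uv"]
        )
        q_crab = to_cone_catches(crab_rc, mapping)
        qc = np.array([q_crab[r] for r in receptors.names])
        lum_crab = luminance_from_catches(q_crab, receptors)
        for _, patch in background_colours.iterrows():
            bg_rc = RegionColour.from_channel_means(
                r=patch["r"], g=patch["g"], b=patch["b"], uv=patch["uv"]
            )
            q_bg = to_cone_catches(bg_rc, mapping)
            qb = np.array([q_bg[r] for r in receptors.names])
            rows.append(
                {
                    "crab_origin": crab["crab_origin"],
                    "background_habitat": patch["background_habitat"],
                    "chromatic_jnd": chromatic_jnd(qc, qb, receptors).jnd,
                    "luminance_jnd": achromatic_jnd(
                        lum_crab, luminance_from_catches(q_bg, receptors), receptors
                    ).jnd,
                }
            )
    pairs = pd.DataFrame(rows)
    grouped = pairs.groupby(["crab_origin", "background_habitat"], sort=True)
    out = grouped.agg(
        n=("chromatic_jnd", "count"),
        chromatic_jnd_mean=("chromatic_jnd", "mean"),
        chromatic_jnd_se=("chromatic_jnd", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        luminance_jnd_mean=("luminance_jnd", "mean"),
        luminance_jnd_se=("luminance_jnd", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
    ).reset_index()
    return out


# Dark-green "mudflat phenotype" crabs, intermediate musselbed crabs, lighter
# variable rockpool crabs: synthetic stand-ins for the game's crab cut-outs.
GAME_CRAB_COLOURS = {
    "mudflat": [0.05, 0.16, 0.24, 0.26],
    "musselbed": [0.07, 0.22, 0.24, 0.22],
    "rockpool": [0.14, 0.38, 0.40, 0.42],
}


def synthetic_game_tables(
    seed: int = 0,
    n_crabs_per_origin: int = 12,
    n_patches_per_habitat: int = 6,
    background_px: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic crab and background colour tables for the game analysis."""
    rng = np.random.default_rng(seed)
    crab_rows = []
    for origin, base in GAME_CRAB_COLOURS.items():
        for i in range(n_crabs_per_origin):
            refl = np.clip(np.asarray(base) + rng.normal(0, 0.02, size=4), 0.01, 1.0)
            crab_rows.append(
                {
                    "crab_id": f"{origin[:3]}{i + 1:02d}", "crab_origin": origin,
                    "uv": refl[0], "b": refl[1], "g": refl[2], "r": refl[3],
                }
            )
    patch_rows = []
    for habitat in HABITATS:
        style = load_background_style(habitat)
        for i in range(n_patches_per_habitat):
            img = generate_background(
                style, background_px, background_px, int(rng.integers(0, 2**31 - 1))
            )
            rc = extract_region(img, np.ones(img.shape, dtype=bool))
            patch_rows.append(
                {
                    "patch_id": f"{habitat[:3]}_p{i + 1:02d}",
                    "background_habitat": habitat,
                    "uv": rc.uv_mean, "b": rc.b_mean, "g": rc.g_mean, "r": rc.r_mean,
                }
            )
    return pd.DataFrame(crab_rows), pd.DataFrame(patch_rows)
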