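#!/usr/bin/env python
"""Generate the synthetic study materials.

Writes a small demonstration set of the three synthetic inputs every later
stage consumes: gravel background images for the three habitats (mudflat,
musselbed, rockpool), one 10-week crab image series per shade class, and a
detection-game trial log. Everything downstream (02, 03) regenerates its
own data from seeds, so this script exists to let you *look* at what the
generators produce.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import argparse
from pathlib import Path

import numpy as np

from camopipe import (
    CrabPhenotype,
    OntogenyParams,
    default_detection_effects,
    default_ontogeny_config,
    generate_background,
    generate_crab_series,
    generate_detection_log,
    load_background_style,
    write_mask,
    write_reflectance_image,
)
from camopipe.io import write_json


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results/01_synthetic"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    print("== synthetic study materials ==")
    for habitat in ("mudflat", "musselbed", "rockpool"):
        style = load_background_style(habitat)
        img = generate_background(style, 96, 96, int(rng.integers(0, 2**31 - 1)))
        write_reflectance_image(img, out / f"background_{habitat}.tiff")
        lum = img.luminance_plane()
        print(
            f"background {habitat:>9}: mean luminance {lum.mean():.3f}, "
            f"pixel sd {lum.std():.3f} ({len(style.granule_palette)} granule colours)"
        )

    cfg = default_ontogeny_config()
    params = OntogenyParams(weeks=cfg["weeks"], **cfg["rates"])
    for shade in ("dark", "pale"):
        ph_cfg = cfg["phenotypes"][shade]
        phenotype = CrabPhenotype(
            base_reflectance=np.array(ph_cfg["base_reflectance"]),
            pattern_contrast=ph_cfg["pattern_contrast"],
            marking_size_px=ph_cfg["marking_size_px"],
            shade_class=shade,
            carapace_width_px=cfg["carapace_width_px"],
        )
        series = generate_crab_series(phenotype, params, int(rng.integers(0, 2**31 - 1)))
        for week, img, mask in series:
            write_reflectance_image(img, out / f"crab_{shade}_week{week:02d}.tiff")
            if week == 0:
                write_mask(mask, out / f"crab_{shade}_mask.png")
        b0 = series[0][1].luminance_plane()[series[0][2]].mean()
        b10 = series[-1][1].luminance_plane()[series[-1][2]].mean()
        print(f"{shade} crab: masked brightness week 0 {b0:.3f} -> week {cfg['weeks']} {b10:.3f}")

    trials = generate_detection_log(default_detection_effects(), n_games=200,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    trials.to_csv(out / "detection_log.csv", index=False)
    print(f"detection log: {len(trials)} slides from 200 games "
          f"(hit rate {trials['hit'].mean():.3f})")

    write_json({"seed": args.seed, "config": cfg}, out / "metadata.json")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
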