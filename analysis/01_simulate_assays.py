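#!/usr/bin/env python
"""Simulate the binding assays under their published designs.

Generates the steady-state SPR dilution series (duplicate, 2 RU noise)
for the three measured TCR affinities — 25.8 uM against the
double-citrullinated epitope on HLA-DRB1*04:01, 50 uM against the
P2-only citrullinated variant, 75.5 uM against the cross-reactive
HLA-DRB1*04:05 — and the FP competition series (triplicate, 3% noise)
for the presenting allomorphs (IC50 0.8 / 1.1 / 1.3 uM), plus one
non-binding allomorph curve that never leaves the upper plateau.

Writes CSVs under results/assays/ for the fitting driver.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tcrint.synthetic import FpSimSpec, SprSimSpec, simulate_fp, simulate_spr

SPR_TRUTHS = {"double_cit_0401": 25.8, "single_cit_1016": 50.0,
              "double_cit_0405": 75.5}
FP_TRUTHS = {"drb1_0101": 0.8, "drb1_0401": 1.1, "drb1_1402": 1.3}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/assays"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    children = iter(np.random.SeedSequence(args.seed).generate_state(8) % 2**31)

    for label, kd in SPR_TRUTHS.items():
        curve = simulate_spr(SprSimSpec(kd=kd, seed=int(next(children))))
        pd.DataFrame({
            "concentration_uM": curve.concentrations,
            "response": curve.responses,
            "replicate": curve.replicate_id,
        }).to_csv(out / f"spr_{label}.csv", index=False)
        print(f"spr_{label}.csv: K_D truth {kd} uM, "
              f"{len(curve.concentrations)} points")

    for label, ic50 in FP_TRUTHS.items():
        curve = simulate_fp(FpSimSpec(ic50=ic50, seed=int(next(children))))
        pd.DataFrame({
            "concentration_uM": curve.competitor_conc,
            "response": curve.normalized_binding,
            "replicate": curve.replicate_id,
        }).to_csv(out / f"fp_{label}.csv", index=False)
        print(f"fp_{label}.csv: IC50 truth {ic50} uM, "
              f"{len(curve.competitor_conc)} points")

    # the non-binding allomorph: flat near 100% relative binding
    rng = np.random.default_rng(int(next(children)))
    conc = np.repeat(300.0 / 2.0 ** np.arange(10), 3)
    flat = 100.0 + rng.normal(0.0, 3.0, size=len(conc))
    pd.DataFrame({
        "concentration_uM": conc, "response": flat,
        "replicate": np.tile([0, 1, 2], 10),
    }).to_csv(out / "fp_drb1_0404.csv", index=False)
    print("fp_drb1_0404.csv: no inhibition up to 300 uM")


if __name__ == "__main__":
    main()
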