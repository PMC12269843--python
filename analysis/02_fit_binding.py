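#!/usr/bin/env python
"""Fit the simulated binding assays and classify variant impact.

Reads the CSVs written by 01_simulate_assays.py, fits the one-site
isotherm to every SPR series (pooled over replicates) and the 4PL to
every FP series, attaches the fold-change impact class relative to the
double-citrullinated wild-type curve, and writes kd_fits.json /
ic50_fits.json under results/binding/.

Expected outcome: recovered K_D within ~15% of the generating truths,
the 50-vs-25.8 uM pair classifying as no_effect (<2-fold), and the
non-binding allomorph reported as "IC50 > 300 uM".
"""

import argparse
from pathlib import Path

from tcrint.config import BindingConfig
from tcrint.report import run_binding


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--assay-dir", type=Path, default=Path("results/assays"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/binding"))
    args = parser.parse_args()

    spr_curves = {p.stem[4:]: p for p in sorted(args.assay_dir.glob("spr_*.csv"))}
    if not spr_curves:
        raise SystemExit("no SPR CSVs found; run 01_simulate_assays.py first")
    spr = run_binding(BindingConfig(
        assay="spr", curves=spr_curves, wildtype="double_cit_0401",
        out_dir=args.out_dir,
    ))
    print("steady-state K_D fits:")
    for label, fit in spr["fits"].items():
        extra = f", {fit['fold_vs_wildtype']:.2f}-fold -> {fit['impact']}" \
            if "impact" in fit else ""
        print(f"  {label}: {fit['kd_uM']} uM (se {fit['se_kd_uM']}){extra}")

    fp_curves = {p.stem[3:]: p for p in sorted(args.assay_dir.glob("fp_*.csv"))}
    fp = run_binding(BindingConfig(
        assay="fp", curves=fp_curves, out_dir=args.out_dir,
    ))
    print("competition IC50 fits:")
    for label, fit in fp["fits"].items():
        print(f"  {label}: {fit['ic50_uM']} uM "
              f"(full inhibition: {fit['reached_full_inhibition']})")


if __name__ == "__main__":
    main()
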