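"""Correlation screening of all 14 analytes against the SNV spectra.

For each analyte and light pathway, Pearson's r and p are computed at every
one of the 288 channels; channels passing |r| > 0.3 and p < 0.01 (collapsed
to local extrema) become model covariates.  The pigmented analytes
(hemoglobin, erythrocytes, bilirubin, ...) should yield strong peaks; the
cell counts and glucose, which carry no visible-range optical signature,
should yield none.

Writes results/screening/{correlation_curves.csv, selected_features.csv}
and correlation-curve plots for hemoglobin and bilirubin.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from drainspec.pipeline import RunConfig, prepare_snv, screen_analyte
from drainspec.simulate import SyntheticConfig, simulate_cohort
from drainspec.spectra import ANALYTES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "screening")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cubes, panels, _ = simulate_cohort(SyntheticConfig(seed=args.seed))
    data = prepare_snv(cubes, panels)
    config = RunConfig(seed=args.seed)

    curve_rows, feature_rows = [], []
    for analyte in ANALYTES:
        curves, features = screen_analyte(data, analyte, config)
        for pw, curve in curves.items():
            for ch in range(curve.r.size):
                curve_rows.append((analyte, pw, ch, curve.grid[ch], curve.r[ch], curve.p[ch]))
        for f in features:
            feature_rows.append((analyte, f.pathway, f.channel, f.wavelength_nm, f.r, f.p))
        label = ", ".join(f"{f.pathway}@{f.wavelength_nm:.0f}nm r={f.r:+.2f}" for f in features)
        print(f"{analyte:26s} {len(features)} features  {label}")

    curves_df = pd.DataFrame(
        curve_rows, columns=["analyte", "pathway", "channel", "wavelength_nm", "r", "p"]
    )
    curves_df.to_csv(args.out / "correlation_curves.csv", index=False)
    pd.DataFrame(
        feature_rows, columns=["analyte", "pathway", "channel", "wavelength_nm", "r", "p"]
    ).to_csv(args.out / "selected_features.csv", index=False)

    for analyte in ("hemoglobin", "bilirubin"):
        fig, ax = plt.subplots(figsize=(7, 4))
        sub = curves_df[curves_df["analyte"] == analyte]
        for pw, color in [("DT", "tab:blue"), ("AT", "tab:red"), ("AR", "tab:green")]:
            part = sub[sub["pathway"] == pw]
            ax.plot(part["wavelength_nm"], part["r"], color=color, label=pw, lw=1)
        ax.axhline(0.3, ls="--", c="gray", lw=0.8)
        ax.axhline(-0.3, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("Pearson r")
        ax.set_title(f"correlation curve: {analyte}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.out / f"curve_{analyte}.png", dpi=120)


if __name__ == "__main__":
    main()
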