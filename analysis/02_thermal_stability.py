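#!/usr/bin/env python
"""Thermal-stability recovery study.

For each zymogen variant's apparent melting temperature, simulates
replicate 20-70 °C fluorescence scans (two-state transition, linear
baselines, 0.5% relative noise) and refits the two-state model, reporting
the mean recovered T_m and its dispersion.  The proline mutants melt
within ~1.5 °C of the wild type; the catalytically dead S196A variants
melt ~5-6 °C higher because autolysis no longer accompanies unfolding.

Writes results/melt/tm_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from zymokin import melt, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "melt"
OUT.mkdir(parents=True, exist_ok=True)

# apparent T_m (degC) per variant
VARIANTS = {
    "wild type": 49.5, "P2A": 49.1, "P5A": 49.4, "P8A": 48.7,
    "P-A": 48.1, "S196A": 54.2, "P-A/S196A": 55.1,
}
N_REP = 25


def main() -> None:
    rows = []
    for i, (name, tm_true) in enumerate(VARIANTS.items()):
        truth = melt.TwoStateFit(
            tm_K=tm_true + melt.CELSIUS_OFFSET, dh_J_mol=300e3,
            y_native=100.0, y_unfolded=35.0,
            slope_native=-0.05, slope_unfolded=-0.02)
        fits = [melt.fit_melting(synthetic.simulate_melting_curve(
            truth, noise_rel=0.005, seed=1000 * i + s)).tm_C
            for s in range(N_REP)]
        rows.append({"variant": name, "tm_true_C": tm_true,
                     "tm_fit_mean_C": np.mean(fits),
                     "tm_fit_sd_C": np.std(fits), "n": N_REP})
        print(f"{name:10s} true {tm_true:5.1f} C  ->  fitted "
              f"{np.mean(fits):6.2f} +- {np.std(fits):4.2f} C")
    pd.DataFrame(rows).to_csv(OUT / "tm_recovery.csv", index=False)
    print(f"\nwrote {OUT / 'tm_recovery.csv'}")


if __name__ == "__main__":
    main()
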