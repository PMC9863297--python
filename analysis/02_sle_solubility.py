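#!/usr/bin/env python
"""Solid-liquid-equilibrium solubility of edaravone from fusion data.

Evaluates the Gibbs energy of fusion and the ideal saturation mole fraction
over the measurement temperature range, and shows how a non-ideal activity
model (one-parameter Margules) shifts the solved saturation point.

Writes results/sle_solubility.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eutsol import sle

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fusion = sle.EDARAVONE_FUSION
    rows = []
    for T in np.arange(278.15, 403.16, 5.0):
        ideal = sle.solve_sle(sle.ideal_activity, fusion, T=float(T))
        pos = sle.solve_sle(sle.margules(1.0), fusion, T=float(T))
        neg = sle.solve_sle(sle.margules(-1.0), fusion, T=float(T))
        rows.append(
            {
                "T_K": float(T),
                "dG_fus_kJ_per_mol": sle.gibbs_fusion(fusion, float(T)),
                "x_ideal": ideal.x_sat,
                "x_margules_A=+1": pos.x_sat,
                "x_margules_A=-1": neg.x_sat,
                "iterations_A=+1": pos.iterations,
            }
        )
    frame = pd.DataFrame(rows)

    at_298 = frame.loc[(frame.T_K - 298.15).abs().idxmin()]
    print(
        f"at 298.15 K: dG_fus = {at_298['dG_fus_kJ_per_mol']:.3f} kJ/mol, "
        f"ideal x_sat = {at_298['x_ideal']:.4f}"
    )
    print(
        "positive deviation (A=+1) suppresses solubility to "
        f"{at_298['x_margules_A=+1']:.4f}; negative (A=-1) raises it to "
        f"{at_298['x_margules_A=-1']:.4f}"
    )
    print(
        f"solver converges in <= {int(frame['iterations_A=+1'].max())} iterations "
        "across the range; x -> 1 at the melting point"
    )
    measured_range = (0.0787, 0.158)  # weakest 1:1 GLE .. best 1:2 ETA at 298.15 K
    print(
        f"measured x_E at 298.15 K ({measured_range[0]}-{measured_range[1]}) exceeds "
        f"the ideal estimate {at_298['x_ideal']:.4f}: strong favorable solute-DES "
        "interactions (ln gamma < 0)"
    )

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "sle_solubility.csv", index=False)
    print(f"wrote {OUT / 'sle_solubility.csv'}")


if __name__ == "__main__":
    main()
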