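#!/usr/bin/env python
"""Tautomer populations and association ranking for edaravone in DES.

Uses illustrative keto/enol/amine relative free energies (synthetic inputs
shaped like bulk-phase quantum-chemistry output, with the keto form a few
kcal/mol below its competitors as established for condensed phases) to show
the population machinery, and ranks the reported association Gibbs energies
of the studied complexes.

Writes results/tautomer_populations.csv and results/association_ranking.csv.
"""

from pathlib import Path

import pandas as pd

from eutsol import tautomers as tt

OUT = Path(__file__).resolve().parents[1] / "results"

# Synthetic bulk-phase relative energies (kcal/mol) vs DES mole fraction:
# keto set to zero, competitors 3.5-4.5 kcal/mol higher, mildly
# composition-dependent - the regime observed for this drug in polar media.
BULK_ENERGIES = {
    x: {"keto": 0.0, "amine": 3.5 + 0.4 * x, "enol": 4.0 + 0.5 * x}
    for x in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
}

# Reported association Gibbs energies at 298.15 K (kcal/mol), activity basis.
ASSOCIATIONS = [
    tt.ReactionThermo("2E -> E-E (drug dimer, stacking)", -13.8, -13.8),
    tt.ReactionThermo("ChCl + EG -> ETA ion pair", -13.3, -13.3),
    tt.ReactionThermo("ChCl + GL -> GLE ion pair", -13.1, -13.1),
    tt.ReactionThermo("ETA + EG -> ETA-EG cluster", -12.8, -12.8),
    tt.ReactionThermo("GLE + GL -> GLE-GL cluster", -11.3, -11.3),
]


def main() -> None:
    pops = tt.population_curve(BULK_ENERGIES, T=298.15)
    print("keto fraction across compositions:")
    print(pops["keto"].to_string(float_format="%.5f"))
    print(
        f"\nketo dominates everywhere (min {pops['keto'].min():.4f}); "
        "enol and amine are negligible in the bulk phase"
    )

    ranked = tt.rank_complexes(ASSOCIATIONS)
    ranking = pd.DataFrame(
        {"reaction": [r.reaction for r in ranked], "dG_a_kcal_per_mol": [r.dG_a for r in ranked]}
    )
    print("\nassociation ranking (most stable first):")
    print(ranking.to_string(index=False))
    K_dimer = tt.K_from_gibbs(ranked[0].dG_a)
    print(f"\nthe drug dimer is the most stable contact; K_a = {K_dimer:.2e}")

    OUT.mkdir(exist_ok=True)
    pops.to_csv(OUT / "tautomer_populations.csv")
    ranking.to_csv(OUT / "association_ranking.csv", index=False)
    print(f"wrote {OUT / 'tautomer_populations.csv'} and association_ranking.csv")


if __name__ == "__main__":
    main()
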