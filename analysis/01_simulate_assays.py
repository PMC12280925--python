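"""Generate the synthetic assay inputs for the downstream analyses.

Writes, for each reference compound, one interaction-binding CSV and one
functional (cAMP) CSV drawn from its reported estimates at the assay design
(agonist ladders, modulator 0/3/10/30 µM, n = 4 replicates, 5% CV), plus a
26-compound screen table with three planted PAMs. Everything is seeded, so
re-running reproduces the files byte for byte.
"""

from pathlib import Path

from allomod import io, presets
from allomod.datatypes import SimulationDesign
from allomod.synthetic_data import gen_functional, gen_interaction_binding, gen_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, compound in enumerate(presets.COMPOUNDS):
        binding = gen_interaction_binding(
            presets.atcm_truth(compound), SimulationDesign(seed=SEED + i)
        )
        io.write_binding_csv(binding, OUT / f"{compound}_binding.csv")
        functional = gen_functional(
            presets.operational_truth(compound),
            SimulationDesign.functional_default(seed=SEED + 100 + i),
        )
        io.write_functional_csv(functional, OUT / f"{compound}_functional.csv")
        print(f"{compound}: wrote binding ({sum(len(d.specific_binding) for d in binding)} pts) "
              f"and functional ({sum(len(d.response) for d in functional)} pts) tables")

    truth_map = {"C02": (0.5, 0.5), "C12": (0.4, 0.4), "C20": (0.5, 0.4)}
    control, treated = gen_screen(truth_map, seed=SEED + 500)
    control["arm"] = "control"
    treated["arm"] = "treated"
    import pandas as pd

    pd.concat([control, treated]).to_csv(OUT / "screen.csv", index=False)
    print(f"screen: 26 compounds x 4 replicates with 3 planted PAMs -> {OUT / 'screen.csv'}")


if __name__ == "__main__":
    main()
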