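"""Run the screening funnel on a synthetic docked library.

Generates a template-based molecule library with dock scores and pose
contacts, partitions it into fragment/lead-like windows, applies the top
rank cut, the S246/L276 hydrogen-bond filter, and Tanimoto leader
clustering, and emits the candidate list that would feed visual inspection.
"""

from pathlib import Path

import pandas as pd

from allomod.datatypes import RankedLibrary
from allomod.io import write_json
from allomod.synthetic_data import gen_molecule_table
from allomod.triage import (
    hbond_filter,
    leader_cluster,
    partition_library,
    select_representatives,
    top_fraction,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    molecules, poses = gen_molecule_table(2000, seed=2026, hbond_prob=0.4)
    bins = partition_library(molecules)
    report = {"n_input": len(molecules), "libraries": {}}
    poses_by_id = {p.molecule_id: p for p in poses}
    for bin_name in ("fragment", "lead_like"):
        members = bins[bin_name]
        lib = RankedLibrary(
            frame=pd.DataFrame(
                {
                    "molecule_id": [m.molecule_id for m in members],
                    "score": [m.dock_score for m in members],
                    "label": "unknown",
                }
            )
        )
        cut_ids = set(top_fraction(lib, fraction=0.1).frame["molecule_id"])
        retained = set(hbond_filter(poses_by_id[i] for i in sorted(cut_ids)))
        survivors = [m for m in members if m.molecule_id in retained]
        clusters = leader_cluster(survivors, threshold=0.5)
        reps = select_representatives(clusters, survivors, max_clusters=1000)
        report["libraries"][bin_name] = {
            "n_in_window": len(members),
            "n_after_rank_cut": len(cut_ids),
            "n_after_hbond_filter": len(retained),
            "n_clusters": len(clusters),
            "candidates": [m.molecule_id for m in reps],
        }
        print(
            f"{bin_name}: {len(members)} in window -> {len(cut_ids)} after rank cut -> "
            f"{len(retained)} with both H-bonds -> {len(clusters)} clusters"
        )
    write_json(report, OUT / "funnel_report.json")
    print(f"wrote {OUT / 'funnel_report.json'}")


if __name__ == "__main__":
    main()
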