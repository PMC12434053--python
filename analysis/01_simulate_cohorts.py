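"""Simulate the study-shaped cohorts every later step analyses.

Generates the ground-truth reference (2,000 genes, 8 cerebellar cell types,
30 markers each), a sorted cohort (3 donors per type), a 25-sample control
unsorted cohort at the control composition, and a 12-sample A-T cohort in
single-effect mode for Purkinje neurons.  Writes counts, metadata, truth
tables and the true marker sets under results/cohorts/.
"""

from pathlib import Path

import pandas as pd

from netsdecon import (
    AT_EFFECTS,
    CONTROL_CEREBELLUM,
    simulate_sorted,
    simulate_unsorted,
    single_effect_composition,
    write_counts,
    write_gmt,
)
from netsdecon.io import GeneSetCollection
from netsdecon.workflows import control_reference

SEED = 20260926
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = control_reference(SEED)
    sorted_counts, sorted_meta, _ = simulate_sorted(ref, donors_per_type=3, seed=SEED + 1)
    ctrl_counts, ctrl_meta, truth = simulate_unsorted(
        ref, CONTROL_CEREBELLUM, n_samples=25, seed=SEED + 2
    )
    fold, direction = AT_EFFECTS.effects["purkinje"]
    preset = single_effect_composition(CONTROL_CEREBELLUM, "purkinje", fold, direction)
    at_counts, at_meta, at_truth = simulate_unsorted(
        ref, preset, n_samples=12, seed=SEED + 3, condition="AT"
    )

    counts = pd.concat([sorted_counts, ctrl_counts, at_counts], axis=1)
    meta = pd.concat([sorted_meta, ctrl_meta, at_meta], ignore_index=True)
    write_counts(counts, OUT / "counts.tsv")
    meta.to_csv(OUT / "metadata.csv", index=False)
    pd.concat([truth.composition, at_truth.composition]).to_csv(
        OUT / "truth_composition.csv"
    )
    write_gmt(GeneSetCollection(dict(ref.markers)), OUT / "true_markers.gmt")
    ref.profiles_pm().to_csv(OUT / "truth_signature.csv")

    print(f"reference: {len(ref.genes)} genes, {len(ref.cell_types)} cell types, "
          f"{len(ref.markers['granule'])} markers/type, boost {ref.boost:g}")
    print(f"cohorts: {sorted_counts.shape[1]} sorted, {ctrl_counts.shape[1]} control "
          f"unsorted, {at_counts.shape[1]} A-T unsorted (Purkinje /"
          f"{fold} single effect)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
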