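"""High-level experiment recipes combining the simulator with the estimators.

These are the standard desk-scale experiments of the analysis: a control
cohort deconvolved globally against the noise-free truth signature, and the
single-effect comparative experiment that recovers one published proportion
fold change per simulated disease cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from netsdecon.deconv import (
    build_comparative_panels,
    deconvolve_comparative,
    deconvolve_global,
    signature_from_reference,
)
from netsdecon.io import normalize
from netsdecon.simulate import (
    AT_EFFECTS,
    CONTROL_CEREBELLUM,
    GroundTruthReference,
    make_reference,
    simulate_unsorted,
    single_effect_composition,
)

__all__ = [
    "control_reference",
    "global_composition_experiment",
    "comparative_fold_experiment",
]


def control_reference(seed: int, **kwargs) -> GroundTruthReference:
    """The study-condition reference: 2,000 genes, 8 types, 30 markers each."""
    defaults = dict(n_genes=2000, markers_per_type=30, dispersion=0.1)
    defaults.update(kwargs)
    return make_reference(seed=seed, **defaults)


def global_composition_experiment(
    seed: int,
    n_samples: int = 25,
    rna_content: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a control unsorted cohort and deconvolve it globally.

    Uses the control composition preset, unit RNA content by default, and
    the noise-free signature built from the truth profiles.  Returns the
    per-sample fraction estimates (plus residual/convergence columns).
    """
    ref = control_reference(seed)
    counts, _, _ = simulate_unsorted(
        ref,
        CONTROL_CEREBELLUM,
        n_samples=n_samples,
        rna_content=rna_content,
        seed=seed + 1,
    )
    expr = normalize(counts, log=False)
    signature = signature_from_reference(ref)
    return deconvolve_global(expr, signature)


def comparative_fold_experiment(
    target: str,
    seed: int,
    n_control: int = 25,
    n_at: int = 12,
) -> dict:
    """Recover one published proportion fold change in single-effect mode.

    Simulates a control cohort at the control preset and an A-T cohort with
    only the target's effect applied, fits the target's comparative panel
    (restricted to the target's marker genes) per sample, and reports the
    ratio of group mean similarity fractions oriented by the effect's
    direction (control/A-T for decreases, A-T/control for increases).
    """
    fold, direction = AT_EFFECTS.effects[target]
    ref = control_reference(seed)
    preset_at = single_effect_composition(CONTROL_CEREBELLUM, target, fold, direction)

    ctrl_counts, _, _ = simulate_unsorted(
        ref, CONTROL_CEREBELLUM, n_samples=n_control, seed=seed + 1
    )
    at_counts, _, _ = simulate_unsorted(
        ref, preset_at, n_samples=n_at, seed=seed + 2, condition="AT"
    )

    signature = signature_from_reference(ref)
    panels = build_comparative_panels(signature, panel_genes=ref.markers)
    panel = next(p for p in panels if p.target == target)
    f_ctrl = deconvolve_comparative(normalize(ctrl_counts, log=False), panel)["fraction"]
    f_at = deconvolve_comparative(normalize(at_counts, log=False), panel)["fraction"]
    mean_ctrl, mean_at = float(f_ctrl.mean()), float(f_at.mean())
    ratio = mean_ctrl / mean_at if direction == "decrease" else mean_at / mean_ctrl
    return dict(
        target=target,
        true_fold=fold,
        direction=direction,
        estimated_fold=ratio,
        mean_control=mean_ctrl,
        mean_at=mean_at,
        n_control=n_control,
        n_at=n_at,
    )
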