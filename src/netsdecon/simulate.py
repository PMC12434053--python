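"""Synthetic sorted/unsorted nuclear RNA-seq cohorts with known ground truth.

The generator emulates the structure of a sorted-nuclei (FANS) cerebellum
cohort: eight sorted cell-type populations plus unsorted samples, control
vs A-T condition labels, donor ages, and an optional ambient-contamination
channel that mimics granule-neuron RNA bleeding into droplet-based
single-nucleus libraries.

Counts are negative binomial (gamma-Poisson), parameterized by mean and a
per-gene dispersion (inverse size): ``var = mu + dispersion * mu**2``.
Every sample additionally carries a per-donor, per-gene log-normal effect.
All outputs are a deterministic function of the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netsdecon.io import CELL_TYPES, Expression, validate_counts

__all__ = [
    "GroundTruthReference",
    "CompositionPreset",
    "EffectPreset",
    "SyntheticTruth",
    "CONTROL_CEREBELLUM",
    "AT_EFFECTS",
    "make_reference",
    "simulate_sorted",
    "simulate_unsorted",
    "simulate_age_cohort",
    "single_effect_composition",
]


@dataclass
class GroundTruthReference:
    """Per-cell-type true mean expression profiles plus marker assignment."""

    genes: list[str]
    cell_types: tuple[str, ...]
    profiles: pd.DataFrame  # genes x cell_types, linear arbitrary units
    markers: dict[str, list[str]]  # cell_type -> marker genes (disjoint)
    boost: float
    dispersion: np.ndarray  # per-gene inverse-size
    seed: int

    def profiles_pm(self) -> pd.DataFrame:
        """Truth profiles rescaled so each cell-type column sums to 1e6."""
        return self.profiles / self.profiles.sum(axis=0) * 1.0e6


@dataclass(frozen=True)
class CompositionPreset:
    """Named cell-type proportion vector on the simplex."""

    name: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        values = np.array(list(self.fractions.values()), dtype=float)
        if (values < 0).any():
            raise ValueError(f"preset {self.name}: negative fraction")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"preset {self.name}: fractions sum to {values.sum()!r}, not 1"
            )

    def as_series(self, cell_types: tuple[str, ...] | None = None) -> pd.Series:
        order = cell_types or tuple(self.fractions)
        return pd.Series({c: self.fractions[c] for c in order}, dtype=float)


@dataclass(frozen=True)
class EffectPreset:
    """Per-cell-type proportion fold changes with direction.

    ``direction == "decrease"`` folds are control/A-T ratios,
    ``"increase"`` folds are A-T/control ratios; all folds are > 1 by
    convention so the direction flag carries the sign.
    """

    name: str
    effects: dict[str, tuple[float, str]]  # cell_type -> (fold, direction)

    def __post_init__(self) -> None:
        for cell_type, (fold, direction) in self.effects.items():
            if fold <= 0:
                raise ValueError(f"{self.name}: fold for {cell_type} must be > 0")
            if direction not in ("increase", "decrease"):
                raise ValueError(f"{self.name}: bad direction {direction!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    composition: pd.DataFrame  # samples x cell_types, nuclei fractions
    rna_content: pd.Series  # per cell type, rho
    ambient_alpha: float
    donor_table: pd.DataFrame  # donor_id, condition, age
    mixture_pm: pd.DataFrame | None = None  # samples' expected per-million profile
    age_genes: pd.DataFrame | None = None  # gene, direction, slope (age cohorts)


#: Control cerebellum composition on the mRNA-proportion scale (rho = 1 use).
#: Granule 0.70, Purkinje 0.007, astrocyte 0.022 and oligodendrocyte 0.013
#: follow the study's deconvolution/flow estimates; basket, Golgi, OPC and
#: microglia close the simplex and are configuration defaults, not
#: literature claims.
CONTROL_CEREBELLUM = CompositionPreset(
    "CONTROL_CEREBELLUM",
    {
        "astrocyte": 0.022,
        "basket": 0.060,
        "golgi": 0.020,
        "granule": 0.700,
        "microglia": 0.113,
        "oligodendrocyte": 0.013,
        "opc": 0.065,
        "purkinje": 0.007,
    },
)

#: A-T proportion effects: neuronal losses (control/A-T fold) and glial
#: gains (A-T/control fold).
AT_EFFECTS = EffectPreset(
    "AT_EFFECTS",
    {
        "purkinje": (1.85, "decrease"),
        "granule": (1.35, "decrease"),
        "golgi": (1.52, "decrease"),
        "basket": (1.45, "decrease"),
        "opc": (1.35, "increase"),
        "oligodendrocyte": (2.0, "increase"),
        "astrocyte": (1.37, "increase"),
        "microglia": (1.44, "increase"),
    },
)


def make_reference(
    n_genes: int = 2000,
    cell_types: tuple[str, ...] = CELL_TYPES,
    markers_per_type: int = 30,
    boost: float = 200.0,
    dispersion: float | np.ndarray = 0.1,
    seed: int = 0,
) -> GroundTruthReference:
    """Draw a ground-truth reference with planted cell-type markers.

    Base gene means are log-normal on the log2 scale (mean 1, sd 1) and
    shared across cell types; each cell type then receives
    ``markers_per_type`` disjoint marker genes whose mean is multiplied by
    ``boost`` in that type only.  The default boost of 200 reflects the
    strong (100-1000x) enrichment of canonical cerebellar markers such as
    PCP2/CALB1 (Purkinje) or GABRA6 (granule) in sorted populations.
    """
    if boost <= 1:
        raise ValueError("boost must be > 1")
    n_marked = len(cell_types) * markers_per_type
    if n_genes < n_marked:
        raise ValueError(
            f"{n_marked} marker genes requested but only {n_genes} genes available"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = 2.0 ** rng.normal(1.0, 1.0, n_genes)
    marker_genes = rng.choice(n_genes, size=n_marked, replace=False)
    blocks = [
        marker_genes[i * markers_per_type : (i + 1) * markers_per_type]
        for i in range(len(cell_types))
    ]
    # Equalize each panel's aggregate baseline abundance.  With only a few
    # dozen heavy-tailed marker genes per type, the random panel mass (and
    # hence each type's transcriptome budget) would otherwise fluctuate far
    # more than real marker programs spread over thousands of genes do.
    masses = np.array([base[idx].sum() for idx in blocks])
    for idx, mass in zip(blocks, masses):
        base[idx] *= masses.mean() / mass
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(cell_types))), index=genes, columns=list(cell_types)
    )
    markers: dict[str, list[str]] = {}
    for cell_type, idx in zip(cell_types, blocks):
        markers[cell_type] = sorted(genes[j] for j in idx)
        profiles.loc[markers[cell_type], cell_type] *= boost
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    if (dispersion < 0).any():
        raise ValueError("dispersion must be >= 0")
    return GroundTruthReference(
        genes=genes,
        cell_types=tuple(cell_types),
        profiles=profiles,
        markers=markers,
        boost=float(boost),
        dispersion=dispersion,
        seed=seed,
    )


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mu`` and ``var = mu + disp * mu**2``."""
    mu = np.maximum(mu, 0.0)
    out = np.empty_like(mu)
    pos = dispersion > 0
    if pos.any():
        lam = rng.gamma(shape=1.0 / dispersion[pos], scale=mu[pos] * dispersion[pos])
        out[pos] = rng.poisson(lam)
    if (~pos).any():
        out[~pos] = rng.poisson(mu[~pos])
    return out


def _draw_library_sizes(rng: np.random.Generator, n: int, libsize: float, sd: float) -> np.ndarray:
    return libsize * np.exp(rng.normal(0.0, sd, n))


def _donor_ages(rng: np.random.Generator, n: int, condition: str) -> np.ndarray:
    # A-T donors die young; controls span the adult range.
    if condition == "AT":
        return rng.integers(8, 36, n)
    return rng.integers(8, 97, n)


def _sample_counts(
    rng: np.random.Generator,
    mixture_pm: np.ndarray,
    dispersion: np.ndarray,
    libsize: float,
    donor_sd: float,
) -> np.ndarray:
    donor_effect = np.exp(rng.normal(0.0, donor_sd, mixture_pm.shape[0]))
    mu = libsize * (mixture_pm / mixture_pm.sum()) * donor_effect
    return _nb_counts(rng, mu, dispersion)


def simulate_sorted(
    ref: GroundTruthReference,
    donors_per_type: int = 3,
    ambient_alpha: float = 0.0,
    seed: int = 0,
    libsize: float = 2.0e6,
    libsize_sd: float = 0.25,
    donor_sd: float = 0.1,
    condition: str = "control",
    ambient_pool: CompositionPreset = CONTROL_CEREBELLUM,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate FANS-sorted profiles, one library per donor and cell type.

    With ``ambient_alpha > 0`` each sorted profile is mixed with an ambient
    pool weighted by the control composition (granule-dominated), emulating
    ambient-RNA contamination of droplet-based single-nucleus data.
    """
    if donors_per_type < 1:
        raise ValueError("donors_per_type must be >= 1")
    if not 0 <= ambient_alpha < 1:
        raise ValueError("ambient_alpha must be in [0, 1)")
    rng = np.random.default_rng(seed)
    profiles_pm = ref.profiles_pm()
    weights = ambient_pool.as_series(ref.cell_types).to_numpy()
    ambient = profiles_pm.to_numpy() @ (weights / weights.sum())

    counts, meta_rows, comp_rows = {}, [], []
    for cell_type in ref.cell_types:
        ages = _donor_ages(rng, donors_per_type, condition)
        for d in range(donors_per_type):
            donor = f"{condition}_d{d:02d}"
            sample = f"{cell_type}_{donor}"
            own = profiles_pm[cell_type].to_numpy()
            mixture = (1.0 - ambient_alpha) * own + ambient_alpha * ambient
            lib = _draw_library_sizes(rng, 1, libsize, libsize_sd)[0]
            counts[sample] = _sample_counts(rng, mixture, ref.dispersion, lib, donor_sd)
            meta_rows.append(
                dict(
                    sample_id=sample,
                    donor_id=donor,
                    cell_type=cell_type,
                    condition=condition,
                    age=int(ages[d]),
                    sex=("F" if rng.random() < 0.5 else "M"),
                    pmi=round(float(np.exp(rng.normal(np.log(20.0), 0.4))), 1),
                    batch=f"b{d % 2 + 1}",
                )
            )
            frac = dict.fromkeys(ref.cell_types, 0.0)
            frac[cell_type] = 1.0
            comp_rows.append(pd.Series(frac, name=sample))

    counts_df = validate_counts(pd.DataFrame(counts, index=ref.genes))
    meta = pd.DataFrame(meta_rows)
    truth = SyntheticTruth(
        composition=pd.DataFrame(comp_rows),
        rna_content=pd.Series(1.0, index=list(ref.cell_types)),
        ambient_alpha=ambient_alpha,
        donor_table=meta[["donor_id", "condition", "age"]].drop_duplicates(),
    )
    return counts_df, meta, truth


def simulate_unsorted(
    ref: GroundTruthReference,
    preset: CompositionPreset = CONTROL_CEREBELLUM,
    n_samples: int = 25,
    rna_content: dict[str, float] | pd.Series | None = None,
    seed: int = 0,
    condition: str = "control",
    libsize: float = 2.0e6,
    libsize_sd: float = 0.25,
    donor_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate unsorted bulk-nuclei mixtures at a known composition.

    The expected mixture is proportional to ``sum_c w_c * rho_c * profile_c``
    with ``w`` the nuclei fractions and ``rho`` the per-type RNA content
    per nucleus; with ``rho = 1`` the expected mRNA fraction of each type
    equals its nuclei fraction.
    """
    rng = np.random.default_rng(seed)
    w = preset.as_series(ref.cell_types)
    if rna_content is None:
        rho = pd.Series(1.0, index=list(ref.cell_types))
    else:
        rho = pd.Series(rna_content, dtype=float).reindex(list(ref.cell_types))
        if rho.isna().any() or (rho <= 0).any():
            raise ValueError("rna_content must be strictly positive for every cell type")
    mix_weights = (w * rho).to_numpy()
    mixture = ref.profiles_pm().to_numpy() @ (mix_weights / mix_weights.sum())

    ages = _donor_ages(rng, n_samples, condition)
    counts, meta_rows = {}, []
    for j in range(n_samples):
        donor = f"{condition}_u{j:02d}"
        sample = f"unsorted_{donor}"
        lib = _draw_library_sizes(rng, 1, libsize, libsize_sd)[0]
        counts[sample] = _sample_counts(rng, mixture, ref.dispersion, lib, donor_sd)
        meta_rows.append(
            dict(
                sample_id=sample,
                donor_id=donor,
                cell_type="unsorted",
                condition=condition,
                age=int(ages[j]),
                sex=("F" if rng.random() < 0.5 else "M"),
                pmi=round(float(np.exp(rng.normal(np.log(20.0), 0.4))), 1),
                batch=f"b{j % 2 + 1}",
            )
        )
    counts_df = validate_counts(pd.DataFrame(counts, index=ref.genes))
    meta = pd.DataFrame(meta_rows)
    composition = pd.DataFrame(
        np.tile(w.to_numpy(), (n_samples, 1)),
        index=counts_df.columns,
        columns=list(ref.cell_types),
    )
    mixture_pm = pd.DataFrame(
        np.tile(mixture / mixture.sum() * 1e6, (n_samples, 1)),
        index=counts_df.columns,
        columns=ref.genes,
    )
    truth = SyntheticTruth(
        composition=composition,
        rna_content=rho,
        ambient_alpha=0.0,
        donor_table=meta[["donor_id", "condition", "age"]].drop_duplicates(),
        mixture_pm=mixture_pm,
    )
    return counts_df, meta, truth


def single_effect_composition(
    preset: CompositionPreset, target: str, fold: float, direction: str
) -> CompositionPreset:
    """Apply one proportion fold change to a preset, closing the simplex.

    The target fraction is divided (``"decrease"``) or multiplied
    (``"increase"``) by ``fold``; the compensating mass is absorbed by the
    granule fraction.  When the target is granule itself, the mass is
    redistributed across the other types proportionally to their preset
    fractions.  One effect per simulation keeps each printed proportion
    ratio exactly recoverable: the published per-type ratios come from
    independent two-component fits and are not jointly simplex-consistent.
    """
    if target not in preset.fractions:
        raise ValueError(f"unknown target {target!r}")
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    fractions = dict(preset.fractions)
    old = fractions[target]
    new = old * fold if direction == "increase" else old / fold
    if not 0 <= new <= 1:
        raise ValueError(f"target fraction {new} outside [0, 1]")
    delta = old - new  # mass released by the target (negative for increases)
    fractions[target] = new
    if target == "granule":
        others = {c: f for c, f in fractions.items() if c != "granule"}
        total = sum(others.values())
        for c, f in others.items():
            fractions[c] = f + delta * f / total
    else:
        fractions["granule"] += delta
        if not 0 <= fractions["granule"] <= 1:
            raise ValueError("granule fraction left [0, 1] while compensating")
    return CompositionPreset(f"{preset.name}|{target}_{direction}_{fold:g}", fractions)


def simulate_age_cohort(
    ref: GroundTruthReference,
    n_control: int = 20,
    n_at: int = 10,
    n_age_genes: int = 100,
    slope_per_year: float = 0.05,
    at_transcriptomic_offset: float = 50.0,
    seed: int = 0,
    libsize: float = 2.0e6,
    libsize_sd: float = 0.25,
    donor_sd: float = 0.1,
    cell_type: str = "astrocyte",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one sorted cell type with a planted transcriptomic aging program.

    ``n_age_genes`` non-marker genes drift with the donor's *transcriptomic*
    age at ``slope_per_year`` log2 units/year (random sign per gene).
    Control donors sit on the age line (transcriptomic age = chronological
    age, uniform over 10-90); A-T donors are drawn young (uniform 15-30)
    but express an age ``at_transcriptomic_offset`` years older, emulating
    accelerated transcriptomic aging.
    """
    rng = np.random.default_rng(seed)
    marker_genes = {g for genes in ref.markers.values() for g in genes}
    candidates = [g for g in ref.genes if g not in marker_genes]
    if len(candidates) < n_age_genes:
        raise ValueError("not enough non-marker genes for the aging program")
    age_gene_idx = rng.choice(len(candidates), n_age_genes, replace=False)
    age_genes = [candidates[i] for i in age_gene_idx]
    directions = rng.choice([-1.0, 1.0], n_age_genes)

    profile = ref.profiles_pm()[cell_type]
    chron_ages = np.concatenate(
        [rng.uniform(10.0, 90.0, n_control), rng.uniform(15.0, 30.0, n_at)]
    )
    trans_ages = chron_ages.copy()
    trans_ages[n_control:] += at_transcriptomic_offset
    conditions = ["control"] * n_control + ["AT"] * n_at

    mid_age = 50.0  # center the program so overall library composition is stable
    gene_index = {g: i for i, g in enumerate(ref.genes)}
    gene_pos = [gene_index[g] for g in age_genes]
    counts, meta_rows = {}, []
    for j, (chron, trans, cond) in enumerate(zip(chron_ages, trans_ages, conditions)):
        donor = f"{cond}_a{j:02d}"
        sample = f"{cell_type}_{donor}"
        mixture = profile.to_numpy().copy()
        mixture[gene_pos] *= 2.0 ** (directions * slope_per_year * (trans - mid_age))
        lib = _draw_library_sizes(rng, 1, libsize, libsize_sd)[0]
        counts[sample] = _sample_counts(rng, mixture, ref.dispersion, lib, donor_sd)
        meta_rows.append(
            dict(
                sample_id=sample,
                donor_id=donor,
                cell_type=cell_type,
                condition=cond,
                age=round(float(chron), 1),
                sex=("F" if rng.random() < 0.5 else "M"),
                pmi=round(float(np.exp(rng.normal(np.log(20.0), 0.4))), 1),
                batch=f"b{j % 2 + 1}",
            )
        )
    counts_df = validate_counts(pd.DataFrame(counts, index=ref.genes))
    meta = pd.DataFrame(meta_rows)
    frac = dict.fromkeys(ref.cell_types, 0.0)
    frac[cell_type] = 1.0
    composition = pd.DataFrame(
        [pd.Series(frac)] * len(meta), index=counts_df.columns
    )
    truth = SyntheticTruth(
        composition=composition,
        rna_content=pd.Series(1.0, index=list(ref.cell_types)),
        ambient_alpha=0.0,
        donor_table=meta[["donor_id", "condition", "age"]].assign(
            transcriptomic_age=trans_ages
        ),
        age_genes=pd.DataFrame(
            {"gene": age_genes, "direction": directions, "slope": slope_per_year}
        ),
    )
    return counts_df, meta, truth
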