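"""Synthetic Ct-level data with known ground truth for every pipeline stage.

The generator emulates the structure the analysis assumes: treatments with
animals nested inside them, several 10-cell pools per animal per cell type,
a gene panel of ~46 measured transcripts plus housekeeping candidates of
graded stability, planted treatment effects on the -ddCt (log2) scale,
animal-level random effects, an optional bimodal subpopulation within one
(treatment, cell type), cell-type marker genes, and a logistic non-detect
dropout curve in Ct.  Effects are planted in expression units and mapped to
Ct by sign inversion (higher expression = lower Ct), so ground truth is
directly comparable to pipeline output.

A parallel generator builds cecal microbial panels (taxa annotated with rank
and phylum, pan-bacterial control assays) with planted per-treatment
abundance shifts, including a noise-free construction whose per-treatment
phylum medians hit prescribed values exactly after global median centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import TREATMENTS, CtMatrix
from .microbiome import TaxonPanel

logger = logging.getLogger(__name__)

BRAIN_TREATMENTS = ("Placebo", "Morphine", "Withdrawal")

DEFAULT_MARKERS = {"neuron": "NeuN", "microglia": "Maf", "astrocyte": "Gfap"}

#: Candidate housekeeping assays with per-gene Ct noise SD; the planted
#: most-stable pair is Ldha/Actb, Gapdh is the designated independent
#: control (normalized, never selectable as reference).
DEFAULT_HOUSEKEEPING_SD = {
    "Ldha": 0.10,
    "Actb": 0.10,
    "Gapdh": 0.30,
    "Hprt1": 0.40,
    "Tbp": 0.50,
}

_NAMED_GENES = (
    "NeuN", "Maf", "Gfap", "Tnf", "cFos", "Ptges3", "Mapk1", "Oprm1",
    "Pdyn", "Kcnip2", "Gabrb1", "Cat", "Gpx3", "Il6st",
)

#: Default planted treatment effects (-ddCt units): withdrawal shifts the
#: inflammatory program while morphine stays close to placebo.
DEFAULT_EFFECTS = {
    "Tnf": {"Withdrawal": 1.5},
    "cFos": {"Withdrawal": 1.0},
    "Gfap": {"Withdrawal": 0.8},
    "Ptges3": {"Withdrawal": 0.8},
    "Il6st": {"Withdrawal": 0.6},
    "Pdyn": {"Withdrawal": 0.7},
    "Kcnip2": {"Withdrawal": -0.8},
    "Gabrb1": {"Withdrawal": -0.6},
    "Cat": {"Withdrawal": -0.7},
    "Gpx3": {"Withdrawal": -0.5},
}

#: Astrocytes show the largest withdrawal shift in these data.
DEFAULT_CELLTYPE_EFFECT_SCALE = {"neuron": 1.0, "microglia": 1.0, "astrocyte": 1.3}


@dataclass
class BimodalSpec:
    """A planted two-component split for one gene in one condition."""

    gene: str = "Mapk1"
    treatment: str = "Withdrawal"
    cell_type: str = "neuron"
    gap: float = 3.0  # distance between component means, -ddCt units
    weight: float = 0.5  # mixing weight of the high component


@dataclass
class SimulationConfig:
    """Everything the single-cell qPCR generator needs; seed is mandatory."""

    seed: int
    treatments: tuple[str, ...] = TREATMENTS
    n_animals_per_treatment: int = 4
    n_pools_per_animal: int = 8
    cell_types: tuple[str, ...] = ("neuron", "microglia", "astrocyte")
    n_genes: int = 46
    housekeeping_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOUSEKEEPING_SD)
    )
    control_gene: str = "Gapdh"
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EFFECTS.items()}
    )
    celltype_effect_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_EFFECT_SCALE)
    )
    animal_sd: float = 0.3
    resid_sd: float = 0.5
    bimodal: tuple[BimodalSpec, ...] = (BimodalSpec(),)
    marker_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    marker_shift: float = 3.0
    #: shared per-sample activation factor added to the listed genes in one
    #: (treatment, cell type): the source of dense withdrawal-astrocyte
    #: co-expression networks
    coactivation_condition: tuple[str, str] = ("Withdrawal", "astrocyte")
    coactivation_genes: tuple[str, ...] = ("Tnf", "cFos", "Gfap", "Ptges3", "Il6st", "Pdyn")
    coactivation_sd: float = 1.0
    #: per-sample latent state factor with heterogeneous positive gene
    #: loadings (capture/metabolic variation): not removed by reference
    #: normalization, it forms the dominant treatment-free PC, pushing the
    #: treatment axes to the later components
    global_factor_sd: float = 0.6
    global_factor_loadings: tuple[float, float] = (0.3, 1.0)
    dropout_ct50: float = 37.0
    dropout_scale: float = 1.0
    baseline_range: tuple[float, float] = (24.0, 30.0)
    pool_size: int = 10
    samples_per_batch: int = 48

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_pools_per_animal < 1 or self.n_animals_per_treatment < 1:
            raise ValueError("need >= 1 pool per animal and >= 1 animal per treatment")
        if self.animal_sd < 0 or self.resid_sd < 0:
            raise ValueError("SDs must be >= 0")
        for spec in self.bimodal:
            if not 0.0 < spec.weight < 1.0:
                raise ValueError("bimodal mixing weights must lie in (0, 1)")

    def gene_panel(self) -> list[str]:
        genes = list(_NAMED_GENES)
        i = len(genes) + 1
        while len(genes) < self.n_genes:
            genes.append(f"Gene{i:02d}")
            i += 1
        return genes[: self.n_genes]


@dataclass
class GroundTruth:
    """Record of everything planted, for round-trip tests."""

    effects: dict
    stable_pair: tuple[str, str]
    control_gene: str
    marker_map: dict
    bimodal_assignments: dict[str, str]  # sample_id -> "high" | "low"
    true_expression: pd.DataFrame  # planted expression component per (sample, gene)
    dropout_params: tuple[float, float]


def default_brain_config(seed: int, **overrides) -> SimulationConfig:
    """Study-shaped brain panel: 3 treatments x 4 animals x 10-cell pools."""
    overrides.setdefault("treatments", BRAIN_TREATMENTS)
    return SimulationConfig(seed=seed, **overrides)


def generate_sc_qpcr(config: SimulationConfig) -> tuple[CtMatrix, pd.DataFrame, GroundTruth]:
    """Draw a single-cell qPCR dataset from the configured model.

    Ct(s, g) = baseline_g - expression(s, g) + N(0, resid_sd), where the
    expression component sums the planted treatment effect (scaled per cell
    type), the animal random effect, any bimodal component shift, and the
    marker shift.  Housekeeping assays get only their own noise.  Non-detects
    are drawn from a logistic curve in the realized Ct.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_panel()
    hk = list(config.housekeeping_sd)
    all_assays = genes + [g for g in hk if g not in genes]

    baselines = pd.Series(
        rng.uniform(*config.baseline_range, size=len(all_assays)), index=all_assays
    )

    rows = []
    for ct_name in config.cell_types:
        for trt in config.treatments:
            for a in range(1, config.n_animals_per_treatment + 1):
                animal = f"{trt}_rat{a}"
                for p in range(1, config.n_pools_per_animal + 1):
                    rows.append(
                        {
                            "sample_id": f"{ct_name}_{trt}_r{a}_p{p}",
                            "animal_id": animal,
                            "treatment": trt,
                            "cell_type": ct_name,
                            "pool_size": config.pool_size,
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    # batches are filled array-by-array within each cell type
    batch_ids = []
    for ct_name in config.cell_types:
        idx = meta.index[meta["cell_type"] == ct_name]
        for i, sid in enumerate(idx):
            batch_ids.append((sid, f"{ct_name}_b{i // config.samples_per_batch + 1}"))
    meta["batch_id"] = pd.Series(dict(batch_ids))

    n = len(meta)
    # animal random effects per (animal, gene)
    animals = meta["animal_id"].unique()
    animal_eff = pd.DataFrame(
        rng.normal(0.0, config.animal_sd, size=(len(animals), len(genes))),
        index=animals, columns=genes,
    )

    expr = pd.DataFrame(0.0, index=meta.index, columns=all_assays)
    for g in genes:
        expr[g] = animal_eff.loc[meta["animal_id"], g].to_numpy()
    for g, per_trt in config.effects.items():
        if g not in genes:
            continue
        for trt, shift in per_trt.items():
            mask = (meta["treatment"] == trt).to_numpy()
            scale = meta["cell_type"].map(config.celltype_effect_scale).fillna(1.0).to_numpy()
            expr.loc[mask, g] += shift * scale[mask]
    for ct_name, marker in config.marker_map.items():
        if marker in expr.columns:
            expr.loc[meta["cell_type"] == ct_name, marker] += config.marker_shift

    if config.global_factor_sd > 0:
        state = rng.normal(0.0, config.global_factor_sd, size=n)
        loadings = rng.uniform(*config.global_factor_loadings, size=len(genes))
        expr[genes] += np.outer(state, loadings)

    if config.coactivation_sd > 0 and config.coactivation_genes:
        trt_name, ct_name = config.coactivation_condition
        mask = (meta["treatment"] == trt_name) & (meta["cell_type"] == ct_name)
        latent = rng.normal(0.0, config.coactivation_sd, size=int(mask.sum()))
        for g in config.coactivation_genes:
            if g in expr.columns:
                expr.loc[mask, g] += latent

    assignments: dict[str, str] = {}
    for spec in config.bimodal:
        mask = (meta["treatment"] == spec.treatment) & (meta["cell_type"] == spec.cell_type)
        ids = meta.index[mask]
        high = rng.random(len(ids)) < spec.weight
        expr.loc[ids[high], spec.gene] += spec.gap / 2.0
        expr.loc[ids[~high], spec.gene] -= spec.gap / 2.0
        assignments.update({sid: ("high" if h else "low") for sid, h in zip(ids, high)})

    ct_vals = pd.DataFrame(index=meta.index, columns=all_assays, dtype=float)
    for g in genes:
        noise = rng.normal(0.0, config.resid_sd, size=n)
        ct_vals[g] = baselines[g] - expr[g].to_numpy() + noise
    for g in hk:
        ct_vals[g] = baselines[g] + rng.normal(0.0, config.housekeeping_sd[g], size=n)

    # logistic dropout in realized Ct: dimmer reactions fail more often
    p_drop = expit((ct_vals.to_numpy() - config.dropout_ct50) / config.dropout_scale)
    drop = rng.random(p_drop.shape) < p_drop
    ct_vals = ct_vals.mask(drop)

    truth = GroundTruth(
        effects={g: dict(v) for g, v in config.effects.items()},
        stable_pair=("Ldha", "Actb"),
        control_gene=config.control_gene,
        marker_map=dict(config.marker_map),
        bimodal_assignments=assignments,
        true_expression=expr,
        dropout_params=(config.dropout_ct50, config.dropout_scale),
    )
    return CtMatrix(ct_vals), meta, truth


# ---------------------------------------------------------------------------
# microbiome panel


def default_taxon_table() -> pd.DataFrame:
    rows = [
        ("Firmicutes", "phylum", "Firmicutes", False),
        ("Bacteroides", "phylum", "Bacteroides", False),
        ("Clostridium coccoides", "subgroup", "Firmicutes", False),
        ("Clostridium leptum", "subgroup", "Firmicutes", False),
        ("Lactobacillus", "genus", "Firmicutes", False),
        ("Butyricicoccus", "genus", "Firmicutes", False),
        ("Faecalibacterium prausnitzii", "species", "Firmicutes", False),
        ("Enterococcus faecalis", "species", "Firmicutes", False),
        ("Bacteroides fragilis", "subgroup", "Bacteroides", False),
        ("Bacteroides vulgatus", "species", "Bacteroides", False),
        ("Bacteroides thetaiotaomicron", "species", "Bacteroides", False),
        ("Bifidobacterium", "genus", "other", False),
        ("Pan Bacteria", "phylum", "other", True),
        ("Universal", "phylum", "other", True),
    ]
    return pd.DataFrame(
        rows, columns=["assay", "rank", "phylum", "is_control"]
    ).set_index("assay")


#: Default planted per-treatment abundance shifts (-ddCt units): withdrawal
#: suppresses Firmicutes and its members, induces Bacteroides and its members.
DEFAULT_TAXON_SHIFTS = {
    "Firmicutes": {"Withdrawal": -1.0},
    "Clostridium coccoides": {"Withdrawal": -0.8},
    "Clostridium leptum": {"Withdrawal": -0.8},
    "Butyricicoccus": {"Withdrawal": -0.6},
    "Faecalibacterium prausnitzii": {"Withdrawal": -0.6},
    "Bifidobacterium": {"Withdrawal": -0.8},
    "Enterococcus faecalis": {"Withdrawal": 1.0},
    "Bacteroides": {"Withdrawal": 2.0},
    "Bacteroides fragilis": {"Withdrawal": 1.5},
    "Bacteroides vulgatus": {"Withdrawal": 1.5},
    "Bacteroides thetaiotaomicron": {"Withdrawal": 1.5},
}


@dataclass
class MicrobiomeConfig:
    seed: int
    treatments: tuple[str, ...] = TREATMENTS
    n_animals_per_treatment: int = 4
    shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_TAXON_SHIFTS.items()}
    )
    animal_sd: float = 0.2
    resid_sd: float = 0.3
    control_sd: float = 0.05
    baseline_range: tuple[float, float] = (14.0, 24.0)
    control_baseline: float = 12.0
    #: exact per-sample -dCt deviations; when set, noise is off and the
    #: planted values are used verbatim (see planted_group_values)
    planted_values: dict[str, pd.Series] | None = None


def planted_group_values(
    targets: dict[str, float],
    n_per_group: int,
    spread: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-sample values with prescribed group medians AND overall median 0.

    Global median centering subtracts the overall per-gene median, so to
    plant exact post-centering group medians the raw values must already
    have overall median zero.  This deterministic construction requires the
    target medians to split half negative / half positive over equally
    sized groups (n_per_group even): each group gets symmetric offsets
    around its target, and the two groups flanking zero donate the overall
    middle pair (-h, +h).
    """
    if n_per_group < 2 or n_per_group % 2:
        raise ValueError("n_per_group must be even and >= 2")
    t = pd.Series(targets, dtype=float)
    if (t == 0).any():
        raise ValueError("zero target medians are not supported")
    neg, pos = t[t < 0], t[t > 0]
    if len(neg) != len(pos):
        raise ValueError(
            "median-zero construction needs equally many negative and positive targets"
        )
    h = spread if spread is not None else min(0.02, float(t.abs().min()) / (n_per_group + 2))
    half = n_per_group // 2
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)]) * h
    out = {g: t[g] + offsets for g in t.index}
    boundary_neg = neg.idxmax()  # negative target closest to zero
    boundary_pos = pos.idxmin()
    out[boundary_neg] = np.sort(out[boundary_neg])
    out[boundary_neg][-1] = -h  # overall middle pair: -h and +h
    out[boundary_pos] = np.sort(out[boundary_pos])
    out[boundary_pos][0] = h
    for g, v in out.items():
        med = np.median(v)
        if not np.isclose(med, t[g]):  # pragma: no cover - defensive
            raise RuntimeError(f"construction failed for {g}: median {med} != {t[g]}")
    return out


def table1_calibrated_config(
    seed: int,
    firmicutes: dict[str, float],
    bacteroides: dict[str, float],
    member_scale: float = 0.5,
) -> MicrobiomeConfig:
    """Noise-free config whose phylum medians are planted exactly.

    ``firmicutes`` / ``bacteroides`` map treatment -> target median -ddCt of
    the phylum assay.  Member taxa are planted in the same directions scaled
    by ``member_scale`` so subgroup shifts mirror the phylum shifts.
    """
    panel = default_taxon_table()
    cfg = MicrobiomeConfig(seed=seed, animal_sd=0.0, resid_sd=0.0, control_sd=0.0)
    n = cfg.n_animals_per_treatment
    planted: dict[str, pd.Series] = {}

    def series_for(targets: dict[str, float]) -> pd.Series:
        vals = planted_group_values(targets, n)
        data = {}
        for trt in cfg.treatments:
            for i, v in enumerate(vals[trt], start=1):
                data[f"cecal_{trt}_r{i}"] = v
        return pd.Series(data)

    planted["Firmicutes"] = series_for(firmicutes)
    planted["Bacteroides"] = series_for(bacteroides)
    for phylum, targets in (("Firmicutes", firmicutes), ("Bacteroides", bacteroides)):
        members = panel.index[(panel["phylum"] == phylum) & (panel["rank"] != "phylum")]
        scaled = {t: v * member_scale for t, v in targets.items()}
        for m in members:
            planted[m] = series_for(scaled)
    cfg.planted_values = planted
    return cfg


def generate_microbiome(
    config: MicrobiomeConfig,
) -> tuple[CtMatrix, pd.DataFrame, TaxonPanel, GroundTruth]:
    """Draw a cecal taxon panel: one sample per animal, stable controls."""
    rng = np.random.default_rng(config.seed)
    panel = TaxonPanel(default_taxon_table())
    taxa = [a for a in panel.table.index if not panel.table.at[a, "is_control"]]
    controls = panel.control_assays

    rows = []
    for trt in config.treatments:
        for a in range(1, config.n_animals_per_treatment + 1):
            rows.append(
                {
                    "sample_id": f"cecal_{trt}_r{a}",
                    "animal_id": f"{trt}_rat{a}",
                    "treatment": trt,
                    "cell_type": "cecal",
                    "batch_id": "cecal_b1",
                    "pool_size": 1,
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    n = len(meta)

    baselines = pd.Series(
        rng.uniform(*config.baseline_range, size=len(taxa)), index=taxa
    )
    expr = pd.DataFrame(0.0, index=meta.index, columns=taxa)
    if config.planted_values is not None:
        for taxon, series in config.planted_values.items():
            expr[taxon] = series.reindex(meta.index).fillna(0.0)
    else:
        animals = meta["animal_id"].unique()
        animal_eff = pd.DataFrame(
            rng.normal(0.0, config.animal_sd, size=(len(animals), len(taxa))),
            index=animals, columns=taxa,
        )
        for taxon in taxa:
            expr[taxon] = animal_eff.loc[meta["animal_id"], taxon].to_numpy()
            expr[taxon] += rng.normal(0.0, config.resid_sd, size=n)
        for taxon, per_trt in config.shifts.items():
            for trt, shift in per_trt.items():
                expr.loc[meta["treatment"] == trt, taxon] += shift

    ct_vals = pd.DataFrame(index=meta.index, columns=taxa + controls, dtype=float)
    for taxon in taxa:
        ct_vals[taxon] = baselines[taxon] - expr[taxon].to_numpy()
    for c in controls:
        ct_vals[c] = config.control_baseline + rng.normal(0.0, config.control_sd, size=n)

    truth = GroundTruth(
        effects={t: dict(v) for t, v in config.shifts.items()},
        stable_pair=tuple(controls[:2]) if len(controls) >= 2 else (controls[0], controls[0]),
        control_gene="",
        marker_map={},
        bimodal_assignments={},
        true_expression=expr,
        dropout_params=(np.inf, 1.0),
    )
    return CtMatrix(ct_vals), meta, panel, truth
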