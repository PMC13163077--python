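"""Synthetic bulk and reference count data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a cluster-labeled single-cell-like reference in which each cell type
carries a block of highly specific marker genes, and bulk Tag-Seq-like
negative-binomial counts over a 2 regions x 2 conditions x 2 sides x
n-subjects design, with condition effects planted in chosen cell types and a
set of lateralized genes whose condition effect has opposite sign in the two
hemispheres (the condition x side interaction phenotype).

Counts are negative binomial with gene-shared dispersion phi
(var = mu + phi * mu^2); per-gene dispersion variation is available through a
log-normal multiplier. Subject is a label only — hemispheric samples are
independent observations, matching the analysis model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, ReferenceMatrix, SampleDesign

DEFAULT_CELL_TYPES = (
    "OD", "ImmatureOD", "OPC", "Microglia", "Astrocytes", "Endothelial",
    "ExNeuron", "Nos1", "ICCells", "InhNeuron", "Penk", "Sst", "Reln",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults echo the study design: 2 regions (CeA, BLA), 2 conditions
    (SNL vs Sham), 2 sides, 6 subjects per group, 13 reference cell types,
    with an oligodendrocyte-like type down-regulated in both regions and a
    glutamatergic-like type up-regulated in one region.
    """

    n_genes: int = 2000
    n_cell_types: int = 13
    markers_per_type: int = 40
    n_cells_per_type: int = 50
    marker_fold: float = 50.0
    n_subjects_per_group: int = 6
    regions: tuple = ("CeA", "BLA")
    baseline_mean: float = 50.0
    gene_mean_sdlog: float = 1.0
    dispersion: float = 0.1
    dispersion_sdlog: float = 0.0
    lib_size_cv: float = 0.3
    effect_log2fc: float = 1.0
    lateralized_log2fc: float = 1.0
    affected_cell_types_down: dict = field(
        default_factory=lambda: {"OD": ["CeA", "BLA"]}
    )
    affected_cell_types_up: dict = field(
        default_factory=lambda: {"ExNeuron": ["BLA"]}
    )
    n_lateralized_genes: int = 40
    cell_type_names: tuple = DEFAULT_CELL_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be nonnegative")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "marker budget exceeds n_genes: "
                f"{self.markers_per_type} x {self.n_cell_types} > {self.n_genes}"
            )
        if self.n_lateralized_genes > self.n_genes:
            raise ValueError("n_lateralized_genes exceeds n_genes")
        # normalize affected-type specs to {type: [regions]}
        self.affected_cell_types_down = self._norm_affected(self.affected_cell_types_down)
        self.affected_cell_types_up = self._norm_affected(self.affected_cell_types_up)
        down = set(self.affected_cell_types_down)
        up = set(self.affected_cell_types_up)
        if down & up:
            raise ValueError(f"cell types in both up and down lists: {sorted(down & up)}")
        types = set(self.cell_types)
        unknown = (down | up) - types
        if unknown:
            raise ValueError(f"affected cell types not among declared types: {sorted(unknown)}")

    def _norm_affected(self, spec) -> dict:
        if isinstance(spec, dict):
            return {t: list(r) for t, r in spec.items()}
        return {t: list(self.regions) for t in spec}

    @property
    def cell_types(self) -> list[str]:
        names = list(self.cell_type_names)[: self.n_cell_types]
        while len(names) < self.n_cell_types:
            names.append(f"Type{len(names) + 1}")
        return names

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(d["regions"])
        d["cell_type_names"] = list(d["cell_type_names"])
        return d


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative binomial draws with mean mu and variance mu + phi*mu^2."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        p = r / (r + mu[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _marker_map(config: SimulationConfig) -> pd.Series:
    """Gene -> cell type for planted markers; '' for non-markers."""
    genes = _gene_ids(config.n_genes)
    assignment = pd.Series("", index=genes, dtype=object)
    i = 0
    for ct in config.cell_types:
        assignment.iloc[i : i + config.markers_per_type] = ct
        i += config.markers_per_type
    return assignment


def generate_reference(config: SimulationConfig):
    """Generate a labeled reference matrix with planted cell-type markers.

    Marker genes have mean expression ``marker_fold`` times higher in their
    own type than elsewhere, so the expected specificity share is
    fold / (fold + n_types - 1); non-marker genes are uniform across types.

    Returns (ReferenceMatrix, GroundTruth DataFrame with columns
    ``cell_type`` and ``is_marker``).
    """
    rng = np.random.default_rng([config.seed, 101])
    genes = _gene_ids(config.n_genes)
    assignment = _marker_map(config)
    types = config.cell_types

    base = 1.0  # mean counts per cell for a non-marker gene, before depth
    mean_by_type = np.full((config.n_genes, len(types)), base)
    for j, ct in enumerate(types):
        mean_by_type[(assignment == ct).to_numpy(), j] *= config.marker_fold

    cells, labels, blocks = [], [], []
    for j, ct in enumerate(types):
        depth = rng.lognormal(mean=0.0, sigma=0.3, size=config.n_cells_per_type)
        mu = mean_by_type[:, [j]] * depth[None, :]
        blocks.append(_nb_sample(rng, mu, config.dispersion))
        cells.extend(f"{ct}_c{i}" for i in range(config.n_cells_per_type))
        labels.extend([ct] * config.n_cells_per_type)

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    reference = ReferenceMatrix(counts, pd.Series(labels, index=cells))
    truth = pd.DataFrame(
        {"cell_type": assignment, "is_marker": (assignment != "").to_numpy()},
        index=genes,
    )
    return reference, truth


def generate_bulk(config: SimulationConfig, reference_truth: pd.DataFrame | None = None):
    """Generate bulk NB counts over the full two-factor design.

    Samples cover regions x {Sham, SNL} x {Left, Right} x subjects. Planted
    effects (log2 scale): genes whose true cell type is in the down list get
    ``-effect_log2fc`` under SNL in the configured regions, the up list
    ``+effect_log2fc``; ``n_lateralized_genes`` additional genes receive an
    opposite-signed per-side condition effect (+/- ``lateralized_log2fc``),
    realizing the condition x side interaction.

    Returns (CountMatrix, SampleDesign, GroundTruth DataFrame). The ground
    truth holds per-region, per-side true condition log2 fold changes in
    columns ``lfc_left_<region>`` / ``lfc_right_<region>``, plus
    ``cell_type``, ``side_lfc`` and ``is_interaction``.
    """
    if reference_truth is None:
        reference_truth = pd.DataFrame(
            {"cell_type": _marker_map(config)}, index=_gene_ids(config.n_genes)
        )
    rng = np.random.default_rng([config.seed, 202])
    genes = _gene_ids(config.n_genes)
    assignment = reference_truth["cell_type"].reindex(genes).fillna("")

    # per-gene baseline means: log-normal spread around baseline_mean
    sdlog = config.gene_mean_sdlog
    base = config.baseline_mean * rng.lognormal(
        mean=-0.5 * sdlog**2, sigma=sdlog, size=config.n_genes
    )
    phi = config.dispersion * (
        rng.lognormal(mean=0.0, sigma=config.dispersion_sdlog, size=config.n_genes)
        if config.dispersion_sdlog > 0
        else np.ones(config.n_genes)
    )

    truth = pd.DataFrame({"cell_type": assignment, "side_lfc": 0.0}, index=genes)
    lfc = {}  # (region, side) -> per-gene condition log2fc
    for region in config.regions:
        for side in ("Left", "Right"):
            lfc[(region, side)] = np.zeros(config.n_genes)
    for spec, sign in ((config.affected_cell_types_down, -1.0),
                       (config.affected_cell_types_up, +1.0)):
        for ct, regions in spec.items():
            mask = (assignment == ct).to_numpy()
            for region in regions:
                for side in ("Left", "Right"):
                    lfc[(region, side)][mask] += sign * config.effect_log2fc

    # lateralized (interaction) genes drawn from unaffected, non-marker genes
    free = (assignment == "").to_numpy()
    for arr in lfc.values():
        free &= arr == 0
    free_idx = np.flatnonzero(free)
    if config.n_lateralized_genes > free_idx.size:
        raise ValueError("not enough unaffected genes for n_lateralized_genes")
    lat_idx = rng.choice(free_idx, size=config.n_lateralized_genes, replace=False)
    lat_sign = np.where(np.arange(config.n_lateralized_genes) % 2 == 0, 1.0, -1.0)
    for region in config.regions:
        lfc[(region, "Left")][lat_idx] += lat_sign * config.lateralized_log2fc
        lfc[(region, "Right")][lat_idx] -= lat_sign * config.lateralized_log2fc

    for region in config.regions:
        truth[f"lfc_left_{region}"] = lfc[(region, "Left")]
        truth[f"lfc_right_{region}"] = lfc[(region, "Right")]
    truth["is_interaction"] = False
    truth.iloc[lat_idx, truth.columns.get_loc("is_interaction")] = True

    sigma = np.sqrt(np.log1p(config.lib_size_cv**2))
    rows, columns, design_rows = [], [], []
    for region in config.regions:
        for condition in ("Sham", "SNL"):
            for side in ("Left", "Right"):
                for subj in range(1, config.n_subjects_per_group + 1):
                    subject = f"{condition}{subj}"
                    sample = f"{region}_{condition}_{side}_s{subj}"
                    libfac = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                    mu = base * libfac
                    if condition == "SNL":
                        mu = mu * np.exp2(lfc[(region, side)])
                    rows.append(_nb_sample(rng, mu, phi))
                    columns.append(sample)
                    design_rows.append(
                        {"sample_id": sample, "region": region,
                         "condition": condition, "side": side, "subject": subject}
                    )
    counts = CountMatrix(pd.DataFrame(np.column_stack(rows), index=genes, columns=columns))
    design = SampleDesign(pd.DataFrame(design_rows))
    return counts, design, truth


def write_truth(truth: pd.DataFrame, path: str) -> None:
    out = truth.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
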