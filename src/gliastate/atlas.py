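"""Synthetic multi-dataset glial atlas generator.

Produces cell x gene count matrices with per-cell metadata (dataset, donor,
region, subcluster, disease, sex, age) and a fully recorded ground truth:
planted subcluster-proportion shifts (log-odds scale), a planted activation
gene-expression program (GEP) with per-cell usages, planted differential-
expression log fold-changes, and per-dataset batch offsets.  Every downstream
stage of the pipeline (composition, shrinkage, DE, factorization, scoring)
can be exercised against these planted truths without any external data.

The generative model, per cell c in sample (donor x region):

    total cells per sample   ~ NegBin(mean, size)            (cluster_size_nb)
    subcluster assignment    ~ Multinomial(p'), p' the baseline composition
                               shifted on the odds scale by the planted
                               per-(disease, subcluster) log-odds effects
    library size L_c         ~ LogNormal(meanlog, sdlog)
    usage u_c                = max(0, baseline + disease shift + noise)
                               for cells of GEP-active subclusters, else 0
    rate p_g                 = softmax(alpha_g + subcluster offset
                                       + batch_{dataset,g} + DE_{disease,g}
                                       + u_c * loading_g)
    counts_cg                ~ NegBin(mean = L_c * p_g, size = theta_g)

The softmax renormalization keeps planted log fold-changes exact on the
relative-abundance scale under library-size variation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtlasConfig",
    "GepSpec",
    "GroundTruth",
    "SyntheticAtlas",
    "PseudobulkMatrix",
    "EffectTable",
    "generate_atlas",
    "pseudobulk",
    "sample_subcluster_sizes",
    "simulate_effect_table",
]

LN2 = float(np.log(2.0))


@dataclass
class GepSpec:
    """A planted gene-expression program.

    loadings: non-negative per-gene vector (log-scale contribution per unit
    usage); active_subclusters: labels whose cells express the program;
    usage_shift: additive per-disease shift of the mean usage; baseline_usage
    and usage_sd set the usage distribution before truncation at zero.
    """

    loadings: np.ndarray
    active_subclusters: tuple[str, ...]
    usage_shift: Mapping[str, float] = field(default_factory=dict)
    baseline_usage: float = 1.0
    usage_sd: float = 0.25

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if np.any(self.loadings < 0):
            raise ValueError("GEP loadings must be non-negative")


@dataclass
class AtlasConfig:
    """Configuration of the synthetic atlas; defaults are a desk-scale cohort
    of three datasets x two regions x three diagnostic groups."""

    n_datasets: int = 3
    regions_per_dataset: tuple[tuple[str, str], ...] = (
        ("FC", "cortical"),
        ("TH", "subcortical"),
    )
    donors_per_group: int = 6
    disease_groups: tuple[str, ...] = ("HC", "AD", "FTD")
    control_group: str = "HC"
    n_genes: int = 300
    subclusters: tuple[tuple[str, float], ...] = (
        ("Micro_Homeo", 0.55),
        ("Micro_DAM_Int1", 0.20),
        ("Micro_DAM_SPP1", 0.10),
        ("Micro_DAM_GPNMB", 0.10),
        ("Micro_BAM", 0.05),
    )
    cluster_size_nb: tuple[float, float] = (300.0, 4.0)  # (mean cells, size)
    proportion_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    gep_spec: GepSpec | None = None
    de_log2fc: Mapping[str, np.ndarray] = field(default_factory=dict)
    batch_sd: float = 0.3
    subcluster_sd: float = 0.3
    libsize_lognormal: tuple[float, float] = (7.6, 0.35)  # (meanlog, sdlog)
    gene_nb_dispersion: float | np.ndarray = 2.0
    age_range: tuple[float, float] = (60.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1 or self.n_genes < 1 or self.donors_per_group < 1:
            raise ValueError("dimensions must be positive")
        props = np.array([p for _, p in self.subclusters], dtype=float)
        if not np.isclose(props.sum(), 1.0, atol=1e-8):
            raise ValueError("baseline subcluster proportions must sum to 1")
        if self.control_group not in self.disease_groups:
            raise ValueError("exactly one disease group must be the control")
        mean, size = self.cluster_size_nb
        if mean <= 0 or size <= 0:
            raise ValueError("NB mean/size parameters must be strictly positive")
        theta = np.asarray(self.gene_nb_dispersion, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("NB mean/size parameters must be strictly positive")
        if self.gep_spec is not None and self.gep_spec.loadings.shape != (self.n_genes,):
            raise ValueError("gep_spec loadings must have length n_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AtlasConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "regions_per_dataset" in raw:
            raw["regions_per_dataset"] = tuple(tuple(r) for r in raw["regions_per_dataset"])
        if "subclusters" in raw:
            raw["subclusters"] = tuple((s, float(p)) for s, p in raw["subclusters"])
        if "proportion_effects" in raw:
            raw["proportion_effects"] = {
                (d, s): float(v) for (d, s), v in
                ((tuple(k.split(":")), v) for k, v in raw["proportion_effects"].items())
            }
        for key in ("cluster_size_nb", "libsize_lognormal", "age_range"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        if "disease_groups" in raw:
            raw["disease_groups"] = tuple(raw["disease_groups"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery tests."""

    proportion_shifts: Mapping[tuple[str, str], float]
    gep_loadings: np.ndarray | None
    gep_usage: np.ndarray  # per cell
    de_log2fc: Mapping[str, np.ndarray]
    batch_offsets: np.ndarray  # datasets x genes
    subcluster_offsets: np.ndarray  # subclusters x genes
    base_log_expression: np.ndarray
    seed: int


@dataclass
class SyntheticAtlas:
    counts: np.ndarray  # cells x genes, int
    cell_meta: pd.DataFrame
    truth: GroundTruth
    config: AtlasConfig
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_names:
            self.gene_names = [f"gene{g}" for g in range(self.counts.shape[1])]

    def write(self, outdir: str | Path) -> None:
        """Write counts (MTX), cell metadata and truth (TSV) and a config echo (JSON)."""
        from scipy import io as sio
        from scipy import sparse

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(self.counts))
        meta = self.cell_meta.copy()
        meta["gep_usage"] = self.truth.gep_usage
        meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
        pd.Series(self.gene_names, name="gene").to_csv(
            outdir / "genes.tsv", sep="\t", index=False
        )
        truth = {
            "proportion_shifts": {f"{d}:{s}": v for (d, s), v in
                                  self.truth.proportion_shifts.items()},
            "seed": self.truth.seed,
        }
        cfg = {
            "n_datasets": self.config.n_datasets,
            "donors_per_group": self.config.donors_per_group,
            "disease_groups": list(self.config.disease_groups),
            "control_group": self.config.control_group,
            "n_genes": self.config.n_genes,
            "seed": self.config.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        (outdir / "config.json").write_text(json.dumps(cfg, indent=1))


@dataclass
class PseudobulkMatrix:
    """Gene x sample aggregated counts with per-sample metadata."""

    counts: pd.DataFrame  # genes x samples
    sample_meta: pd.DataFrame  # one row per sample (index = sample id)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def sample_subcluster_sizes(
    mean: float, size: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n subcluster/sample cell totals from NegBin(mean, size).

    `size` is the NB dispersion (shape) parameter: var = mean + mean^2/size.
    """
    if mean <= 0 or size <= 0:
        raise ValueError("NB mean and size must be strictly positive")
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n)


def _shifted_proportions(
    base: np.ndarray, labels: Sequence[str], disease: str,
    effects: Mapping[tuple[str, str], float],
) -> np.ndarray:
    """Apply per-subcluster log-odds shifts on the odds scale, renormalize."""
    odds = base.copy()
    for i, lab in enumerate(labels):
        shift = effects.get((disease, lab), 0.0)
        if shift:
            odds[i] = base[i] * np.exp(shift)
    return odds / odds.sum()


def generate_atlas(config: AtlasConfig) -> SyntheticAtlas:
    """Generate a synthetic atlas; identical config + seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    sub_labels = [s for s, _ in config.subclusters]
    base_props = np.array([p for _, p in config.subclusters], dtype=float)
    n_sub = len(sub_labels)

    alpha = rng.normal(0.0, 1.0, size=G)
    batch = rng.normal(0.0, config.batch_sd, size=(config.n_datasets, G))
    sub_off = rng.normal(0.0, config.subcluster_sd, size=(n_sub, G))
    theta = np.broadcast_to(
        np.asarray(config.gene_nb_dispersion, dtype=float), (G,)
    ).copy()

    de_ln = {d: np.asarray(v, dtype=float) * LN2 for d, v in config.de_log2fc.items()}
    gep = config.gep_spec
    active_idx = (
        {sub_labels.index(s) for s in gep.active_subclusters} if gep is not None else set()
    )

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    usages: list[np.ndarray] = []
    mean_cells, size_cells = config.cluster_size_nb

    for d in range(config.n_datasets):
        ds = f"dataset{d}"
        for grp in config.disease_groups:
            for j in range(config.donors_per_group):
                donor = f"{ds}_{grp}_donor{j}"
                age = rng.uniform(*config.age_range)
                sex = "F" if rng.random() < 0.5 else "M"
                props = _shifted_proportions(
                    base_props, sub_labels, grp, config.proportion_effects
                )
                for region, region_class in config.regions_per_dataset:
                    total = int(
                        sample_subcluster_sizes(mean_cells, size_cells, 1, rng)[0]
                    )
                    if total == 0:
                        continue
                    sub_counts = rng.multinomial(total, props)
                    for si, n_cells in enumerate(sub_counts):
                        if n_cells == 0:
                            continue
                        eta = alpha + batch[d] + sub_off[si]
                        if grp in de_ln:
                            eta = eta + de_ln[grp]
                        if gep is not None and si in active_idx:
                            u = np.maximum(
                                0.0,
                                gep.baseline_usage
                                + gep.usage_shift.get(grp, 0.0)
                                + rng.normal(0.0, gep.usage_sd, size=n_cells),
                            )
                            eta_cells = eta[None, :] + u[:, None] * gep.loadings[None, :]
                        else:
                            u = np.zeros(n_cells)
                            eta_cells = np.broadcast_to(eta, (n_cells, G))
                        logits = eta_cells - eta_cells.max(axis=1, keepdims=True)
                        p = np.exp(logits)
                        p /= p.sum(axis=1, keepdims=True)
                        lib = rng.lognormal(*config.libsize_lognormal, size=n_cells)
                        mu = lib[:, None] * p
                        nbp = theta[None, :] / (theta[None, :] + mu)
                        blocks.append(
                            rng.negative_binomial(theta[None, :], nbp).astype(np.int32)
                        )
                        usages.append(u)
                        meta_rows.extend(
                            {
                                "dataset": ds,
                                "donor": donor,
                                "region": region,
                                "region_class": region_class,
                                "subcluster": sub_labels[si],
                                "disease": grp,
                                "sex": sex,
                                "age": age,
                            }
                            for _ in range(n_cells)
                        )

    counts = np.vstack(blocks) if blocks else np.zeros((0, G), dtype=np.int32)
    cell_meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        proportion_shifts=dict(config.proportion_effects),
        gep_loadings=gep.loadings if gep is not None else None,
        gep_usage=np.concatenate(usages) if usages else np.zeros(0),
        de_log2fc=dict(config.de_log2fc),
        batch_offsets=batch,
        subcluster_offsets=sub_off,
        base_log_expression=alpha,
        seed=config.seed,
    )
    return SyntheticAtlas(counts=counts, cell_meta=cell_meta, truth=truth, config=config)


def pseudobulk(
    counts: np.ndarray | SyntheticAtlas,
    cell_meta: pd.DataFrame | None = None,
    group_keys: Sequence[str] = ("donor", "region"),
    gene_names: Sequence[str] | None = None,
) -> PseudobulkMatrix:
    """Aggregate cell counts by summation over the given metadata keys.

    Totals are conserved exactly: the sum of all pseudobulk entries equals
    the sum of the input counts.
    """
    if isinstance(counts, SyntheticAtlas):
        atlas = counts
        counts, cell_meta = atlas.counts, atlas.cell_meta
        gene_names = gene_names or atlas.gene_names
    if cell_meta is None:
        raise ValueError("cell_meta is required when counts is an array")
    group_keys = list(group_keys)
    if not group_keys:
        raise ValueError("at least one grouping key is required")
    missing = [k for k in group_keys if k not in cell_meta.columns]
    if missing:
        raise KeyError(f"grouping keys not in metadata: {missing}")

    if gene_names is None:
        gene_names = [f"gene{g}" for g in range(counts.shape[1])]
    key = cell_meta[group_keys].astype(str).agg("|".join, axis=1)
    order = pd.unique(key)
    code = pd.Categorical(key, categories=order).codes
    agg = np.zeros((len(order), counts.shape[1]), dtype=np.int64)
    np.add.at(agg, code, counts)
    pb = pd.DataFrame(agg.T, index=list(gene_names), columns=list(order))

    meta_cols = [
        c for c in ("dataset", "donor", "region", "region_class", "disease", "sex", "age")
        if c in cell_meta.columns
    ]
    sample_meta = (
        cell_meta.assign(_sample=key)
        .groupby("_sample", sort=False)
        .agg({c: "first" for c in meta_cols} | {"_sample": "size"})
        .rename(columns={"_sample": "n_cells"})
        .loc[list(order)]
    )
    sample_meta.index.name = "sample"
    return PseudobulkMatrix(counts=pb, sample_meta=sample_meta)


@dataclass
class EffectTable:
    """Per-feature per-condition effect estimates B-hat and standard errors S-hat.

    When the inputs are z-scores, S-hat is all ones.
    """

    bhat: np.ndarray  # features x conditions
    shat: np.ndarray
    conditions: list[str] = field(default_factory=list)
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bhat = np.atleast_2d(np.asarray(self.bhat, dtype=float))
        self.shat = np.atleast_2d(np.asarray(self.shat, dtype=float))
        if self.bhat.shape != self.shat.shape:
            raise ValueError("bhat and shat must have the same shape")
        if np.any(self.shat <= 0):
            raise ValueError("standard errors must be strictly positive")
        if not self.conditions:
            self.conditions = [f"cond{r}" for r in range(self.bhat.shape[1])]
        if not self.features:
            self.features = [f"feat{j}" for j in range(self.bhat.shape[0])]

    @property
    def n_conditions(self) -> int:
        return self.bhat.shape[1]


def simulate_effect_table(
    R: int,
    n_features: int,
    component_mix: Sequence[tuple[np.ndarray, float]],
    noise_se: float | np.ndarray = 1.0,
    seed: int = 0,
) -> tuple[EffectTable, dict]:
    """Draw true effects from an MVN mixture and add observation noise.

    Returns the observed EffectTable and a truth dict with the true effects
    and per-feature component assignments (recovery-test oracle).
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in component_mix], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError("mixture weights must sum to 1")
    covs = []
    for U, _ in component_mix:
        U = np.asarray(U, dtype=float)
        if U.shape != (R, R):
            raise ValueError("covariance shape mismatch")
        ev = np.linalg.eigvalsh((U + U.T) / 2)
        if ev.min() < -1e-8:
            raise ValueError("covariance components must be PSD")
        covs.append((U + U.T) / 2)
    assign = rng.choice(len(covs), size=n_features, p=weights)
    true = np.zeros((n_features, R))
    for k, U in enumerate(covs):
        idx = np.where(assign == k)[0]
        if len(idx) and np.any(U):
            true[idx] = rng.multivariate_normal(np.zeros(R), U, size=len(idx), method="eigh")
    se = np.broadcast_to(np.asarray(noise_se, dtype=float), (n_features, R)).copy()
    obs = true + rng.normal(0.0, 1.0, size=(n_features, R)) * se
    table = EffectTable(bhat=obs, shat=se)
    return table, {"true_effects": true, "assignments": assign, "seed": seed}
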