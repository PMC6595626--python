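"""Seeded synthetic six-stage germination datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* stage-peaked expression clusters (Gaussian bump over the stage axis on the
  log2 scale),
* coexpression modules whose shared latent profile correlates with a one-hot
  stage indicator at a controllable Pearson r,
* an annotation bin over-represented in one planted cluster,
* transcription factors expressed above threshold at exactly one stage,
* metabolite stage trajectories, each coupled to one "causal" enzyme-family
  gene at a controllable correlation while decoy family members follow
  independent trajectories,
* a triphasic fresh-weight imbibition curve.

All randomness flows from one ``SeedSequence``; each table draws from its own
child stream so enlarging one table never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import N_STAGES, DesignError, StageDesign
from .matrix import ExpressionMatrix, MetaboliteTable

ROLES = ("synthesis", "decomposition")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study design: 6 stages, 3 expression replicates and 6
    metabolite replicates per stage, 19 pathway metabolites, 24-cluster-scale
    gene structure at desk size.
    """

    n_genes: int = 600
    n_metabolites: int = 19
    n_clusters_planted: int = 6
    n_modules_planted: int = 3
    module_size: int = 40
    module_stage_r: float = 0.9
    noise_sd: float = 0.2
    n_bins: int = 10
    enrichment_fold: float = 4.0
    causal_gene_rho: float = 0.9
    n_decoy_members: int = 4
    expression_replicates: int = 3
    metabolite_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_metabolites",
            "n_clusters_planted",
            "n_modules_planted",
            "module_size",
            "n_bins",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.module_stage_r <= 1.0:
            raise ValueError("module_stage_r must be in [0, 1]")
        if not 0.0 <= self.causal_gene_rho <= 1.0:
            raise ValueError("causal_gene_rho must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.expression_replicates < 2 or self.metabolite_replicates < 2:
            raise DesignError("replicate counts must be >= 2")


@dataclass
class GroundTruth:
    """Planted structure record for parameter-recovery tests."""

    cluster_of_gene: dict[str, int] = field(default_factory=dict)
    stage_of_cluster: dict[int, int] = field(default_factory=dict)
    module_of_gene: dict[str, int] = field(default_factory=dict)
    stage_of_module: dict[int, int] = field(default_factory=dict)
    bin_of_gene: dict[str, str] = field(default_factory=dict)
    enriched_cluster: int = 0
    enriched_bin: str = ""
    causal_gene_of_metabolite: dict[str, str] = field(default_factory=dict)
    direction_of_metabolite: dict[str, list[str]] = field(default_factory=dict)
    single_stage_tf_genes: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cluster_of_gene={k: int(v) for k, v in d["cluster_of_gene"].items()},
            stage_of_cluster={int(k): int(v) for k, v in d["stage_of_cluster"].items()},
            module_of_gene={k: int(v) for k, v in d["module_of_gene"].items()},
            stage_of_module={int(k): int(v) for k, v in d["stage_of_module"].items()},
            bin_of_gene=dict(d["bin_of_gene"]),
            enriched_cluster=int(d["enriched_cluster"]),
            enriched_bin=d["enriched_bin"],
            causal_gene_of_metabolite=dict(d["causal_gene_of_metabolite"]),
            direction_of_metabolite={
                k: list(v) for k, v in d["direction_of_metabolite"].items()
            },
            single_stage_tf_genes={
                k: int(v) for k, v in d["single_stage_tf_genes"].items()
            },
        )


@dataclass
class SimDataset:
    """One generated dataset: both omics tables, annotation and truth."""

    expression: ExpressionMatrix
    metabolites: MetaboliteTable
    annotation: pd.DataFrame  # gene_id, bin_code, bin_name
    truth: GroundTruth
    config: SimConfig


@dataclass(frozen=True)
class FreshWeightSeries:
    """Fresh weight (g) of imbibing seeds sampled over time (minutes)."""

    time: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if len(self.time) != len(self.weight):
            raise ValueError("time and weight must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly ascending")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")


def _standardize(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample sd (ddof=1)."""
    v = v - v.mean()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return v / sd


def _latent_with_exact_correlation(
    target: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-sd vector whose in-sample Pearson correlation with ``target`` is r.

    Draws a random direction, projects out ``target``, and mixes
    r * target + sqrt(1-r^2) * residual so the sample correlation is exact.
    """
    z = _standardize(target.astype(float))
    if r >= 1.0:
        return z
    for _ in range(64):
        w = rng.standard_normal(len(z))
        w = w - w.mean()
        w = w - (w @ z) / (z @ z) * z
        if w.std(ddof=1) > 1e-12:
            break
    w = _standardize(w)
    return r * z + np.sqrt(1.0 - r * r) * w


def _stage_vector(design: StageDesign) -> np.ndarray:
    return np.array([design.stage_of_sample[s] for s in design.samples])


def _rank_coupled_profile(
    traj: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Profile holding the values of ``traj`` rearranged so that its Spearman
    correlation with ``traj`` is the achievable value nearest ``rho``.

    With six stages Spearman correlations form a discrete set; the
    permutation of rank positions closest to the target is drawn uniformly
    among the minimizers. ``rho = 1`` returns ``traj`` itself (identity
    permutation), so a noiseless causal gene is an exact monotone transform
    of its metabolite trajectory.
    """
    n = len(traj)
    if rho >= 1.0:
        return traj.copy()
    import itertools

    ident = np.arange(n)
    scale = n * (n * n - 1) / 6.0
    best_gap, best_perms = np.inf, []
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = 1.0 - ((p - ident) ** 2).sum() / scale
        gap = abs(r - rho)
        if gap < best_gap - 1e-12:
            best_gap, best_perms = gap, [p]
        elif gap <= best_gap + 1e-12:
            best_perms.append(p)
    perm = best_perms[rng.integers(len(best_perms))]
    order = np.argsort(traj)  # ranks: order[j] is the stage with rank j
    profile = np.empty(n)
    profile[order] = np.sort(traj)[perm]
    return profile


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate one seeded dataset.

    Gene budget is allocated to planted modules, single-stage transcription
    factors and enzyme families first; every remaining gene joins a planted
    stage-peaked cluster. Raises if ``n_genes`` cannot cover one gene per
    planted cluster.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_metab, rng_bins, _ = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    expr_design = StageDesign.balanced(config.expression_replicates)
    metab_design = StageDesign.balanced(config.metabolite_replicates)
    stage_of_expr_sample = _stage_vector(expr_design)
    n_expr_samples = expr_design.n_samples

    n_module_genes = config.n_modules_planted * config.module_size
    n_tf_genes = N_STAGES
    n_enzyme_genes = config.n_metabolites * (1 + config.n_decoy_members)
    n_cluster_genes = config.n_genes - n_module_genes - n_tf_genes - n_enzyme_genes
    if n_cluster_genes < config.n_clusters_planted:
        raise ValueError(
            "n_genes too small: need at least "
            f"{n_module_genes + n_tf_genes + n_enzyme_genes + config.n_clusters_planted}"
        )

    genes = [f"gene{i:05d}" for i in range(1, config.n_genes + 1)]
    log2_expr = np.empty((config.n_genes, n_expr_samples))
    truth = GroundTruth()
    row = 0

    # --- planted stage-peaked clusters (Gaussian bump on log2 scale) ---
    bump_width = 0.75
    stage_axis = np.arange(1, N_STAGES + 1)
    for c in range(1, config.n_clusters_planted + 1):
        peak = (c - 1) % N_STAGES + 1
        truth.stage_of_cluster[c] = peak
    cluster_ids = np.arange(n_cluster_genes) % config.n_clusters_planted + 1
    for g in range(n_cluster_genes):
        c = int(cluster_ids[g])
        peak = truth.stage_of_cluster[c]
        base = rng_expr.uniform(2.0, 6.0)
        amp = rng_expr.uniform(2.0, 4.0)
        profile = base + amp * np.exp(-((stage_axis - peak) ** 2) / (2 * bump_width**2))
        log2_expr[row] = profile[stage_of_expr_sample - 1] + rng_expr.normal(
            0.0, config.noise_sd, n_expr_samples
        )
        truth.cluster_of_gene[genes[row]] = c
        row += 1

    # --- planted coexpression modules sharing a latent stage-linked profile ---
    for m in range(1, config.n_modules_planted + 1):
        target_stage = (m - 1) % N_STAGES + 1
        truth.stage_of_module[m] = target_stage
        onehot = (stage_of_expr_sample == target_stage).astype(float)
        latent = _latent_with_exact_correlation(onehot, config.module_stage_r, rng_expr)
        for _ in range(config.module_size):
            base = rng_expr.uniform(3.0, 6.0)
            amp = rng_expr.uniform(1.0, 2.0)
            log2_expr[row] = base + amp * latent + rng_expr.normal(
                0.0, config.noise_sd, n_expr_samples
            )
            truth.module_of_gene[genes[row]] = m
            row += 1

    # --- single-stage transcription factors (>= 1 FPKM at one stage only) ---
    on_log2, off_log2 = np.log2(50.0), np.log2(0.005)
    for stage in range(1, N_STAGES + 1):
        profile = np.full(N_STAGES, off_log2)
        profile[stage - 1] = on_log2
        log2_expr[row] = profile[stage_of_expr_sample - 1] + rng_expr.normal(
            0.0, config.noise_sd, n_expr_samples
        )
        truth.single_stage_tf_genes[genes[row]] = stage
        row += 1

    # --- metabolites: AR(1) chain of stage trajectories along the pathway ---
    metab_ids = [f"metab{j:03d}" for j in range(1, config.n_metabolites + 1)]
    n_metab_samples = metab_design.n_samples
    stage_of_metab_sample = _stage_vector(metab_design)
    chain_mixing = 0.7
    trajectories = np.empty((config.n_metabolites, N_STAGES))
    prev = None
    for j in range(config.n_metabolites):
        fresh = _standardize(rng_metab.standard_normal(N_STAGES))
        if prev is None:
            traj = fresh
        else:
            traj = chain_mixing * prev + np.sqrt(1 - chain_mixing**2) * fresh
        trajectories[j] = traj
        prev = traj

    log2_metab = np.empty((config.n_metabolites, n_metab_samples))
    metab_amp = rng_metab.uniform(1.5, 2.5, config.n_metabolites)
    metab_base = rng_metab.uniform(10.0, 16.0, config.n_metabolites)
    for j in range(config.n_metabolites):
        profile = metab_base[j] + metab_amp[j] * trajectories[j]
        log2_metab[j] = profile[stage_of_metab_sample - 1] + rng_metab.normal(
            0.0, config.noise_sd, n_metab_samples
        )
        delta = profile - profile[0]
        truth.direction_of_metabolite[metab_ids[j]] = [
            "up" if d >= 1.0 else ("down" if d <= -1.0 else "flat") for d in delta
        ]

    # --- enzyme families: one causal member coupled to the trajectory ---
    enzyme_rows = []
    for j, mid in enumerate(metab_ids):
        family_profiles = []
        causal = _rank_coupled_profile(
            trajectories[j], config.causal_gene_rho, rng_metab
        )
        family_profiles.append(causal)
        for _ in range(config.n_decoy_members):
            family_profiles.append(_standardize(rng_metab.standard_normal(N_STAGES)))
        for k, stage_profile in enumerate(family_profiles):
            gid = genes[row]
            base = rng_expr.uniform(3.0, 6.0)
            amp = rng_expr.uniform(1.5, 2.5)
            profile = base + amp * stage_profile
            log2_expr[row] = profile[stage_of_expr_sample - 1] + rng_expr.normal(
                0.0, config.noise_sd, n_expr_samples
            )
            role = ROLES[(j + k) % 2]
            enzyme_rows.append({"gene_id": gid, "metabolite_id": mid, "role": role})
            if k == 0:
                truth.causal_gene_of_metabolite[mid] = gid
            row += 1
    assert row == config.n_genes

    # --- annotation bins with one planted over-representation ---
    bins = [f"bin{b:02d}" for b in range(1, config.n_bins + 1)]
    bin_names = {b: f"category_{b}" for b in bins}
    truth.enriched_cluster = 1
    truth.enriched_bin = bins[0]
    enriched_p = min(0.9, config.enrichment_fold / config.n_bins)
    other_p = (1.0 - enriched_p) / max(1, config.n_bins - 1)
    for gid in genes:
        if truth.cluster_of_gene.get(gid) == truth.enriched_cluster:
            probs = [enriched_p] + [other_p] * (config.n_bins - 1)
        else:
            probs = [1.0 / config.n_bins] * config.n_bins
        truth.bin_of_gene[gid] = bins[rng_bins.choice(config.n_bins, p=probs)]

    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "bin_code": [truth.bin_of_gene[g] for g in genes],
            "bin_name": [bin_names[truth.bin_of_gene[g]] for g in genes],
        }
    )

    expression = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log2_expr), index=pd.Index(genes, name="gene_id"),
            columns=expr_design.samples,
        ),
        expr_design,
    )
    pathway_edges = [
        (metab_ids[j], metab_ids[j + 1]) for j in range(config.n_metabolites - 1)
    ]
    metabolites = MetaboliteTable(
        pd.DataFrame(
            np.exp2(log2_metab), index=pd.Index(metab_ids, name="metabolite_id"),
            columns=metab_design.samples,
        ),
        metab_design,
        enzyme_map=pd.DataFrame(enzyme_rows),
        pathway_edges=pathway_edges,
    )
    return SimDataset(expression, metabolites, annotation, truth, config)


def generate_imbibition_series(
    breakpoints: tuple[float, float] = (120.0, 600.0),
    slopes: tuple[float, float, float] = (0.004, 0.001, 0.003),
    noise_sd: float = 0.0,
    n_points: int = 81,
    seed: int = 0,
    t_max: float = 1200.0,
    start_weight: float = 0.5,
) -> FreshWeightSeries:
    """Triphasic water-uptake curve: rapid imbibition, plateau, regrowth.

    Piecewise-linear continuous mean with additive Gaussian noise; the first
    slope must exceed the second (rapid then slow uptake).
    """
    b1, b2 = breakpoints
    if not 0.0 < b1 < b2 < t_max:
        raise ValueError("breakpoints must be strictly increasing inside (0, t_max)")
    s1, s2, s3 = slopes
    if s1 <= s2:
        raise ValueError("rapid-uptake slope must exceed the plateau slope")
    t = np.linspace(0.0, t_max, n_points)
    mean = (
        start_weight
        + s1 * np.minimum(t, b1)
        + s2 * np.clip(t - b1, 0.0, b2 - b1)
        + s3 * np.maximum(t - b2, 0.0)
    )
    rng = np.random.default_rng(seed)
    w = mean + rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else mean
    return FreshWeightSeries(time=t, weight=w)


# ---------------------------------------------------------------------------
# Disk round-trip


def write_dataset(dataset: SimDataset, directory: str | Path) -> dict:
    """Write all tables as TSV plus truth/manifest JSON; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(name: str, df: pd.DataFrame, index: bool) -> None:
        path = directory / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        files[name] = {"rows": int(df.shape[0]), "columns": int(df.shape[1] + index)}

    _write("expression.tsv", dataset.expression.data, index=True)
    _write("metabolites.tsv", dataset.metabolites.data, index=True)
    _write("annotation.tsv", dataset.annotation, index=False)
    _write("enzyme_map.tsv", dataset.metabolites.enzyme_map, index=False)
    edges = pd.DataFrame(
        dataset.metabolites.pathway_edges, columns=["metabolite_a", "metabolite_b"]
    )
    _write("pathway_edges.tsv", edges, index=False)

    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth.to_json_dict(), indent=1))
    files["truth.json"] = {"rows": 1, "columns": 1}

    manifest = {
        "seed": dataset.config.seed,
        "config": dataclasses.asdict(dataset.config),
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(directory: str | Path) -> SimDataset:
    """Inverse of :func:`write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = SimConfig(**manifest["config"])
    expr_df = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    metab_df = pd.read_csv(directory / "metabolites.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t")
    enzyme_map = pd.read_csv(directory / "enzyme_map.tsv", sep="\t")
    edges_df = pd.read_csv(directory / "pathway_edges.tsv", sep="\t")
    truth = GroundTruth.from_json_dict(
        json.loads((directory / "truth.json").read_text())
    )
    expression = ExpressionMatrix(
        expr_df, StageDesign.from_sample_ids(list(expr_df.columns))
    )
    metabolites = MetaboliteTable(
        metab_df,
        StageDesign.from_sample_ids(list(metab_df.columns)),
        enzyme_map=enzyme_map,
        pathway_edges=[tuple(r) for r in edges_df.itertuples(index=False)],
    )
    return SimDataset(expression, metabolites, annotation, truth, config)
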