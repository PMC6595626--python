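"""Weighted coexpression network core, implemented from the defining formulas.

The network is built from gene-gene Pearson correlations raised to a soft
threshold power beta (unsigned by default), summarized by the topological
overlap measure

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij   = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu.

Modules are branches of the average-linkage 1 - TOM dendrogram under a static
cut; each module is summarized by its eigengene (first principal component of
the gene-standardized module submatrix), correlated against one-hot stage
indicators with a Student-t p-value, and mined for hub genes by intramodular
connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import StageDesign

logger = logging.getLogger(__name__)

# module label palette in the conventional size order; overflow -> module<N>
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
UNASSIGNED = "grey"


def _drop_zero_variance(data: pd.DataFrame) -> pd.DataFrame:
    sd = data.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d zero-variance genes", int(flat.sum()))
    return data.loc[~flat]


def adjacency(data: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta (unsigned).

    ``data`` is gene x sample. Zero-variance genes are dropped first. The
    signed variant uses ((1 + cor)/2)^beta.
    """
    data = _drop_zero_variance(data)
    corr = np.corrcoef(data.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=data.index, columns=data.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = row sum of A excluding self."""
    return adj.sum(axis=1) - 1.0


def pick_soft_threshold(
    data: pd.DataFrame,
    candidates: range = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose connectivity distribution fits a scale-free law.

    For each candidate power the log10 binned connectivity histogram is
    regressed on log10 mean connectivity; the smallest beta with fit
    R^2 >= target and negative slope wins. If none qualifies the beta with
    the largest R^2 is returned with a warning. Also returns the fit table.
    """
    data = _drop_zero_variance(data)
    if len(data) < 3:
        warnings.warn("too few genes for a scale-free fit; using smallest candidate")
        return candidates[0], pd.DataFrame()
    rows = []
    for beta in candidates:
        k = connectivity(adjacency(data, beta, signed=signed)).to_numpy()
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append({"beta": beta, "r2": r2, "slope": slope})
    table = pd.DataFrame(rows).fillna({"r2": 0.0, "slope": 0.0})
    ok = table[(table["r2"] >= r2_target) & (table["slope"] < 0)]
    if len(ok):
        return int(ok.iloc[0]["beta"]), table
    warnings.warn("no candidate reached the scale-free R^2 target; using best fit")
    return int(table.loc[table["r2"].idxmax(), "beta"]), table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if len(k) < 4 or np.ptp(k) == 0:
        return 0.0, 0.0
    # equal-width bins in k (frequencies must be free to vary for the fit)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    if np.isnan(res.rvalue) or np.isnan(res.slope):
        return 0.0, 0.0
    return float(res.rvalue**2), float(res.slope)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with unit diagonal."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - 1.0
    # L_ij = sum_{u != i,j} a_iu a_uj = (A @ A)_ij - 2 a_ij  (since a_ii = 1)
    l = a @ a - 2.0 * a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Gene-to-module assignment with per-module summaries."""

    module_of_gene: pd.Series  # gene -> color label or "grey"
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # sample x module
    variance_explained: dict[str, float] = field(default_factory=dict)
    k_within: pd.Series | None = None
    hubs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_of_gene.unique() if m != UNASSIGNED]

    def genes_in(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])


def detect_modules(
    tom: pd.DataFrame, cut_height: float = 0.25, min_size: int = 30
) -> ModuleSet:
    """Static-cut module detection on the 1 - TOM dendrogram.

    Average-linkage clusters at dissimilarity ``cut_height``; groups smaller
    than ``min_size`` become "grey" (unassigned). Labels follow the
    conventional color order by decreasing module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    genes = list(tom.index)
    if len(genes) < min_size:
        return ModuleSet(pd.Series(UNASSIGNED, index=tom.index, name="module"))
    dist = np.clip(1.0 - tom.to_numpy(), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].index
    # size-ranked color labels; ties broken by raw label for determinism
    order = sorted(keep, key=lambda lab: (-sizes[lab], lab))
    label_of = {
        lab: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, lab in enumerate(order)
    }
    labels = [label_of.get(lab, UNASSIGNED) for lab in raw]
    return ModuleSet(pd.Series(labels, index=tom.index, name="module"))


def module_eigengene(
    data: pd.DataFrame, module_genes: list[str]
) -> tuple[pd.Series, float]:
    """Module eigengene: first principal component across samples.

    Genes are z-scored across samples; the leading right singular vector of
    the standardized submatrix is the per-sample eigengene, unit norm, with
    sign oriented so the average gene-eigengene correlation is positive.
    Returns (eigengene, fraction of variance explained).
    """
    if len(module_genes) == 0:
        raise ValueError("empty module")
    sub = data.loc[module_genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    # orientation: average correlation of genes with the eigengene >= 0
    if u[:, 0].sum() < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return pd.Series(me, index=data.columns, name="ME"), var_explained


def summarize_modules(data: pd.DataFrame, modules: ModuleSet) -> ModuleSet:
    """Fill eigengenes and variance explained for every non-grey module."""
    cols = {}
    for mod in modules.modules:
        me, ve = module_eigengene(data, modules.genes_in(mod))
        cols[mod] = me
        modules.variance_explained[mod] = ve
    modules.eigengenes = pd.DataFrame(cols)
    return modules


def module_stage_correlation(
    eigengenes: pd.DataFrame, design: StageDesign
) -> pd.DataFrame:
    """Pearson r and Student-t p of each eigengene vs each one-hot stage.

    With n samples, t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom,
    two-sided. Rows: (module, stage, r, p).
    """
    n = len(eigengenes.index)
    if n < 3:
        raise ValueError("need at least 3 samples")
    stage_of = [design.stage_of_sample[s] for s in eigengenes.index]
    rows = []
    for mod in eigengenes.columns:
        me = eigengenes[mod].to_numpy(dtype=float)
        if np.std(me) == 0:
            raise ValueError(f"constant eigengene for module {mod!r}")
        for stage in design.stages:
            onehot = np.array([1.0 if s == stage else 0.0 for s in stage_of])
            r = float(np.corrcoef(me, onehot)[0, 1])
            rows.append(
                {"module": mod, "stage": stage, "r": r, "p": correlation_pvalue(r, n)}
            )
    return pd.DataFrame(rows)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p-value of a Pearson correlation over n samples."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def intramodular_connectivity(adj: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """k_within(i) = sum of adjacencies to the other module members."""
    sub = adj.loc[module_genes, module_genes]
    return sub.sum(axis=1) - 1.0


def top_hubs(k_within: pd.Series, n: int = 10) -> list[str]:
    """The n most intramodularly connected genes; ties by gene id."""
    order = sorted(k_within.index, key=lambda g: (-k_within[g], g))
    return order[:n]


def export_network(
    weights: pd.DataFrame,
    directory: str | Path,
    weight_threshold: float = 0.1,
    node_attributes: pd.DataFrame | None = None,
    basename: str = "network",
) -> dict[str, Path]:
    """Write thresholded edges as SIF, GraphML and TSV for viewer import.

    Edges with weight >= threshold are kept. ``node_attributes`` (indexed by
    gene) may carry module, hub and transcription-factor flags.
    """
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValueError("weight_threshold must be in [0, 1]")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = list(weights.index)
    w = weights.to_numpy()
    g = nx.Graph()
    for i, gene in enumerate(genes):
        attrs = {}
        if node_attributes is not None and gene in node_attributes.index:
            attrs = {k: _plain(v) for k, v in node_attributes.loc[gene].items()}
        g.add_node(gene, **attrs)
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        if w[i, j] >= weight_threshold:
            g.add_edge(genes[i], genes[j], weight=float(w[i, j]))

    paths = {
        "sif": directory / f"{basename}.sif",
        "graphml": directory / f"{basename}.graphml",
        "tsv": directory / f"{basename}_edges.tsv",
    }
    with open(paths["sif"], "w") as fh:
        for a, b in g.edges:
            fh.write(f"{a}\tco\t{b}\n")
    nx.write_graphml(g, paths["graphml"])
    pd.DataFrame(
        [
            {"source": a, "target": b, "weight": d["weight"]}
            for a, b, d in g.edges(data=True)
        ],
        columns=["source", "target", "weight"],
    ).to_csv(paths["tsv"], sep="\t", index=False)
    return paths


def _plain(v):
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v
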