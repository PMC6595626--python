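"""Targeted correlation network analysis (TCNA).

For each target metabolite, the stage-mean trajectory of every enzyme-family
member annotated to synthesize or decompose it is Spearman-correlated with
the metabolite's stage-mean trajectory; pathway-adjacent metabolite pairs
form the backbone. With only six stage points the two-sided p-value is
computed exactly by enumerating all 720 rank permutations. Edges carry
(rho, p, significant, sign); family members are ranked by |rho| to nominate
the candidate gene behind each metabolite's trajectory.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .design import StageDesign

_EPS = 1e-12


def stage_mean_profiles(data: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    """Entity x stage arithmetic means on the original scale."""
    present = sorted(set(design.stage_of_sample.values()))
    cols = {}
    for stage in present:
        samples = design.samples_for_stage(stage)
        cols[stage] = data[samples].mean(axis=1)
    return pd.DataFrame(cols)


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman(
    x: np.ndarray, y: np.ndarray, exact_n_max: int = 8
) -> tuple[float, float, bool]:
    """Spearman rho with an exact permutation p-value for short vectors.

    rho is the Pearson correlation of average ranks. For n <= ``exact_n_max``
    the two-sided p enumerates all n! permutations of one rank vector:
    p = #{perm : |rho_perm| >= |rho_obs|} / n!. Longer vectors fall back to
    the t approximation. A constant input yields (0.0, 1.0, True) where the
    boolean flags the degenerate case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("profiles must have equal length")
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0, True
    rx = _rank(x) - (n + 1) / 2
    ry = _rank(y) - (n + 1) / 2
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    rho = float(rx @ ry) / denom
    if n <= exact_n_max:
        perms = np.array(list(itertools.permutations(ry)))
        rhos = perms @ rx / denom
        p = float(np.count_nonzero(np.abs(rhos) >= abs(rho) - _EPS) / len(perms))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, _EPS))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0), False


@dataclass(frozen=True)
class TCNAEdge:
    source: str  # gene id or metabolite id
    target: str  # metabolite id
    kind: str  # "gene-metabolite" or "metabolite-metabolite"
    role: str  # synthesis | decomposition | pathway-adjacent
    rho: float
    p: float
    significant: bool
    sign: str  # positive | negative

    def __post_init__(self) -> None:
        expected = "negative" if self.rho < 0 else "positive"
        if self.sign != expected:
            raise ValueError("edge sign must match the sign of rho")


def build_tcna(
    expr_profiles: pd.DataFrame,
    metab_profiles: pd.DataFrame,
    enzyme_map: pd.DataFrame,
    pathway_edges: list[tuple[str, str]] | None = None,
    r_min: float = 0.25,
    alpha: float = 0.05,
    targets: list[str] | None = None,
) -> nx.Graph:
    """Targeted correlation graph over stage-mean trajectories.

    One candidate edge per annotated synthesis/decomposition family member of
    each target metabolite and one per pathway-adjacent metabolite pair.
    Edges with |rho| >= ``r_min`` are kept; an edge is significant (drawn
    solid) when additionally p <= ``alpha``. Node and edge iteration order is
    sorted, so the graph is independent of input order.
    """
    if pathway_edges is None:
        pathway_edges = []
    if targets is None:
        targets = sorted(enzyme_map["metabolite_id"].unique())
    graph = nx.Graph()

    for metab in sorted(targets):
        if metab not in metab_profiles.index:
            raise KeyError(f"target metabolite {metab!r} absent from profiles")
        members = enzyme_map[enzyme_map["metabolite_id"] == metab]
        if members.empty:
            import warnings

            warnings.warn(f"no enzyme-family members for {metab!r}; skipped")
            continue
        graph.add_node(metab, kind="metabolite", shape="rectangle")
        mvec = metab_profiles.loc[metab].to_numpy()
        for _, row in members.sort_values("gene_id").iterrows():
            gene = row["gene_id"]
            if gene not in expr_profiles.index:
                raise KeyError(f"enzyme gene {gene!r} absent from expression profiles")
            rho, p, _ = spearman(expr_profiles.loc[gene].to_numpy(), mvec)
            if abs(rho) < r_min:
                continue
            graph.add_node(gene, kind="gene", shape="triangle", role=row["role"])
            graph.add_edge(
                gene,
                metab,
                kind="gene-metabolite",
                role=row["role"],
                rho=rho,
                p=p,
                significant=bool(p <= alpha and abs(rho) >= r_min),
                sign="negative" if rho < 0 else "positive",
            )

    target_set = set(targets)
    for a, b in sorted(tuple(sorted(e)) for e in pathway_edges):
        if a not in target_set and b not in target_set:
            continue
        if a not in metab_profiles.index or b not in metab_profiles.index:
            raise KeyError(f"pathway edge ({a}, {b}) references unknown metabolite")
        rho, p, _ = spearman(
            metab_profiles.loc[a].to_numpy(), metab_profiles.loc[b].to_numpy()
        )
        if abs(rho) < r_min:
            continue
        for node in (a, b):
            graph.add_node(node, kind="metabolite", shape="rectangle")
        graph.add_edge(
            a,
            b,
            kind="metabolite-metabolite",
            role="pathway-adjacent",
            rho=rho,
            p=p,
            significant=bool(p <= alpha and abs(rho) >= r_min),
            sign="negative" if rho < 0 else "positive",
        )
    return graph


def rank_candidates(graph: nx.Graph, metabolite: str) -> pd.DataFrame:
    """Family members of one metabolite ranked by correlation strength.

    Sorted by |rho| descending, then smaller p, then gene id; the top row is
    the candidate gene for the metabolite's trajectory.
    """
    if metabolite not in graph:
        raise KeyError(f"{metabolite!r} not in graph")
    rows = []
    for nbr in graph.neighbors(metabolite):
        edge = graph.edges[metabolite, nbr]
        if edge["kind"] != "gene-metabolite":
            continue
        rows.append(
            {
                "metabolite": metabolite,
                "gene_id": nbr,
                "role": edge["role"],
                "rho": edge["rho"],
                "p": edge["p"],
                "significant": edge["significant"],
            }
        )
    if not rows:
        raise ValueError(f"metabolite {metabolite!r} has no gene edges")
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["rho", "p", "gene_id"],
        key=lambda col: -col.abs() if col.name == "rho" else col,
    ).reset_index(drop=True)
    df.insert(1, "rank", np.arange(1, len(df) + 1))
    return df


def export_graph(graph: nx.Graph, directory: str | Path, basename: str = "tcna") -> dict[str, Path]:
    """Write GraphML, SIF and an edge TSV with viewer styling attributes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    styled = graph.copy()
    for a, b, d in styled.edges(data=True):
        d["style"] = "solid" if d["significant"] else "dashed"
        d["color"] = "red" if d["sign"] == "positive" else "blue"
    paths = {
        "graphml": directory / f"{basename}.graphml",
        "sif": directory / f"{basename}.sif",
        "tsv": directory / f"{basename}_edges.tsv",
    }
    nx.write_graphml(styled, paths["graphml"])
    edges = sorted(styled.edges(data=True))
    with open(paths["sif"], "w") as fh:
        for a, b, d in edges:
            fh.write(f"{a}\t{d['role']}\t{b}\n")
    pd.DataFrame(
        [
            {
                "source": a,
                "target": b,
                "type": d["kind"],
                "role": d["role"],
                "rho": d["rho"],
                "p": d["p"],
                "significant": d["significant"],
                "sign": d["sign"],
            }
            for a, b, d in edges
        ],
        columns=[
            "source", "target", "type", "role", "rho", "p", "significant", "sign",
        ],
    ).to_csv(paths["tsv"], sep="\t", index=False)
    return paths
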