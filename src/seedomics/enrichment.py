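"""Fisher's-exact over/under-representation of annotation bins in gene sets.

Each gene carries one or more functional bins; a gene set (cluster,
supercluster or module) is tested bin by bin against the annotated gene
universe using exact hypergeometric tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationTable:
    """gene -> functional bin(s) over a background universe."""

    table: pd.DataFrame  # columns: gene_id, bin_code, bin_name
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "bin_code"}
        if not required.issubset(self.table.columns):
            raise ValueError("annotation needs gene_id and bin_code columns")
        # duplicate (gene, bin) rows collapse to one membership
        self.table = self.table.drop_duplicates(subset=["gene_id", "bin_code"])
        if self.universe is None:
            self.universe = sorted(self.table["gene_id"].unique())
        missing = set(self.table["gene_id"]) - set(self.universe)
        if missing:
            raise ValueError(f"annotated genes outside universe: {sorted(missing)[:5]}")

    def genes_in_bin(self, bin_code: str) -> set[str]:
        return set(self.table.loc[self.table["bin_code"] == bin_code, "gene_id"])

    @property
    def bins(self) -> list[str]:
        return list(dict.fromkeys(self.table["bin_code"]))

    def bin_name(self, bin_code: str) -> str:
        if "bin_name" not in self.table.columns:
            return bin_code
        rows = self.table.loc[self.table["bin_code"] == bin_code, "bin_name"]
        return str(rows.iloc[0]) if len(rows) else bin_code


def fisher_enrichment(
    set_genes: set[str], bin_genes: set[str], universe: set[str]
) -> tuple[float, float, float]:
    """Exact hypergeometric tails for one set x bin contingency.

    Returns (p_over, p_under, fold) where p_over = P(X >= k),
    p_under = P(X <= k), X ~ Hypergeom(N=|universe|, K=|bin|, n=|set|), and
    fold = (k/n) / (K/N).
    """
    if not set_genes or not universe:
        raise ValueError("empty gene set or universe")
    if not set_genes <= universe or not bin_genes <= universe:
        raise ValueError("set and bin must be subsets of the universe")
    n_universe = len(universe)
    n_bin = len(bin_genes)
    n_set = len(set_genes)
    k = len(set_genes & bin_genes)
    p_over = float(hypergeom.sf(k - 1, n_universe, n_bin, n_set))
    p_under = float(hypergeom.cdf(k, n_universe, n_bin, n_set))
    expected = n_bin / n_universe
    fold = (k / n_set) / expected if expected > 0 else float("nan")
    return p_over, p_under, fold


def enrich_all(
    set_genes: set[str],
    annotation: AnnotationTable,
    alpha: float = 0.05,
    adjust: str = "none",
    set_label: str = "set",
) -> pd.DataFrame:
    """One enrichment row per bin; significance at ``alpha`` on the smaller tail.

    ``adjust``: "none" (raw p, the conventional threshold here) or "BH"
    (Benjamini-Hochberg across bins, applied to the smaller tail).
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjust keyword {adjust!r}")
    universe = set(annotation.universe)
    stray = set_genes - universe
    if stray:
        raise ValueError(f"set genes outside universe: {sorted(stray)[:5]}")
    rows = []
    for bin_code in annotation.bins:
        bin_genes = annotation.genes_in_bin(bin_code)
        p_over, p_under, fold = fisher_enrichment(set_genes, bin_genes, universe)
        rows.append(
            {
                "set": set_label,
                "bin_code": bin_code,
                "bin_name": annotation.bin_name(bin_code),
                "k": len(set_genes & bin_genes),
                "n": len(set_genes),
                "K": len(bin_genes),
                "N": len(universe),
                "fold": fold,
                "p_over": p_over,
                "p_under": p_under,
                "direction": "over" if p_over <= p_under else "under",
            }
        )
    result = pd.DataFrame(rows)
    p_min = result[["p_over", "p_under"]].min(axis=1)
    if adjust == "BH":
        p_min = pd.Series(
            multipletests(p_min, method="fdr_bh")[1], index=result.index
        )
    result["significant"] = p_min <= alpha
    return result
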