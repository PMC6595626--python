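"""Empirical noise-probability differential expression between stages.

For a stage pair, each gene gets a log2 ratio of stage means (M) and an
absolute difference of stage means (D). A noise cloud of (|M|, D) points is
built from within-stage replicate pairs of both stages pooled across genes;
the probability of differential expression q is the fraction of noise points
strictly dominated by the gene's signal point in both coordinates. Genes are
called at fold change >= 2 and q >= 0.8 (both inclusive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StageDesign
from .matrix import ExpressionMatrix

PSEUDOCOUNT = 0.5


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> ExpressionMatrix:
    """FPKM = 1e9 * c / (N * L) from a fragment-count table.

    ``gene_lengths`` is in bp per gene; ``library_sizes`` is the total mapped
    fragments per sample.
    """
    lengths = gene_lengths.reindex(counts.index)
    sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    fpkm = 1e9 * counts.div(lengths, axis=0).div(sizes, axis=1)
    return ExpressionMatrix(fpkm, StageDesign.from_sample_ids(list(counts.columns)))


def noise_distribution(
    expr: ExpressionMatrix, stage_a: int, stage_b: int
) -> np.ndarray:
    """Pooled within-stage (|M|, D) noise points, shape (n_points, 2).

    For every within-stage replicate pair in either stage and every gene:
    |M| = |log2((x_i + c)/(x_j + c))| and D = |x_i - x_j| with pseudocount c.
    With r replicates per stage this yields 2 * C(r, 2) * n_genes points.
    """
    points = []
    for stage in (stage_a, stage_b):
        samples = expr.design.samples_for_stage(stage)
        if len(samples) < 2:
            raise ValueError(f"stage {stage} has fewer than 2 replicates")
        for si, sj in itertools.combinations(samples, 2):
            xi = expr.data[si].to_numpy(float)
            xj = expr.data[sj].to_numpy(float)
            m = np.abs(np.log2((xi + PSEUDOCOUNT) / (xj + PSEUDOCOUNT)))
            d = np.abs(xi - xj)
            points.append(np.column_stack([m, d]))
    return np.concatenate(points, axis=0)


@dataclass
class DEGTable:
    """Per-gene DE statistics for one stage comparison."""

    comparison: str
    table: pd.DataFrame  # columns: M, D, q, fold_change, direction

    def called(self, fc_threshold: float = 2.0, q_threshold: float = 0.8) -> pd.DataFrame:
        t = self.table
        return t[(t["fold_change"] >= fc_threshold) & (t["q"] >= q_threshold)]


def de_probability(
    expr: ExpressionMatrix, stage_a: int, stage_b: int, noise: np.ndarray
) -> DEGTable:
    """Signal (M, D) per gene and its empirical probability q against noise.

    M = log2(mean_a + c) - log2(mean_b + c); D = |mean_a - mean_b|;
    q = fraction of noise points with |M_noise| < |M| AND D_noise < D
    (strict: a tied noise point counts as not dominated). Direction is "up"
    when the gene is higher in ``stage_a``.
    """
    if len(noise) == 0:
        raise ValueError("noise distribution is empty")
    mean_a = expr.data[expr.design.samples_for_stage(stage_a)].mean(axis=1).to_numpy()
    mean_b = expr.data[expr.design.samples_for_stage(stage_b)].mean(axis=1).to_numpy()
    m = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    d = np.abs(mean_a - mean_b)

    # q via sorted-noise counting: for each gene count noise points strictly
    # below in both coordinates
    abs_m = np.abs(m)
    nm, nd = noise[:, 0], noise[:, 1]
    q = np.empty(len(m))
    for i in range(len(m)):
        q[i] = np.count_nonzero((nm < abs_m[i]) & (nd < d[i]))
    q /= len(noise)

    table = pd.DataFrame(
        {
            "M": m,
            "D": d,
            "q": q,
            "fold_change": np.exp2(abs_m),
            "direction": np.where(m > 0, "up", "down"),
        },
        index=expr.data.index,
    )
    return DEGTable(comparison=f"stage{stage_a}_vs_stage{stage_b}", table=table)


@dataclass
class DEGSet:
    comparison: str
    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


def call_degs(
    deg_table: DEGTable, fc_threshold: float = 2.0, q_threshold: float = 0.8
) -> DEGSet:
    """Partition called genes (inclusive thresholds) by direction."""
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    called = deg_table.called(fc_threshold, q_threshold)
    return DEGSet(
        comparison=deg_table.comparison,
        up=list(called.index[called["direction"] == "up"]),
        down=list(called.index[called["direction"] == "down"]),
    )


def stagewise_degs(
    expr: ExpressionMatrix,
    mode: str = "vs_first",
    fc_threshold: float = 2.0,
    q_threshold: float = 0.8,
) -> dict[str, tuple[DEGTable, DEGSet]]:
    """All stage comparisons of one matrix.

    mode="vs_first" compares every later stage against stage 1 (dry seed);
    mode="successive" compares each stage with its predecessor.
    """
    stages = expr.design.stages
    if mode == "vs_first":
        pairs = [(s, stages[0]) for s in stages[1:]]
    elif mode == "successive":
        pairs = [(stages[i + 1], stages[i]) for i in range(len(stages) - 1)]
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    out = {}
    for later, earlier in pairs:
        noise = noise_distribution(expr, later, earlier)
        table = de_probability(expr, later, earlier, noise)
        out[table.comparison] = (table, call_degs(table, fc_threshold, q_threshold))
    return out


def deg_union(results: dict[str, tuple[DEGTable, DEGSet]]) -> list[str]:
    """Union of called genes over all comparisons, in matrix order."""
    seen: set[str] = set()
    for _, degset in results.values():
        seen.update(degset.genes)
    first_table = next(iter(results.values()))[0].table
    return [g for g in first_table.index if g in seen]
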