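"""Two-step metabolite significance: VIP filter then Student's t-test.

For each stage-vs-reference comparison a single latent discriminant component
is fitted to the autoscaled two-group abundance block; each metabolite's
variable importance in projection (VIP) for that component is
sqrt(P) * |w_j| with unit loading vector w, so sum of squared VIPs equals the
number of metabolites P. Metabolites passing VIP > 1.0 are then tested with
an equal-variance two-sample t-test; significance requires both VIP > 1.0
(strict) and p < 0.05 (strict), with direction from the sign of the group
mean difference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MetaboliteTable

logger = logging.getLogger(__name__)


def pls_vip(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-component VIP scores for a two-group block.

    ``x`` is samples x metabolites (will be column-autoscaled), ``y`` holds
    binary group labels. The latent loading is w = X'y_c / ||X'y_c|| (the
    one-component solution of the latent-structure regression); VIP_j =
    sqrt(P) * |w_j|. Zero-variance columns get VIP 0 with a warning.
    Returns (vip, w).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("x must be samples x variables aligned with y")
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("y must contain exactly two groups")
    for g in groups:
        if np.sum(y == g) < 2:
            raise ValueError("each group needs >= 2 samples")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance metabolites get VIP 0", int(flat.sum()))
    sd_safe = np.where(flat, 1.0, sd)
    xs = (x - mean) / sd_safe
    xs[:, flat] = 0.0
    yc = y - y.mean()
    cov = xs.T @ yc
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise ValueError("labels are uncorrelated with every metabolite")
    w = cov / norm
    p_vars = x.shape[1]
    vip = np.sqrt(p_vars) * np.abs(w)
    if flat.any():
        # renormalize over informative columns so sum VIP^2 = P still holds
        informative = ~flat
        w_sub = w[informative] / np.linalg.norm(w[informative])
        vip = np.zeros(p_vars)
        vip[informative] = np.sqrt(p_vars) * np.abs(w_sub)
        w = np.where(informative, w, 0.0)
    return vip, w


def two_sample_t(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided equal-variance Student t-test p-value.

    Degenerate zero-pooled-variance inputs: equal means give p = 1,
    unequal means give p = 0 (the limiting value, logged).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 values")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return 1.0
        logger.warning("zero pooled variance with unequal means: p -> 0 limit")
        return 0.0
    return float(stats.ttest_ind(g1, g2, equal_var=True).pvalue)


def call_changed_metabolites(
    table: MetaboliteTable,
    reference_stage: int = 1,
    vip_min: float = 1.0,
    alpha: float = 0.05,
    mode: str = "vs_reference",
) -> pd.DataFrame:
    """Per (metabolite, stage) significance calls against the reference stage.

    Abundances are log2-transformed before autoscaling (multiplicative noise
    model). For each non-reference stage, the VIP filter runs on the combined
    stage+reference block; retained metabolites (VIP strictly > ``vip_min``)
    are t-tested, and a call requires p strictly < ``alpha``. Direction is the
    sign of the stage-minus-reference mean log difference.

    ``mode``: "vs_reference" compares every stage with ``reference_stage``;
    "successive" compares each stage with its predecessor.
    """
    stages = table.design.stages
    if reference_stage not in stages:
        raise ValueError(f"reference stage {reference_stage} absent")
    if mode == "vs_reference":
        pairs = [(s, reference_stage) for s in stages if s != reference_stage]
    elif mode == "successive":
        pairs = [(stages[i + 1], stages[i]) for i in range(len(stages) - 1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    log_data = np.log2(table.data)
    rows = []
    for stage, ref in pairs:
        s_cols = table.design.samples_for_stage(stage)
        r_cols = table.design.samples_for_stage(ref)
        block = log_data[r_cols + s_cols].to_numpy().T  # samples x metabolites
        labels = np.array([0.0] * len(r_cols) + [1.0] * len(s_cols))
        vip, _ = pls_vip(block, labels)
        for j, metab in enumerate(table.metabolites):
            g_stage = log_data.loc[metab, s_cols].to_numpy()
            g_ref = log_data.loc[metab, r_cols].to_numpy()
            p = two_sample_t(g_stage, g_ref)
            diff = float(g_stage.mean() - g_ref.mean())
            rows.append(
                {
                    "metabolite": metab,
                    "stage": stage,
                    "reference": ref,
                    "vip": float(vip[j]),
                    "p": p,
                    "direction": "up" if diff > 0 else "down",
                    "significant": bool(vip[j] > vip_min and p < alpha),
                }
            )
    return pd.DataFrame(rows)
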