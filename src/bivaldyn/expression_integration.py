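"""Expression thresholds, group-median comparisons, and differential
expression calls.

Thresholds follow the array-analysis conventions of the study design:
the detection floor is the maximum log2 expression over a set of
never-expressed control genes (Y-chromosome genes on a female cell
line, or the generator's null genes), and a gene is *expressed* when
its per-time-point mean exceeds 100 linear units (log2 ~= 6.64) at one
or more time points.

Differential expression uses two one-way fixed-effects ANOVA models —
one over the hypoxia arm (t0, t8, t24) and one over the reoxygenation
arm (t24, reox8, t0) — with Benjamini-Hochberg FDR correction over
expressed genes.  A gene is significant when it is expressed, its
largest between-time-point |log2 fold change| within the model reaches
the threshold, and its q-value passes.

Group medians (e.g., mark-state or profile-class gene sets) are
compared with the unpaired two-sided Mann-Whitney rank-sum test; the
sets differ in size and membership, for which the signed-rank pairing
is undefined.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_genomics import ExpressionMatrix, PipelineParams

MODELS: dict[str, tuple[str, ...]] = {
    "hypoxia": ("t0", "t8", "t24"),
    "reoxygenation": ("t24", "reox8", "t0"),
}


def detection_floor(
    expression: ExpressionMatrix, null_gene_ids: set[str]
) -> float:
    """Maximum log2 expression over the null genes and all samples."""
    ids = [g for g in null_gene_ids if g in expression.data.index]
    if not ids:
        raise ValueError("no null gene present in the expression matrix")
    return float(expression.data.loc[ids].to_numpy().max())


def expressed_flags(
    expression: ExpressionMatrix,
    params: PipelineParams | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-gene ``detected`` and ``expressed`` booleans.

    ``expressed``: per-time-point replicate mean above log2 of the
    linear-scale threshold for at least one time point.  ``detected``:
    any sample value above the detection floor (always true when no
    floor is known).
    """
    params = params or PipelineParams()
    if floor is None:
        floor = expression.detection_floor
    means = expression.timepoint_means()
    expressed = (means > params.expressed_threshold_log2).any(axis=1)
    if floor is None:
        detected = pd.Series(True, index=expression.data.index)
    else:
        detected = (expression.data > floor).any(axis=1)
    detected |= expressed  # expressed implies detected by construction
    return pd.DataFrame({"detected": detected, "expressed": expressed})


def median_by_group(
    expression: ExpressionMatrix,
    gene_groups: Mapping[str, set[str]],
    timepoint: str,
    min_group_size: int = 3,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Median per-gene mean expression per group at one time point, with
    pairwise two-sided Mann-Whitney tests.

    Groups smaller than ``min_group_size`` are skipped from testing with
    a warning.  Returns ``(medians, tests)`` where ``tests`` has columns
    group_a, group_b, p_value, significant.
    """
    means = expression.timepoint_means()[timepoint]
    values: dict[str, np.ndarray] = {}
    medians: dict[str, float] = {}
    for name, ids in gene_groups.items():
        present = [g for g in ids if g in means.index]
        vals = means.loc[present].to_numpy()
        values[name] = vals
        medians[name] = float(np.median(vals)) if len(vals) else float("nan")
    rows = []
    for a, b in itertools.combinations(gene_groups, 2):
        if len(values[a]) < min_group_size or len(values[b]) < min_group_size:
            warnings.warn(
                f"group {a!r} or {b!r} has fewer than {min_group_size} genes; "
                "test skipped"
            )
            continue
        p = float(
            stats.mannwhitneyu(values[a], values[b], alternative="two-sided").pvalue
        )
        rows.append(
            {"group_a": a, "group_b": b, "p_value": p, "significant": p < 0.05}
        )
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "significant"])
    return medians, tests


def _oneway_anova_rows(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Row-wise one-way fixed-effects ANOVA p-values.

    ``groups`` are 2-D arrays (genes x replicates), one per condition.
    Degenerate rows: zero within- and between-group variance -> p = 1
    (no evidence of change); zero within- but nonzero between-group
    variance -> p = 0.
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    group_means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    grand = np.sum(group_means * ns, axis=1) / n_total
    ssb = np.sum(ns * (group_means - grand[:, None]) ** 2, axis=1)
    ssw = np.zeros_like(ssb)
    for g, mean in zip(groups, group_means.T):
        ssw += np.sum((g - mean[:, None]) ** 2, axis=1)
    dfb, dfw = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(f, dfb, dfw)
    tol = 1e-12
    p = np.where(ssw <= tol, np.where(ssb <= tol, 1.0, 0.0), p)
    return p


def benjamini_hochberg(
    pvalues: np.ndarray, method: str = "bh"
) -> np.ndarray:
    """FDR-adjusted q-values; ``method="storey"`` rescales the BH
    q-values by a conservative null-proportion estimate pi0."""
    q = multipletests(pvalues, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, 2.0 * float(np.mean(pvalues > 0.5)))
        q = np.minimum(1.0, pi0 * q)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return q


def differential_calls(
    expression: ExpressionMatrix,
    params: PipelineParams | None = None,
    models: Mapping[str, Sequence[str]] | None = None,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-gene differential calls for each ANOVA model.

    Returns a DataFrame with one row per gene per model and columns
    ``model, p_value, q_value, max_abs_log2_fc, expressed, significant``.
    q-values are computed over expressed genes only (others carry NaN
    and can never be significant).
    """
    params = params or PipelineParams()
    if models is None:
        models = {
            name: tps
            for name, tps in MODELS.items()
            if all(tp in expression.timepoints for tp in tps)
        }
        if not models:
            raise ValueError(
                "expression matrix lacks the timepoints of both standard models"
            )
    flags = expressed_flags(expression, params)
    expressed = flags["expressed"]
    means = expression.timepoint_means()
    frames = []
    for model_name, tps in models.items():
        groups = [
            expression.data[expression.columns_for(tp)].to_numpy() for tp in tps
        ]
        if any(g.shape[1] < 2 for g in groups):
            raise ValueError(f"model {model_name!r} needs >= 2 replicates per timepoint")
        p = _oneway_anova_rows(groups)
        model_means = means[list(tps)].to_numpy()
        fc = model_means.max(axis=1) - model_means.min(axis=1)
        q = np.full_like(p, np.nan)
        mask = expressed.to_numpy()
        if mask.any():
            q[mask] = benjamini_hochberg(p[mask], fdr_method)
        significant = (
            mask
            & (fc >= params.fc_log2_min)
            & (np.nan_to_num(q, nan=1.0) <= params.qvalue_max)
        )
        frames.append(
            pd.DataFrame(
                {
                    "model": model_name,
                    "p_value": p,
                    "q_value": q,
                    "max_abs_log2_fc": fc,
                    "expressed": mask,
                    "significant": significant,
                },
                index=expression.data.index,
            )
        )
    return pd.concat(frames)
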