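"""Differential-methylation calling and supervised clustering.

The screen applies layered criteria to each locus of a beta matrix:
one-way ANOVA between DS and control groups, a fold-change threshold on
the ratio of group means, and (for the bead-array screens) an absolute
difference threshold in fraction units.  No multiple-testing correction
is applied (the raw p < .01 plus effect-size filters define the screen);
a Benjamini-Hochberg FDR column is emitted for information only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import (
    BetaMatrix,
    DiffMethCriteria,
    GROUP_CONTROL,
    GROUP_DS,
    GROUPS,
    ProbeAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)


def remove_sex_probes(matrix: BetaMatrix, annotation: ProbeAnnotation) -> BetaMatrix:
    """Drop every probe annotated to the X or Y chromosome.

    All probes must be annotated; the removed count is logged.
    """
    ann = annotation.lookup(matrix.probes)  # errors on unannotated probes
    keep = ~ann["chrom"].isin(("X", "Y"))
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d X/Y probes", removed)
    return matrix.subset_probes(ann.loc[keep, "probe_id"].tolist())


def _check_groups(groups: pd.Series) -> None:
    unknown = sorted(set(groups) - set(GROUPS))
    if unknown:
        raise ValidationError(f"unknown group labels: {unknown}")


def anova_per_locus(matrix: BetaMatrix, groups: pd.Series) -> pd.DataFrame:
    """Classic one-way fixed-effects F-test p-value per locus.

    With two groups the pooled-variance F equals the square of the pooled
    t statistic.  Loci with missing values are tested on the non-missing
    samples; a group left with < 2 usable values skips the locus with a
    reason.  Loci with zero between-group difference return p = 1.
    """
    _check_groups(groups)
    groups = groups.loc[matrix.samples]
    ds_cols = groups.index[groups == GROUP_DS]
    ctrl_cols = groups.index[groups == GROUP_CONTROL]
    if len(ds_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError("each group needs >= 2 samples")

    v = matrix.values
    a = v[ds_cols].to_numpy(float)
    b = v[ctrl_cols].to_numpy(float)
    complete = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)

    p = np.full(len(v), np.nan)
    reason = np.full(len(v), "", dtype=object)
    if complete.any():
        res = stats.f_oneway(a[complete], b[complete], axis=1)
        p[complete] = res.pvalue
    n_dropped = 0
    for i in np.flatnonzero(~complete):
        ai = a[i][~np.isnan(a[i])]
        bi = b[i][~np.isnan(b[i])]
        if len(ai) < 2 or len(bi) < 2:
            reason[i] = "fewer_than_2_usable_values_in_a_group"
            continue
        n_dropped += 1
        p[i] = stats.f_oneway(ai, bi).pvalue
    if n_dropped or (reason != "").any():
        logger.info(
            "ANOVA: %d loci tested on reduced samples, %d skipped",
            n_dropped, int((reason != "").sum()),
        )
    # identical group means with zero between-group variance give F = 0;
    # normalise the numerically exact case to p = 1
    p = np.where(np.isfinite(p), np.minimum(p, 1.0), p)
    return pd.DataFrame({"probe_id": matrix.probes, "p_anova": p, "reason": reason})


def welch_anova_per_locus(matrix: BetaMatrix, groups: pd.Series) -> pd.DataFrame:
    """Welch (unequal-variance) alternative to :func:`anova_per_locus`."""
    _check_groups(groups)
    groups = groups.loc[matrix.samples]
    v = matrix.values
    a = v[groups.index[groups == GROUP_DS]].to_numpy(float)
    b = v[groups.index[groups == GROUP_CONTROL]].to_numpy(float)
    p = np.full(len(v), np.nan)
    for i in range(len(v)):
        ai, bi = a[i][~np.isnan(a[i])], b[i][~np.isnan(b[i])]
        if len(ai) >= 2 and len(bi) >= 2:
            p[i] = stats.ttest_ind(ai, bi, equal_var=False).pvalue
    return pd.DataFrame({"probe_id": matrix.probes, "p_anova": p, "reason": ""})


def call_differential(matrix: BetaMatrix, groups: pd.Series,
                      criteria: DiffMethCriteria, welch: bool = False) -> pd.DataFrame:
    """Apply the layered screen criteria and return per-locus calls.

    ``passed`` requires p < p_threshold AND fold > fold_threshold AND
    (when the absolute-difference criterion is in use, threshold > 0)
    abs_diff > abs_diff_threshold.  Fold is max(group means)/min(group
    means), treating hyper- and hypomethylation symmetrically; a zero
    minimum mean gives infinite fold, which passes the fold criterion
    only when the absolute-difference criterion also holds.
    """
    anova = welch_anova_per_locus(matrix, groups) if welch else anova_per_locus(matrix, groups)
    groups = groups.loc[matrix.samples]
    v = matrix.values
    mean_ds = v[groups.index[groups == GROUP_DS]].mean(axis=1, skipna=True).to_numpy(float)
    mean_ctrl = v[groups.index[groups == GROUP_CONTROL]].mean(axis=1, skipna=True).to_numpy(float)

    hi = np.maximum(mean_ds, mean_ctrl)
    lo = np.minimum(mean_ds, mean_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.inf)
    abs_diff = np.abs(mean_ds - mean_ctrl)
    direction = np.where(mean_ds >= mean_ctrl, "hyper_in_ds", "hypo_in_ds")

    p = anova["p_anova"].to_numpy(float)
    abs_ok = abs_diff > criteria.abs_diff_threshold if criteria.abs_diff_threshold > 0 \
        else np.ones(len(v), dtype=bool)
    fold_ok = np.where(
        np.isinf(fold),
        abs_diff > (criteria.abs_diff_threshold if criteria.abs_diff_threshold > 0 else 0.0),
        fold > criteria.fold_threshold,
    )
    passed = (p < criteria.p_threshold) & fold_ok & abs_ok
    passed &= ~np.isnan(p)

    calls = pd.DataFrame({
        "probe_id": matrix.probes,
        "mean_ds": mean_ds,
        "mean_ctrl": mean_ctrl,
        "fold": fold,
        "abs_diff": abs_diff,
        "p_anova": p,
        "direction": direction,
        "passed": passed,
    })
    # informational BH-FDR over the tested loci (never used for calling)
    tested = ~np.isnan(p)
    q = np.full(len(p), np.nan)
    if tested.any():
        q[tested] = stats.false_discovery_control(p[tested], method="bh")
    calls["fdr_bh"] = q
    calls.loc[~tested, "passed"] = False
    return calls


def gene_level_summary(calls: pd.DataFrame, annotation: ProbeAnnotation) -> dict:
    """Reporting-only probe -> gene roll-up: counts of passed probes and of
    distinct gene symbols among them."""
    passed = calls[calls["passed"]]
    ann = annotation.lookup(passed["probe_id"].tolist()) if len(passed) else passed
    genes = sorted({g for g in (ann["gene"] if len(passed) else []) if g})
    return {"n_probes_passed": int(len(passed)), "n_genes_passed": len(genes), "genes": genes}


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, as a condensed matrix."""
    c = np.corrcoef(data)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def supervised_cluster(matrix: BetaMatrix) -> dict:
    """Average-linkage hierarchical clustering of both axes with distance
    1 - Pearson correlation, applied to the called loci.

    Constant (zero-variance) loci are excluded from the correlation
    distance with a warning.  Ties break deterministically by input order
    (scipy's linkage is deterministic for fixed input).
    """
    v = matrix.values.to_numpy(float)
    if v.shape[0] < 2:
        raise ValidationError("supervised clustering needs >= 2 loci")
    keep = v.std(axis=1) > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.warning("excluded %d constant loci from clustering", n_const)
    probes = [p for p, k in zip(matrix.probes, keep) if k]
    v = v[keep]
    if v.shape[0] < 2:
        raise ValidationError("fewer than 2 non-constant loci to cluster")

    locus_link = hierarchy.linkage(_correlation_distance(v), method="average")
    sample_data = v.T
    keep_s = sample_data.std(axis=1) > 0
    if not keep_s.all():
        raise ValidationError("constant-valued sample encountered in clustering")
    sample_link = hierarchy.linkage(_correlation_distance(sample_data), method="average")

    return {
        "locus_order": [probes[i] for i in hierarchy.leaves_list(locus_link)],
        "sample_order": [matrix.samples[i] for i in hierarchy.leaves_list(sample_link)],
        "locus_linkage": locus_link,
        "sample_linkage": sample_link,
        "n_constant_excluded": n_const,
    }
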