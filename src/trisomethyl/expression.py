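"""qPCR relative expression, group comparisons, dosage expectation, and
5aza-dC dose-response trend analysis.

Relative expression uses the delta-CT method with 2-fold-per-cycle
amplification: 2^-(mean target CT - mean reference CT).  Group
comparisons use Welch's t-test on relative expression.  Trisomic dosage
genes are expected at copy-number ratio (3:2 = 1.5-fold for complete
trisomy 21).  Demethylating-drug dose responses are summarised by the
Spearman rank correlation of expression against dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GROUP_CONTROL, GROUP_DS, ValidationError


def relative_expression(target_cts, reference_cts, efficiency: float = 2.0) -> float:
    """Per-sample relative expression: efficiency^-(dCT),
    dCT = mean(target CT) - mean(reference CT)."""
    t = np.asarray(target_cts, float)
    r = np.asarray(reference_cts, float)
    if len(r) == 0:
        raise ValidationError("reference CT values missing")
    if len(t) == 0:
        raise ValidationError("target CT values missing")
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValidationError("CT values must be > 0")
    dct = float(t.mean() - r.mean())
    return float(efficiency ** (-dct))


def relative_expression_table(ct_df: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per (sample, gene) relative expression from a long CT table
    (sample_id, gene, replicate, ct, reference_ct)."""
    rows = []
    for (sample, gene), sub in ct_df.groupby(["sample_id", "gene"], sort=False):
        rows.append({
            "sample_id": sample,
            "gene": gene,
            "relative_expression": relative_expression(
                sub["ct"].to_numpy(), sub["reference_ct"].to_numpy(), efficiency),
        })
    return pd.DataFrame(rows)


def group_expression_test(values, groups, log_scale: bool = False,
                          pooled: bool = False) -> dict:
    """DS/control fold of group means plus a two-sample t-test.

    Welch's test by default (pooled variance behind a flag); optional
    log transform of expression before testing.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    ds = v[g == GROUP_DS]
    ctrl = v[g == GROUP_CONTROL]
    if len(ds) < 2 or len(ctrl) < 2:
        raise ValidationError("need >= 2 samples per group")
    fold = float(ds.mean() / ctrl.mean())
    x, y = (np.log(ds), np.log(ctrl)) if log_scale else (ds, ctrl)
    if np.std(x) == 0 and np.std(y) == 0:
        p = 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
        t_stat = 0.0 if p == 1.0 else float("inf")
    else:
        res = stats.ttest_ind(x, y, equal_var=pooled)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {"fold": fold, "t": t_stat, "p": p, "n_ds": len(ds), "n_ctrl": len(ctrl)}


def dosage_expectation(copy_number_case: float, copy_number_ctrl: float) -> float:
    """Expected expression fold under a pure physical gene-dosage effect."""
    if copy_number_case < 1 or copy_number_ctrl < 1:
        raise ValidationError("copy numbers must be >= 1")
    return copy_number_case / copy_number_ctrl


def dose_response_trend(doses, values, alpha: float = 0.05) -> dict:
    """Monotone trend of expression against drug dose.

    Spearman rank correlation over all (dose, expression) points;
    direction is the sign of rho when p < alpha, else "flat".  A series
    with no variation returns "flat" with a note.
    """
    d = np.asarray(doses, float)
    v = np.asarray(values, float)
    if len(np.unique(d)) < 3:
        raise ValidationError("need >= 3 dose levels")
    if np.std(v) == 0 or np.std(d) == 0:
        return {"direction": "flat", "rho": 0.0, "p": 1.0,
                "note": "no variation in the series"}
    rho, p = stats.spearmanr(d, v)
    if np.isnan(rho):
        return {"direction": "flat", "rho": 0.0, "p": 1.0, "note": "ties across all values"}
    direction = "flat"
    if p < alpha:
        direction = "up" if rho > 0 else "down"
    return {"direction": direction, "rho": float(rho), "p": float(p), "note": ""}


def methylation_expression_concordance(calls: pd.DataFrame,
                                       expression_folds: pd.DataFrame) -> pd.DataFrame:
    """Per-gene concordance of methylation direction with expression change.

    Expected sign: promoter hypomethylation in DS predicts increased
    expression; hypermethylation predicts decreased expression.  Genes
    whose observed fold contradicts the prediction are flagged
    paradoxical and reported, never suppressed.

    ``calls``: columns gene, direction (hyper_in_ds / hypo_in_ds);
    ``expression_folds``: columns gene, fold (DS/control).
    """
    merged = calls.merge(expression_folds, on="gene", how="inner")
    expected = np.where(merged["direction"] == "hypo_in_ds", "up", "down")
    observed = np.where(merged["fold"] > 1.0, "up",
                        np.where(merged["fold"] < 1.0, "down", "flat"))
    merged = merged.assign(
        expected_sign=expected,
        observed_sign=observed,
        concordant=expected == observed,
    )
    merged["paradoxical"] = (~merged["concordant"]) & (merged["observed_sign"] != "flat")
    return merged
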