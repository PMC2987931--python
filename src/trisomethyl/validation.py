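"""Targeted-assay statistics for the validation series.

Covers: pyrosequencing region means (>= 8 successive CpGs), age-adjusted
case-control logistic regression with a Firth bias-reduced fallback for
separated data, longitudinal within-individual stability, the linear
mosaic-trisomy dilution model, and the cell-type mixture explainability
test (can plausible shifts in leukocyte differential counts account for
an observed bulk methylation difference?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import GROUP_DS, ValidationError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- pyroseq

def pyroseq_region_mean(per_cpg_values, min_cpgs: int = 8) -> float:
    """Arithmetic mean percent methylation over the CpGs of one region.

    Regions with fewer than ``min_cpgs`` CpGs are not reportable.
    """
    vals = np.asarray(per_cpg_values, float)
    if len(vals) < min_cpgs:
        raise ValidationError(
            f"region has {len(vals)} CpGs; at least {min_cpgs} required")
    if np.any((vals < 0) | (vals > 100)):
        raise ValidationError("per-CpG percent values must lie in [0, 100]")
    return float(vals.mean())


def pyroseq_sample_means(long_df: pd.DataFrame, min_cpgs: int = 8) -> pd.DataFrame:
    """Per (gene, sample) region means from a long table
    (gene, sample_id, cpg_index, percent)."""
    rows = []
    for (gene, sample), sub in long_df.groupby(["gene", "sample_id"], sort=False):
        rows.append({
            "gene": gene,
            "sample_id": sample,
            "region_mean": pyroseq_region_mean(sub["percent"].to_numpy(), min_cpgs),
            "n_cpgs": len(sub),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------- age-adjusted group test

def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth bias-reduced logistic regression.

    Newton iteration on the modified score U*(b) = X'(y - p + h(0.5 - p))
    where h are the hat-diagonal values; the penalized log-likelihood is
    l(b) + 0.5 log det I(b).  Returns (beta, penalized loglik, Fisher info).
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_ll(b):
        eta = X @ b
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    pl = penalized_ll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise ValidationError("singular information matrix in Firth fit") from None
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ score
        scale = 1.0
        for _ in range(50):
            cand_pl = penalized_ll(beta + scale * delta)
            if cand_pl >= pl - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * delta
        pl = penalized_ll(beta)
        if np.max(np.abs(scale * delta)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    return beta, pl, info


def age_adjusted_group_test(methylation, age, group) -> dict:
    """Logistic regression group ~ methylation + age; p for methylation.

    Plain maximum likelihood with a Wald p-value is used when the fit is
    regular.  When quasi-separation is detected (any fitted probability
    within 1e-8 of 0/1, or non-convergence) the model is refit with Firth
    bias-reduced likelihood and the reported p comes from the penalized
    likelihood-ratio test, which stays calibrated under separation where
    the Wald statistic degenerates; the fallback is always flagged.
    If age is constant it is dropped, reducing to the unadjusted fit.
    """
    meth = np.asarray(methylation, float)
    age = np.asarray(age, float)
    grp = np.asarray(group)
    if np.std(meth) == 0:
        raise ValidationError("methylation is constant; group test undefined")
    y = (grp == GROUP_DS).astype(float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both groups required")

    use_age = np.std(age) > 0
    cols = [np.ones_like(meth), meth] + ([age] if use_age else [])
    X = np.column_stack(cols)

    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and handled below via the Firth refit
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            fitted = fit.predict(X)
        # quasi-separation: fitted probabilities collapsing to the
        # boundary, or an exploding slope.  Near-separated fits keep a
        # finite Wald p only through an inflated SE (Hauck-Donner), so
        # they are routed to the Firth branch like fully separated ones.
        separated = (not fit.mle_retvals.get("converged", True)) or \
            np.any(fitted < 1e-6) or np.any(fitted > 1 - 1e-6) or \
            abs(fit.params[1]) * float(np.std(meth)) > 15.0
        if not separated:
            return {
                "coef": float(fit.params[1]),
                "p_methylation": float(fit.pvalues[1]),
                "method": "ml_wald",
                "firth": False,
                "n": len(y),
            }
    except Exception:  # statsmodels raises on perfect separation
        pass

    beta_full, pl_full, _ = _firth_fit(X, y)
    X_red = np.delete(X, 1, axis=1)
    _, pl_red, _ = _firth_fit(X_red, y)
    lr = max(0.0, 2.0 * (pl_full - pl_red))
    p = float(stats.chi2.sf(lr, df=1))
    logger.info("quasi-separation detected; Firth penalized-likelihood-ratio test used")
    return {
        "coef": float(beta_full[1]),
        "p_methylation": p,
        "method": "firth_plrt",
        "firth": True,
        "n": len(y),
    }


# ----------------------------------------------------------- stability

def stability_over_time(values: pd.DataFrame) -> pd.DataFrame:
    """Within-individual stability of region means across blood draws.

    ``values``: columns individual_id, gene, timepoint_index, region_mean.
    Returns per (individual, gene): the range (max - min) and the maximum
    pairwise absolute difference across time points; individuals with a
    single time point are excluded.
    """
    rows = []
    for (ind, gene), sub in values.groupby(["individual_id", "gene"], sort=False):
        v = sub["region_mean"].to_numpy(float)
        if len(v) < 2:
            continue
        rows.append({
            "individual_id": ind,
            "gene": gene,
            "n_timepoints": len(v),
            "range": float(v.max() - v.min()),
            "max_pair_diff": float(np.max(np.abs(v[:, None] - v[None, :]))),
        })
    return pd.DataFrame(rows, columns=["individual_id", "gene", "n_timepoints",
                                       "range", "max_pair_diff"])


def cohort_stability_summary(per_individual: pd.DataFrame) -> dict:
    """Cohort summary: median of within-individual ranges."""
    if len(per_individual) == 0:
        return {"n_pairs": 0, "median_range": float("nan")}
    return {
        "n_pairs": int(len(per_individual)),
        "median_range": float(per_individual["range"].median()),
    }


# ---------------------------------------------------------- mosaic dilution

def mosaic_dilution_predict(mu_tri: float, mu_di: float, f: float) -> float:
    """Expected bulk methylation of a mosaic sample: f*mu_tri + (1-f)*mu_di,
    since bulk methylation averages linearly over cells."""
    if not (0.0 <= f <= 1.0):
        raise ValidationError("mosaic fraction must lie in [0, 1]")
    return f * mu_tri + (1.0 - f) * mu_di


def mosaic_fraction_estimate(observed: float, mu_tri: float, mu_di: float) -> float:
    """Invert the dilution model: (observed - mu_di)/(mu_tri - mu_di),
    clipped to [0, 1].  Loci with equal state means are uninformative."""
    if mu_tri == mu_di:
        raise ValidationError("uninformative locus: trisomic and disomic means equal")
    return float(np.clip((observed - mu_di) / (mu_tri - mu_di), 0.0, 1.0))


def mosaic_fraction_estimate_panel(observed: dict, mu_tri: dict, mu_di: dict,
                                   variances: dict | None = None) -> dict:
    """Multi-gene mosaic fraction: inverse-variance-weighted mean of
    per-gene estimates.  Per-gene weights are (mu_tri - mu_di)^2 / var,
    i.e. the precision of each gene's f-hat; uniform when no variances are
    given.  (The descriptive mosaic tables in the source study perform no
    such estimation; this estimator is an extension.)"""
    genes = [g for g in observed if g in mu_tri and g in mu_di and mu_tri[g] != mu_di[g]]
    if not genes:
        raise ValidationError("no informative loci for mosaic estimation")
    ests = np.array([mosaic_fraction_estimate(observed[g], mu_tri[g], mu_di[g])
                     for g in genes])
    if variances:
        w = np.array([
            (mu_tri[g] - mu_di[g]) ** 2 / max(variances.get(g, 1.0), 1e-12)
            for g in genes
        ])
    else:
        w = np.ones(len(genes))
    f_hat = float(np.sum(w * ests) / np.sum(w))
    return {"f_hat": f_hat, "per_gene": dict(zip(genes, ests)), "n_genes": len(genes)}


# ------------------------------------------------------- mixture explainability

@dataclass
class MixtureSpec:
    """Cell-type mixture scenario at one locus.

    ``methylation``: per-type methylation fraction; ``lower``/``upper``:
    the plausible range of each type's proportion (from normal differential
    counts); ``reference``: the reference proportion vector w0.
    """

    cell_types: tuple
    methylation: tuple  # m_c, fractions
    lower: tuple
    upper: tuple
    reference: tuple  # w0, sums to 1

    def __post_init__(self):
        m, lo, hi, w0 = map(np.asarray, (self.methylation, self.lower, self.upper, self.reference))
        k = len(self.cell_types)
        if not (len(m) == len(lo) == len(hi) == len(w0) == k):
            raise ValidationError("mixture spec fields must have equal length")
        if np.any((m < 0) | (m > 1)) or np.any((lo < 0) | (hi > 1)) or np.any(lo > hi):
            raise ValidationError("mixture bounds/methylation outside [0, 1]")
        if abs(w0.sum() - 1.0) > 1e-9:
            raise ValidationError("reference proportions must sum to 1")
        if lo.sum() > 1.0 + 1e-12 or hi.sum() < 1.0 - 1e-12:
            raise ValidationError("infeasible proportion box: no vector in the box sums to 1")


def _extreme_mixture(m: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                     maximize: bool) -> np.ndarray:
    """LP extreme of sum(w*m) over {lo <= w <= hi, sum w = 1}.

    The optimum sits at a vertex of the polytope; greedy allocation of the
    remaining budget to cell types in order of methylation reaches it
    exactly (fractional-knapsack argument).
    """
    w = lo.astype(float).copy()
    budget = 1.0 - w.sum()
    order = np.argsort(-m if maximize else m, kind="stable")
    for idx in order:
        add = min(hi[idx] - lo[idx], budget)
        w[idx] += add
        budget -= add
        if budget <= 1e-15:
            break
    return w


def mixture_explained(observed_bulk_diff: float, spec: MixtureSpec) -> dict:
    """Could a shift in cell-type proportions alone account for the
    observed bulk methylation difference?

    Bulk methylation averages linearly over cells, so the achievable bulk
    shift relative to the reference proportions is max over the proportion
    polytope of |sum w_c m_c - sum w0_c m_c|; ``explainable`` is true when
    that maximum reaches |observed_bulk_diff|.  The answer is symmetric in
    the sign of the observed difference.
    """
    m = np.asarray(spec.methylation, float)
    lo = np.asarray(spec.lower, float)
    hi = np.asarray(spec.upper, float)
    w0 = np.asarray(spec.reference, float)
    ref = float(m @ w0)
    up = float(m @ _extreme_mixture(m, lo, hi, maximize=True))
    down = float(m @ _extreme_mixture(m, lo, hi, maximize=False))
    max_shift = max(up - ref, ref - down)
    max_shift = max(max_shift, 0.0)
    return {
        "max_achievable_shift": max_shift,
        "explainable": bool(max_shift >= abs(observed_bulk_diff) - 1e-12),
        "reference_bulk": ref,
        "max_bulk": up,
        "min_bulk": down,
    }
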