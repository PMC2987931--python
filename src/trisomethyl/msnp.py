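"""Methylation indices from methylation-sensitive digest-representation arrays.

Each biological sample is assayed by three genomic representations:
S (StyI only), SH (StyI + methylation-sensitive HpaII) and SM (StyI +
MspI, the methylation-insensitive isoschizomer).  At a locus with HpaII
sites between the StyI sites, methylation preserves SH signal while MspI
always cuts, so SM signal indicates incomplete digestion.  The
methylation index (MI) is the fractional preservation of intensity in SH
relative to S; the Class-2 filter keeps only loci whose SM/S ratio shows
reliable digestion (< 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("S", "SH", "SM")
MI_MODES = ("ratio", "background_subtracted")


def normalize_arrays(table: pd.DataFrame, invariant_probes=None) -> pd.DataFrame:
    """Scale every array to a common median intensity.

    An "array" is one (sample, representation, replicate) hybridisation.
    The common target is the global median over the invariant probe set
    (default: all probes).  This is a simple deterministic stand-in for
    model-based array normalisation.
    """
    t = table.copy()
    if invariant_probes is not None:
        inv = t[t["probe_id"].isin(set(invariant_probes))]
    else:
        inv = t
    target = float(inv["intensity"].median())
    keys = ["sample_id", "representation", "replicate"]
    med = inv.groupby(keys)["intensity"].median().rename("array_median")
    t = t.merge(med, on=keys, how="left")
    t["intensity"] = t["intensity"] * (target / t["array_median"])
    return t.drop(columns="array_median")


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean intensity per (probe, sample, representation).

    Returns a wide table with columns ``S_av, SH_av, SM_av`` plus the
    replicate counts; (probe, sample) cells missing any representation
    are flagged unusable.
    """
    bad = set(table["representation"]) - set(REPRESENTATIONS)
    if bad:
        raise ValidationError(f"unknown representations: {sorted(bad)}")
    if (table["intensity"] < 0).any():
        raise ValidationError("intensities must be >= 0")
    g = table.groupby(["probe_id", "sample_id", "representation"])["intensity"]
    means = g.mean().unstack("representation")
    counts = g.size().unstack("representation").fillna(0).astype(int)
    out = pd.DataFrame(index=means.index)
    for rep in REPRESENTATIONS:
        out[f"{rep}_av"] = means[rep] if rep in means else np.nan
        out[f"n_{rep}"] = counts[rep] if rep in counts else 0
    out["usable"] = out[[f"n_{r}" for r in REPRESENTATIONS]].gt(0).all(axis=1)
    n_bad = int((~out["usable"]).sum())
    if n_bad:
        logger.warning("%d probe/sample cells missing a representation", n_bad)
    return out.reset_index()


def class2_filter(averages: pd.DataFrame, ratio_threshold: float = 0.5) -> pd.DataFrame:
    """Reliability filter for informative (Class-2) loci.

    A probe passes when the median across samples of SM_av/S_av is
    strictly below ``ratio_threshold``: strong SM signal loss shows the
    flanking sites really are cut by the methylation-insensitive enzyme.
    The ratio is aggregated across samples (median) so the filter is an
    experiment-level property of the probe.
    """
    df = averages.copy()
    zero_s = df["S_av"] <= 0
    df["sm_s_ratio"] = np.where(zero_s, np.nan, df["SM_av"] / df["S_av"])
    per_probe = df.groupby("probe_id").agg(
        median_sm_s=("sm_s_ratio", "median"),
        any_zero_s=("S_av", lambda s: bool((s <= 0).any())),
    )
    per_probe["class2_pass"] = (per_probe["median_sm_s"] < ratio_threshold) & ~per_probe["any_zero_s"]
    per_probe["reason"] = np.where(
        per_probe["any_zero_s"], "zero_S_intensity",
        np.where(per_probe["class2_pass"], "", "sm_s_ratio_not_below_threshold"),
    )
    return per_probe.reset_index()


def methylation_index(averages: pd.DataFrame, mode: str = "ratio") -> pd.DataFrame:
    """Per (probe, sample) methylation index, clipped to [0, 1].

    ratio mode: MI = SH_av / S_av (fractional preservation of intensity).
    background_subtracted mode: MI = (SH_av - SM_av) / (S_av - SM_av),
    treating residual SM signal as undigested background; cells with
    S_av <= SM_av are returned missing with a reason.
    """
    if mode not in MI_MODES:
        raise ValidationError(f"unknown MI mode {mode!r}; choose from {MI_MODES}")
    df = averages.copy()
    s, sh, sm = (df[c].to_numpy(float) for c in ("S_av", "SH_av", "SM_av"))
    reason = np.full(len(df), "", dtype=object)
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.where(s > 0, sh / s, np.nan)
        reason[s <= 0] = "zero_S_intensity"
    else:
        denom = s - sm
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.where(denom > 0, (sh - sm) / denom, np.nan)
        reason[denom <= 0] = "S_not_above_SM_background"
    n_clip = int(np.sum((mi < 0) | (mi > 1)))
    if n_clip:
        logger.info("clipped %d MI values into [0,1] (%s mode)", n_clip, mode)
    df["mi"] = np.clip(mi, 0.0, 1.0)
    df["mi_reason"] = reason
    df.attrs["n_clipped"] = n_clip
    return df


def msnp_to_beta(mi_table: pd.DataFrame, class2: pd.DataFrame) -> BetaMatrix:
    """Beta matrix of MI values restricted to Class-2-passing probes."""
    passing = set(class2.loc[class2["class2_pass"], "probe_id"])
    sub = mi_table[mi_table["probe_id"].isin(passing)]
    wide = sub.pivot(index="probe_id", columns="sample_id", values="mi")
    wide.index.name = "probe_id"
    wide.columns.name = None
    return BetaMatrix(wide)


@dataclass
class MsnpResult:
    averages: pd.DataFrame
    class2: pd.DataFrame
    mi: pd.DataFrame
    beta: BetaMatrix


def run_msnp(table: pd.DataFrame, mode: str = "ratio", normalize: bool = False,
             ratio_threshold: float = 0.5) -> MsnpResult:
    """Full digest-array stage: (optional normalisation), replicate
    averaging, Class-2 filtering, MI computation, beta-matrix export."""
    if normalize:
        table = normalize_arrays(table)
    av = average_replicates(table)
    cls2 = class2_filter(av, ratio_threshold)
    mi = methylation_index(av, mode=mode)
    beta = msnp_to_beta(mi, cls2)
    return MsnpResult(averages=av, class2=cls2, mi=mi, beta=beta)
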