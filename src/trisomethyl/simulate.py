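"""Synthetic cohort generator.

Emulates the statistical structure of a trisomy-21 (DS) versus control
leukocyte methylation study so that every downstream stage runs without
external data:

* an Infinium-like beta matrix with planted differentially methylated loci
  at validated effect sizes, bounded beta-distributed noise, an age trend
  for selected loci in controls, mosaic-trisomy dilution, and a cell-type
  mixture layer (bulk methylation is the proportion-weighted average of
  per-cell-type values);
* methylation-sensitive digest-array intensity tables with the replicate
  structure of the wet assay (duplicate S and SH representations, single
  SM) and a configurable incomplete-digestion leak;
* per-CpG pyrosequencing percent-methylation tables for >= 8-CpG regions;
* qPCR cycle-threshold triplicates with trisomic 3:2 dosage effects and
  demethylating-drug (5aza-dC) dose-response series.

All randomness flows from a single mandatory seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    GROUP_CONTROL,
    GROUP_DS,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Noise concentration of the beta-distributed per-sample methylation draw,
# by the qualitative shape of the observed group distributions: dichotomous
# groups barely overlap, "overlapping" groups shift but mix, "wide" loci
# vary broadly within both groups.
SHAPE_DISPERSION = {
    "dichotomous": 150.0,
    "overlapping": 60.0,
    "wide": 15.0,
}

CELL_TYPES = ("pmn", "lymphocyte", "monocyte", "nk")
# Typical adult leukocyte differential: neutrophils dominate, lymphocytes
# second, monocytes and NK cells minor.
DEFAULT_CELL_PROPS = (0.60, 0.30, 0.06, 0.04)


@dataclass(frozen=True)
class LocusEffectSpec:
    """Planted effect at one locus: group means, noise shape, age trend."""

    gene: str
    mu_ds: float
    mu_ctrl: float
    shape: str = "overlapping"
    dispersion: float | None = None  # overrides the shape default when set
    age_slope_ctrl: float = 0.0  # change in fraction per year, controls only
    chrom: str = "1"
    position: int = 1_000_000
    cgi_flag: bool = False
    n_ds_printed: int | None = None  # targeted-validation sample sizes
    n_ctrl_printed: int | None = None

    def __post_init__(self):
        for mu in (self.mu_ds, self.mu_ctrl):
            if not (0.0 <= mu <= 1.0):
                raise ValidationError(f"{self.gene}: group mean {mu} outside [0,1]")
        if self.shape not in SHAPE_DISPERSION:
            raise ValidationError(f"{self.gene}: unknown shape {self.shape!r}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValidationError(f"{self.gene}: dispersion must be > 0")

    @property
    def effective_dispersion(self) -> float:
        return self.dispersion if self.dispersion is not None else SHAPE_DISPERSION[self.shape]


# Validated differentially methylated panel: per-gene mean percent
# methylation in DS and control leukocytes (stored as fractions), the
# qualitative distribution shape, and the targeted-assay sample sizes.
# TMEM131 methylation declines with age in controls; DS values are
# uniformly low regardless of age.
TABLE1_PANEL: tuple[LocusEffectSpec, ...] = (
    LocusEffectSpec("TMEM131", 0.109, 0.411, "dichotomous", age_slope_ctrl=-0.002,
                    chrom="2", position=97_000_000, n_ds_printed=207, n_ctrl_printed=73),
    LocusEffectSpec("TCF7", 0.265, 0.440, "overlapping",
                    chrom="5", position=134_100_000, n_ds_printed=207, n_ctrl_printed=64),
    LocusEffectSpec("SH3BP2", 0.345, 0.236, "overlapping",
                    chrom="4", position=2_800_000, cgi_flag=True,
                    n_ds_printed=203, n_ctrl_printed=67),
    LocusEffectSpec("FAM62C", 0.460, 0.401, "wide",
                    chrom="3", position=158_400_000, n_ds_printed=87, n_ctrl_printed=45),
    LocusEffectSpec("CD3Z", 0.160, 0.290, "dichotomous",
                    chrom="1", position=167_400_000, n_ds_printed=113, n_ctrl_printed=45),
    LocusEffectSpec("PLD6", 0.231, 0.108, "dichotomous",
                    chrom="17", position=17_200_000, cgi_flag=True,
                    n_ds_printed=105, n_ctrl_printed=40),
    LocusEffectSpec("EIF4E", 0.240, 0.147, "dichotomous",
                    chrom="4", position=99_800_000, cgi_flag=True,
                    n_ds_printed=110, n_ctrl_printed=42),
    LocusEffectSpec("CPT1B", 0.711, 0.462, "dichotomous",
                    chrom="22", position=50_570_000, cgi_flag=True,
                    n_ds_printed=73, n_ctrl_printed=33),
    LocusEffectSpec("SUMO3", 0.530, 0.407, "overlapping",
                    chrom="21", position=44_800_000, cgi_flag=True,
                    n_ds_printed=98, n_ctrl_printed=39),
)

# The eight genes with strongly significant (p < .0001) group differences;
# FAM62C differs more weakly (p = .005) and is excluded.
STRONG_GENES = ("TMEM131", "TCF7", "SH3BP2", "CD3Z", "PLD6", "EIF4E", "CPT1B", "SUMO3")


@dataclass(frozen=True)
class ExpressionGeneSpec:
    """Per-gene expression behaviour for the qPCR simulation.

    ``fold_ds`` is the expected DS/control ratio of relative expression;
    ``aza_sign`` is the direction of the 5aza-dC dose response (+1 up,
    -1 down, 0 none); ``dosage`` marks a pure chromosome-21 copy-number
    gene (fold follows copy number 3:2).
    """

    gene: str
    fold_ds: float
    aza_sign: int
    dosage: bool = False
    base_expression: float = 1.0


# Expression behaviour of the genes followed up by qPCR: promoter-
# hypomethylated genes over-expressed in DS (TMEM131 short isoform, NPDC1,
# NOD2, CD3Z), TCF7 under-expressed, SUMO3 a chromosome-21 dosage gene
# (1.5-fold), CPT1B paradoxically over-expressed despite hypermethylation.
EXPRESSION_PANEL: tuple[ExpressionGeneSpec, ...] = (
    ExpressionGeneSpec("TMEM131", 2.5, +1),
    ExpressionGeneSpec("TCF7", 0.45, -1),
    ExpressionGeneSpec("NPDC1", 2.0, +1),
    ExpressionGeneSpec("NOD2", 2.0, +1),
    ExpressionGeneSpec("CD3Z", 2.5, +1),
    ExpressionGeneSpec("SUMO3", 1.5, 0, dosage=True),
    ExpressionGeneSpec("CPT1B", 1.8, +1),
)


@dataclass
class MsnpSpec:
    """Digest-array noise model.

    ``leak`` is the undigested fraction surviving either enzyme
    (incomplete digestion): SH expectation S*(MI*(1-leak)+leak), SM
    expectation S*leak at informative loci.  Replicate noise is
    multiplicative lognormal.
    """

    baseline_intensity: float = 1000.0
    probe_intensity_sd: float = 0.3  # lognormal sigma of per-probe baseline
    sample_scale_sd: float = 0.1  # lognormal sigma of per-array scale
    replicate_noise_sd: float = 0.05
    leak: float = 0.02
    n_noninformative: int = 25  # loci without adjacent HpaII sites (SM ~ S)


@dataclass
class PyroseqSpec:
    n_cpgs: int = 10
    cpg_noise_sd: float = 0.025  # per-CpG fraction-scale measurement noise


@dataclass
class ExpressionSpec:
    genes: tuple[ExpressionGeneSpec, ...] = EXPRESSION_PANEL
    expr_cv: float = 0.25  # lognormal sigma of biological expression spread
    ct_noise_sd: float = 0.15  # cycles, per qPCR replicate
    ref_ct: float = 20.0
    base_dct: float = 4.0  # cycles between reference and a unit-expression target
    n_replicates: int = 3
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.5)  # 5aza-dC, uM
    dose_potency: float = 0.5  # log-fold change per uM
    dose_noise_cv: float = 0.2
    dose_reps: int = 3


@dataclass
class CohortConfig:
    """Complete description of a simulated case-control study."""

    seed: int
    n_ds: int = 29
    n_ctrl: int = 20
    age_range_ds: tuple[float, float] = (20.0, 70.0)
    age_range_ctrl: tuple[float, float] = (20.0, 70.0)
    loci: tuple[LocusEffectSpec, ...] = TABLE1_PANEL
    n_null_loci: int = 500
    null_dispersion: float = 60.0
    null_mu_range: tuple[float, float] = (0.05, 0.95)
    # mosaic DS samples: {DS sample index (0-based) -> trisomic fraction}
    mosaics: dict = field(default_factory=dict)
    # individuals with repeat blood draws (longitudinal stability)
    n_ds_repeat: int = 0
    # cell-type mixture layer
    cell_types: tuple[str, ...] = CELL_TYPES
    cell_props: tuple[float, ...] = DEFAULT_CELL_PROPS
    prop_concentration: float = 200.0
    # optional per-gene per-cell-type methylation offsets (fraction units)
    celltype_offsets: dict = field(default_factory=dict)
    msnp: MsnpSpec = field(default_factory=MsnpSpec)
    pyroseq: PyroseqSpec = field(default_factory=PyroseqSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    include_msnp: bool = True
    include_pyroseq: bool = True
    include_expression: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory for simulation")
        if self.n_ds < 0 or self.n_ctrl < 0 or self.n_null_loci < 0:
            raise ValidationError("counts must be >= 0")
        if abs(sum(self.cell_props) - 1.0) > 1e-9:
            raise ValidationError("cell-type proportions must sum to 1")


def table1_default_config(seed: int = 0, n_ds: int = 29, n_ctrl: int = 20,
                          n_null_loci: int = 500, **overrides) -> CohortConfig:
    """Study-default configuration: the validated 9-gene effect panel at its
    published group means, plus ``n_null_loci`` null loci, at the
    genome-wide screen's cohort size (29 DS / 20 controls)."""
    overrides.setdefault("loci", TABLE1_PANEL)
    return CohortConfig(seed=seed, n_ds=n_ds, n_ctrl=n_ctrl,
                        n_null_loci=n_null_loci, **overrides)


@dataclass
class SimulatedCohort:
    """All tables produced for one simulated study."""

    config: CohortConfig
    sheet: SampleSheet
    beta: BetaMatrix
    annotation: ProbeAnnotation
    truth: pd.DataFrame  # per (probe, sample) pre-mixture methylation
    celltype_values: dict  # cell type -> DataFrame like truth
    msnp: pd.DataFrame | None
    pyroseq: pd.DataFrame | None
    ct: pd.DataFrame | None
    dose: pd.DataFrame | None
    n_clipped: int


# ------------------------------------------------------------------ internals

def _beta_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    a = mean * dispersion
    b = (1.0 - mean) * dispersion
    return rng.beta(a, b)


def _clip_means(mu: np.ndarray, counter: list) -> np.ndarray:
    lo, hi = 1e-4, 1.0 - 1e-4
    n_bad = int(np.sum((mu < lo) | (mu > hi)))
    if n_bad:
        counter[0] += n_bad
        logger.warning("clipped %d expected methylation values into [0,1]", n_bad)
    return np.clip(mu, lo, hi)


def _build_sheet(config: CohortConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    ages_ds = rng.uniform(*config.age_range_ds, size=config.n_ds)
    ages_ctrl = rng.uniform(*config.age_range_ctrl, size=config.n_ctrl)
    props = rng.dirichlet(
        np.asarray(config.cell_props) * config.prop_concentration,
        size=config.n_ds + config.n_ctrl + config.n_ds_repeat,
    )
    k = 0
    for i in range(config.n_ds):
        rows.append({
            "sample_id": f"DS{i + 1:02d}",
            "group": GROUP_DS,
            "age": round(float(ages_ds[i]), 2),
            "timepoint_index": 0,
            "individual_id": f"ds_ind{i + 1:02d}",
            "mosaic_fraction": float(config.mosaics.get(i, 1.0)),
            **{f"prop_{t}": props[k][j] for j, t in enumerate(config.cell_types)},
        })
        k += 1
    # repeat draws: second time point for the first n_ds_repeat DS individuals
    for i in range(min(config.n_ds_repeat, config.n_ds)):
        rows.append({
            "sample_id": f"DS{i + 1:02d}_t1",
            "group": GROUP_DS,
            "age": round(float(ages_ds[i]) + 3.0, 2),
            "timepoint_index": 1,
            "individual_id": f"ds_ind{i + 1:02d}",
            "mosaic_fraction": float(config.mosaics.get(i, 1.0)),
            **{f"prop_{t}": props[k][j] for j, t in enumerate(config.cell_types)},
        })
        k += 1
    for i in range(config.n_ctrl):
        rows.append({
            "sample_id": f"C{i + 1:02d}",
            "group": GROUP_CONTROL,
            "age": round(float(ages_ctrl[i]), 2),
            "timepoint_index": 0,
            "individual_id": f"ctrl_ind{i + 1:02d}",
            "mosaic_fraction": 0.0,
            **{f"prop_{t}": props[k][j] for j, t in enumerate(config.cell_types)},
        })
        k += 1
    return SampleSheet(pd.DataFrame(rows))


def _all_loci(config: CohortConfig, rng: np.random.Generator):
    """Planted panel plus generated null loci (shared mu across groups)."""
    loci = list(config.loci)
    lo, hi = config.null_mu_range
    null_mu = rng.uniform(lo, hi, size=config.n_null_loci)
    null_chrom = rng.integers(1, 23, size=config.n_null_loci)
    for j in range(config.n_null_loci):
        loci.append(LocusEffectSpec(
            gene=f"NULL{j + 1:04d}",
            mu_ds=float(null_mu[j]),
            mu_ctrl=float(null_mu[j]),
            shape="overlapping",
            dispersion=config.null_dispersion,
            chrom=str(null_chrom[j]),
            position=1_000_000 + 1000 * j,
        ))
    return loci


def _build_annotation(loci, extra_noninf=0) -> ProbeAnnotation:
    rows = [{
        "probe_id": spec.gene,
        "chrom": spec.chrom,
        "position": spec.position,
        "gene": spec.gene,
        "cgi_flag": spec.cgi_flag,
        "assay_class": "infinium_cpg",
    } for spec in loci]
    for j in range(extra_noninf):
        rows.append({
            "probe_id": f"NONINF{j + 1:04d}",
            "chrom": str(1 + j % 22),
            "position": 500_000 + 1000 * j,
            "gene": "",
            "cgi_flag": False,
            "assay_class": "msnp_class2",
        })
    return ProbeAnnotation(pd.DataFrame(rows))


# ------------------------------------------------------------------ cohort

def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate the full study: sample sheet, beta matrix (with cell-type
    mixture layer), digest-array intensities, pyrosequencing tables and
    qPCR tables, all reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    clip_counter = [0]

    sheet = _build_sheet(config, rng)
    t = sheet.table
    sample_ids = t["sample_id"].tolist()
    loci = _all_loci(config, rng)
    annotation = _build_annotation(loci, config.msnp.n_noninformative if config.include_msnp else 0)

    age = t["age"].to_numpy(float)
    mosaic = t["mosaic_fraction"].to_numpy(float)
    is_ctrl = (t["group"] == GROUP_CONTROL).to_numpy()
    age_mid_ctrl = float(np.mean(config.age_range_ctrl))

    # pre-mixture ("true") methylation per locus and sample
    truth_rows = {}
    for spec in loci:
        mu = np.where(
            is_ctrl,
            spec.mu_ctrl + spec.age_slope_ctrl * (age - age_mid_ctrl),
            mosaic * spec.mu_ds + (1.0 - mosaic) * spec.mu_ctrl,
        )
        mu = _clip_means(mu, clip_counter)
        truth_rows[spec.gene] = _beta_draw(rng, mu, spec.effective_dispersion)
    truth = pd.DataFrame(truth_rows, index=sample_ids).T
    truth.index.name = "probe_id"

    # repeat draws share the individual's underlying state: redraw noise only
    # around the same expected value, which the construction above already
    # does (same mosaic fraction and group mean).

    # cell-type mixture layer: bulk = sum_c w_c * m_c
    prop_cols = [f"prop_{ct}" for ct in config.cell_types]
    W = t[prop_cols].to_numpy(float)  # samples x cell types
    celltype_values = {}
    bulk = np.zeros_like(truth.to_numpy())
    for c, ct in enumerate(config.cell_types):
        m_c = truth.to_numpy().copy()
        for g, offsets in config.celltype_offsets.items():
            if g in truth.index and ct in offsets:
                gi = truth.index.get_loc(g)
                m_c[gi, :] = np.clip(m_c[gi, :] + offsets[ct], 0.0, 1.0)
        celltype_values[ct] = pd.DataFrame(m_c, index=truth.index, columns=truth.columns)
        bulk += W[:, c][None, :] * m_c
    beta = BetaMatrix(pd.DataFrame(bulk, index=truth.index, columns=truth.columns))

    msnp_table = generate_msnp_intensities(truth, config, rng) if config.include_msnp else None

    pyroseq = None
    if config.include_pyroseq:
        frames = []
        for spec in config.loci:
            vals = beta.values.loc[spec.gene]
            frames.append(_pyroseq_from_truth(
                spec.gene, vals.index.to_numpy(), vals.to_numpy(float), config.pyroseq, rng))
        pyroseq = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["gene", "sample_id", "cpg_index", "percent"])

    ct_tab = dose_tab = None
    if config.include_expression:
        ct_tab, dose_tab = generate_expression(config, sheet, rng)

    return SimulatedCohort(
        config=config, sheet=sheet, beta=beta, annotation=annotation,
        truth=truth, celltype_values=celltype_values, msnp=msnp_table,
        pyroseq=pyroseq, ct=ct_tab, dose=dose_tab, n_clipped=clip_counter[0],
    )


# ------------------------------------------------------------------ MSNP

def generate_msnp_intensities(truth: pd.DataFrame, config: CohortConfig,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Digest-representation intensities for every locus in ``truth``.

    Per biological sample: duplicate S and SH arrays, a single SM array.
    At informative (HpaII-flanked) loci the expected intensities are
    S_true, S_true*(MI*(1-leak)+leak) and S_true*leak; non-informative
    loci retain full signal in every representation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    spec = config.msnp
    samples = list(truth.columns)
    probes = list(truth.index)
    noninf = [f"NONINF{j + 1:04d}" for j in range(spec.n_noninformative)]

    base = spec.baseline_intensity * np.exp(
        rng.normal(0.0, spec.probe_intensity_sd, size=len(probes) + len(noninf)))
    sample_scale = np.exp(rng.normal(0.0, spec.sample_scale_sd, size=len(samples)))

    mi_true = truth.to_numpy(float)  # probes x samples
    all_probes = probes + noninf
    s_true = base[:, None] * sample_scale[None, :]  # (probes+noninf) x samples

    frac = {
        "S": np.ones((len(all_probes), len(samples))),
        "SH": np.vstack([
            mi_true * (1.0 - spec.leak) + spec.leak,
            np.ones((len(noninf), len(samples))),
        ]),
        "SM": np.vstack([
            np.full((len(probes), len(samples)), spec.leak),
            np.ones((len(noninf), len(samples))),
        ]),
    }
    reps = {"S": 2, "SH": 2, "SM": 1}
    records = []
    for rep_name in ("S", "SH", "SM"):
        expected = s_true * frac[rep_name]
        for r in range(reps[rep_name]):
            noise = np.exp(rng.normal(0.0, spec.replicate_noise_sd, size=expected.shape)) \
                if spec.replicate_noise_sd > 0 else 1.0
            obs = expected * noise
            records.append(pd.DataFrame({
                "probe_id": np.repeat(all_probes, len(samples)),
                "sample_id": np.tile(samples, len(all_probes)),
                "representation": rep_name,
                "replicate": r,
                "intensity": obs.ravel(),
            }))
    return pd.concat(records, ignore_index=True)


# ------------------------------------------------------------------ pyroseq

def _pyroseq_from_truth(gene: str, sample_ids: np.ndarray, truth: np.ndarray,
                        spec: PyroseqSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = len(sample_ids)
    eps = rng.normal(0.0, spec.cpg_noise_sd, size=(n, spec.n_cpgs)) \
        if spec.cpg_noise_sd > 0 else np.zeros((n, spec.n_cpgs))
    per_cpg = np.clip(truth[:, None] + eps, 0.0, 1.0) * 100.0
    return pd.DataFrame({
        "gene": gene,
        "sample_id": np.repeat(sample_ids, spec.n_cpgs),
        "cpg_index": np.tile(np.arange(spec.n_cpgs), n),
        "percent": per_cpg.ravel(),
    })


def generate_pyroseq_group(spec: LocusEffectSpec, group: str, n: int, seed: int,
                           age_range: tuple[float, float] = (20.0, 70.0),
                           pyroseq: PyroseqSpec | None = None) -> pd.DataFrame:
    """Targeted pyrosequencing simulation for one gene and one group at an
    arbitrary sample size (the validation series is much larger than the
    array cohort).  Controls get the gene's age trend over ``age_range``."""
    if pyroseq is None:
        pyroseq = PyroseqSpec()
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n)
    age_mid = float(np.mean(age_range))
    if group == GROUP_CONTROL:
        mu = spec.mu_ctrl + spec.age_slope_ctrl * (age - age_mid)
    else:
        mu = np.full(n, spec.mu_ds)
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    truth = _beta_draw(rng, mu, spec.effective_dispersion)
    ids = np.array([f"{group}{i + 1:03d}" for i in range(n)])
    df = _pyroseq_from_truth(spec.gene, ids, truth, pyroseq, rng)
    df["age"] = np.repeat(age, pyroseq.n_cpgs)
    df["group"] = group
    return df


# ------------------------------------------------------------------ expression

def generate_expression(config: CohortConfig, sheet: SampleSheet,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR CT triplicates per sample/gene plus 5aza-dC dose-response series.

    Dosage genes scale with mean chromosome-21 copy number (2 + trisomic
    fraction), so a complete-trisomy group shows the 3:2 = 1.5-fold ratio.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    spec = config.expression
    t = sheet.table
    ct_rows = []
    for g in spec.genes:
        for _, row in t.iterrows():
            if row["group"] == GROUP_DS:
                if g.dosage:
                    fold = (2.0 + row["mosaic_fraction"]) / 2.0
                else:
                    f = row["mosaic_fraction"]
                    fold = f * g.fold_ds + (1.0 - f) * 1.0
            else:
                fold = 1.0
            expr = g.base_expression * fold
            if spec.expr_cv > 0:
                expr *= float(np.exp(rng.normal(0.0, spec.expr_cv)))
            dct = spec.base_dct - np.log2(expr)
            for r in range(spec.n_replicates):
                noise_t = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                noise_r = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                ct_rows.append({
                    "sample_id": row["sample_id"],
                    "gene": g.gene,
                    "replicate": r,
                    "ct": spec.ref_ct + dct + noise_t,
                    "reference_ct": spec.ref_ct + noise_r,
                })
    ct_df = pd.DataFrame(ct_rows)

    dose_rows = []
    for g in spec.genes:
        if g.aza_sign == 0:
            continue
        for condition in ("Jurkat", "PBMC"):
            for d in spec.doses:
                expected = g.base_expression * np.exp(g.aza_sign * spec.dose_potency * d)
                for r in range(spec.dose_reps):
                    v = expected
                    if spec.dose_noise_cv > 0:
                        v *= float(np.exp(rng.normal(0.0, spec.dose_noise_cv)))
                    dose_rows.append({
                        "gene": g.gene,
                        "condition": condition,
                        "dose": d,
                        "replicate": r,
                        "expression": v,
                    })
    dose_df = pd.DataFrame(dose_rows)
    return ct_df, dose_df


def generate_dose_series(gene_spec: ExpressionGeneSpec, seed: int,
                         spec: ExpressionSpec | None = None) -> pd.DataFrame:
    """Stand-alone 5aza-dC dose-response series for one gene (one condition)."""
    if spec is None:
        spec = ExpressionSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for d in spec.doses:
        expected = gene_spec.base_expression * np.exp(
            gene_spec.aza_sign * spec.dose_potency * d)
        for r in range(spec.dose_reps):
            v = expected
            if spec.dose_noise_cv > 0:
                v *= float(np.exp(rng.normal(0.0, spec.dose_noise_cv)))
            rows.append({"gene": gene_spec.gene, "condition": "PBMC",
                         "dose": d, "replicate": r, "expression": v})
    return pd.DataFrame(rows)


def panel_gene(gene: str) -> LocusEffectSpec:
    """Look up a validated-panel locus by gene symbol."""
    for spec in TABLE1_PANEL:
        if spec.gene == gene:
            return spec
    raise KeyError(gene)
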