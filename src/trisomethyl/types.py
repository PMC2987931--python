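"""Shared domain types for the methylation analysis pipeline.

All methylation values are stored internally as *fractions* in [0, 1];
percent (100x) appears only at presentation boundaries (pyrosequencing
tables, printed reports).  Keeping a single internal unit avoids 100x
scale bugs between the array, pyrosequencing and simulation layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALLOWED_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
SEX_CHROMS = ("X", "Y")

ASSAY_CLASSES = ("msnp_class2", "infinium_cpg", "pyroseq_region")

GROUP_DS = "DS"
GROUP_CONTROL = "control"
GROUPS = (GROUP_DS, GROUP_CONTROL)


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def _chrom_sort_key(chrom: str) -> tuple[int, int]:
    """Order chromosomes 1..22 numerically, then X, then Y."""
    if chrom == "X":
        return (1, 0)
    if chrom == "Y":
        return (1, 1)
    return (0, int(chrom))


@dataclass
class ProbeAnnotation:
    """Locus annotation table: identity, position, gene, CGI flag, assay class.

    Positions are 1-based inclusive (converted to 0-based half-open only at
    BED export).  ``cgi_flag`` marks regions meeting CpG-island criteria
    (GC >= 50%, length > 200 bp, observed/expected CpG > 0.6).
    """

    table: pd.DataFrame  # columns: probe_id, chrom, position, gene, cgi_flag, assay_class

    REQUIRED = ("probe_id", "chrom", "position", "gene", "cgi_flag", "assay_class")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe ids in annotation: {dups[:5]}")
        bad_chrom = sorted(set(t["chrom"].astype(str)) - set(ALLOWED_CHROMS))
        if bad_chrom:
            raise ValidationError(f"chromosome names outside allowed set: {bad_chrom}")
        if (t["position"] < 1).any():
            bad = t.loc[t["position"] < 1, "probe_id"].tolist()
            raise ValidationError(f"positions must be >= 1; offending probes: {bad[:5]}")
        bad_cls = sorted(set(t["assay_class"]) - set(ASSAY_CLASSES))
        if bad_cls:
            raise ValidationError(f"unknown assay classes: {bad_cls}")
        self.table = t.reset_index(drop=True)

    def lookup(self, probe_ids) -> pd.DataFrame:
        """Return annotation rows for ``probe_ids``; error on unannotated probes."""
        idx = self.table.set_index("probe_id")
        missing = [p for p in probe_ids if p not in idx.index]
        if missing:
            raise ValidationError(f"probes without annotation: {missing[:10]}")
        return idx.loc[list(probe_ids)].reset_index()

    def sex_probes(self) -> list[str]:
        mask = self.table["chrom"].isin(SEX_CHROMS)
        return self.table.loc[mask, "probe_id"].tolist()


@dataclass
class BetaMatrix:
    """Fractional methylation (beta) values, probes x samples, in [0, 1].

    Missing values are NaN and are never silently imputed; downstream
    operations either drop flagged loci (with a logged count) or skip them
    with a reason.
    """

    values: pd.DataFrame  # index: probe_id, columns: sample_id, float in [0,1] or NaN

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )
        self.values = v.astype(float)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])


@dataclass
class SampleSheet:
    """Per-sample metadata: group, age, time point, mosaicism, cell counts.

    ``mosaic_fraction`` is the fraction of trisomic cells (1.0 = complete
    trisomy 21; controls 0.0).  Optional cell-type proportion columns are
    prefixed ``prop_`` and must sum to 1 per sample.
    """

    table: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "group",
        "age",
        "timepoint_index",
        "individual_id",
        "mosaic_fraction",
    )

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sheet")
        bad_grp = sorted(set(t["group"]) - set(GROUPS))
        if bad_grp:
            raise ValidationError(f"unknown group labels: {bad_grp}")
        if (t["age"] < 0).any():
            raise ValidationError("ages must be >= 0")
        mf = t["mosaic_fraction"].to_numpy(dtype=float)
        if np.any((mf < 0) | (mf > 1)):
            raise ValidationError("mosaic_fraction must lie in [0, 1]")
        prop_cols = self.prop_columns
        if prop_cols:
            sums = t[prop_cols].sum(axis=1).to_numpy(dtype=float)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = t.loc[np.abs(sums - 1.0) > 1e-9, "sample_id"].tolist()
                raise ValidationError(
                    f"cell-type proportions do not sum to 1 for samples: {bad[:5]}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def prop_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("prop_")]

    def groups_for(self, sample_ids) -> pd.Series:
        """Group label per sample id, in the given order."""
        idx = self.table.set_index("sample_id")["group"]
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise ValidationError(f"samples missing from sheet: {missing[:10]}")
        return idx.loc[list(sample_ids)]

    def unique_cases(self) -> "SampleSheet":
        """Restrict to each individual's first blood draw (timepoint 0).

        Repeated draws from the same individual are reserved for the
        longitudinal stability analysis and excluded from group testing.
        """
        return SampleSheet(self.table[self.table["timepoint_index"] == 0].copy())


@dataclass
class DiffMethCriteria:
    """Layered differential-methylation thresholds.

    ``fold_threshold`` applies to max(group means)/min(group means);
    ``abs_diff_threshold`` is in fraction units (0 disables the criterion).
    """

    p_threshold: float = 0.01
    fold_threshold: float = 1.2
    abs_diff_threshold: float = 0.0
    exclude_sex_chroms: bool = True
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.fold_threshold <= 1.0:
            raise ValidationError("fold_threshold must be > 1")
        if self.abs_diff_threshold < 0:
            raise ValidationError("abs_diff_threshold must be >= 0")


# Screen presets: MSNP screen (fold only), peripheral-blood-leukocyte
# Infinium screen, and the T-cell Infinium screen.
CRITERIA_PRESETS: dict[str, DiffMethCriteria] = {
    "msnp": DiffMethCriteria(0.01, 1.2, 0.0, True, name="msnp"),
    "pbl": DiffMethCriteria(0.01, 1.2, 0.10, True, name="pbl"),
    "tcell": DiffMethCriteria(0.01, 1.3, 0.15, True, name="tcell"),
}


def criteria_preset(name: str) -> DiffMethCriteria:
    try:
        return CRITERIA_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown criteria preset {name!r}; choose from {sorted(CRITERIA_PRESETS)}"
        ) from None
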