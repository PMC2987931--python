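"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV.  Writers optionally emit a single ``#`` comment
header carrying the tool version and the run seed; readers skip comment
lines.  Writing uses pandas' shortest-round-trip float formatting so a
write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from . import __version__
from .types import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
    _chrom_sort_key,
)


def _header_comment(seed=None) -> str:
    line = f"# trisomethyl v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _write_tsv(df: pd.DataFrame, path, *, index: bool, seed=None, comment: bool = True) -> None:
    buf = _io.StringIO()
    if comment:
        buf.write(_header_comment(seed))
    df.to_csv(buf, sep="\t", index=index, na_rep="")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------- beta matrix

def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV of fractional methylation values.

    First column is ``probe_id``, header row holds sample ids; cells are
    numeric or empty (missing).  Out-of-range or duplicate entries raise a
    :class:`ValidationError` naming the offending probe/sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return BetaMatrix(df.astype(float))


def write_beta_matrix(matrix: BetaMatrix, path, seed=None) -> None:
    _write_tsv(matrix.values, path, index=True, seed=seed)


# ---------------------------------------------------------------- sample sheet

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    df["sample_id"] = df["sample_id"].astype(str)
    df["individual_id"] = df["individual_id"].astype(str)
    df["group"] = df["group"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, seed=None) -> None:
    _write_tsv(sheet.table, path, index=False, seed=seed)


# ----------------------------------------------------------------- annotation

def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df["probe_id"] = df["probe_id"].astype(str)
    df["gene"] = df["gene"].fillna("").astype(str)
    df["cgi_flag"] = df["cgi_flag"].astype(bool)
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path, seed=None) -> None:
    _write_tsv(annotation.table, path, index=False, seed=seed)


# ---------------------------------------------------------------- long tables

def read_long_table(path) -> pd.DataFrame:
    """Read a generic long-format TSV (MSNP intensities, pyroseq, CT, dose)."""
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_long_table(df: pd.DataFrame, path, seed=None) -> None:
    _write_tsv(df, path, index=False, seed=seed)


# -------------------------------------------------------------------- results

def write_results_table(calls: pd.DataFrame, path, seed=None) -> None:
    """Write per-locus differential-methylation statistics as TSV."""
    _write_tsv(calls, path, index=False, seed=seed)


def export_bed(calls: pd.DataFrame, annotation: ProbeAnnotation, path, seed=None) -> None:
    """Export called loci as BED6.

    Annotation positions are 1-based inclusive; BED uses 0-based half-open
    intervals, so a probe at position ``p`` becomes ``[p-1, p)``.  Records
    are sorted by chromosome (1..22, X, Y) then start.  Probes missing from
    the annotation raise an error listing the ids.
    """
    probe_ids = list(calls["probe_id"])
    ann = annotation.lookup(probe_ids)
    bed = pd.DataFrame(
        {
            "chrom": ann["chrom"].astype(str),
            "start": ann["position"].astype(int) - 1,
            "end": ann["position"].astype(int),
            "name": ann["probe_id"],
            "score": 0,
            "strand": ".",
        }
    )
    bed = bed.sort_values(
        by=["chrom", "start"],
        key=lambda col: col.map(_chrom_sort_key) if col.name == "chrom" else col,
        kind="stable",
    ).reset_index(drop=True)
    with open(path, "w") as fh:
        bed.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file back to a table with 1-based positions."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    df["position"] = df["start"].astype(int) + 1
    return df
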