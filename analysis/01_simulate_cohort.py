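#!/usr/bin/env python
"""Simulate the study cohort.

Generates the full synthetic case-control study at the genome-wide
screen's size (29 DS / 20 controls) with the validated nine-gene effect
panel, 500 null loci, digest-array intensities, pyrosequencing tables
and qPCR tables, and writes every table under results/cohort/.
"""

from pathlib import Path

from trisomethyl import io
from trisomethyl.simulate import generate_cohort, table1_default_config

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = table1_default_config(seed=SEED, n_ds_repeat=4, mosaics={28: 0.45})
    coh = generate_cohort(cfg)

    io.write_sample_sheet(coh.sheet, OUT / "sample_sheet.tsv", seed=SEED)
    io.write_beta_matrix(coh.beta, OUT / "beta.tsv", seed=SEED)
    io.write_annotation(coh.annotation, OUT / "annotation.tsv", seed=SEED)
    io.write_long_table(coh.msnp, OUT / "msnp_intensities.tsv", seed=SEED)
    io.write_long_table(coh.pyroseq, OUT / "pyroseq.tsv", seed=SEED)
    io.write_long_table(coh.ct, OUT / "qpcr_ct.tsv", seed=SEED)
    io.write_long_table(coh.dose, OUT / "aza_dose_response.tsv", seed=SEED)

    n_ds = (coh.sheet.table["group"] == "DS").sum()
    n_ctrl = (coh.sheet.table["group"] == "control").sum()
    print(f"cohort: {n_ds} DS samples (incl. 4 repeat draws, 1 mosaic at 45% "
          f"trisomic cells), {n_ctrl} controls")
    print(f"beta matrix: {len(coh.beta.probes)} loci x {len(coh.beta.samples)} samples "
          f"({cfg.n_null_loci} null + {len(cfg.loci)} planted)")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
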