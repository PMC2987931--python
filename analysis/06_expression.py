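#!/usr/bin/env python
"""qPCR expression analysis.

Relative expression by the delta-CT method, DS/control group tests,
the chromosome-21 dosage expectation, 5aza-dC dose-response trends, and
methylation-expression concordance (paradoxical genes flagged).
"""

from pathlib import Path

import pandas as pd

from trisomethyl import io
from trisomethyl.expression import (
    dosage_expectation,
    dose_response_trend,
    group_expression_test,
    methylation_expression_concordance,
    relative_expression_table,
)
from trisomethyl.simulate import TABLE1_PANEL

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ct = io.read_long_table(ROOT / "cohort" / "qpcr_ct.tsv")
    dose = io.read_long_table(ROOT / "cohort" / "aza_dose_response.tsv")
    sheet = io.read_sample_sheet(ROOT / "cohort" / "sample_sheet.tsv")
    out = ROOT / "expression"
    out.mkdir(parents=True, exist_ok=True)

    rel = relative_expression_table(ct)
    grp = sheet.table.set_index("sample_id")["group"]
    rows = []
    for gene, sub in rel.groupby("gene", sort=False):
        res = group_expression_test(sub["relative_expression"],
                                    grp.loc[sub["sample_id"]].to_numpy())
        rows.append({"gene": gene, **res})
    tests = pd.DataFrame(rows)
    io.write_results_table(tests, out / "group_tests.tsv", seed=1)

    print("DS/control expression folds (Welch t-test):")
    for _, r in tests.iterrows():
        print(f"  {r['gene']:>8}: fold {r['fold']:.2f}, p = {r['p']:.2e}")
    sumo3 = tests.set_index("gene").loc["SUMO3"]
    print(f"SUMO3 vs pure chromosome-21 dosage expectation "
          f"{dosage_expectation(3, 2):.2f}: observed {sumo3['fold']:.2f}")

    print("5aza-dC dose-response trends (Spearman):")
    trends = []
    for (gene, cond), sub in dose.groupby(["gene", "condition"], sort=False):
        res = dose_response_trend(sub["dose"], sub["expression"])
        trends.append({"gene": gene, "condition": cond, **res})
        print(f"  {gene:>8} [{cond}]: {res['direction']} "
              f"(rho {res['rho']:.2f}, p {res['p']:.1e})")
    io.write_results_table(pd.DataFrame(trends), out / "dose_trends.tsv", seed=1)

    # concordance: methylation direction vs expression change
    calls = pd.DataFrame({
        "gene": [s.gene for s in TABLE1_PANEL],
        "direction": ["hypo_in_ds" if s.mu_ds < s.mu_ctrl else "hyper_in_ds"
                      for s in TABLE1_PANEL],
    })
    conc = methylation_expression_concordance(
        calls, tests.rename(columns={"fold": "fold"})[["gene", "fold"]])
    io.write_results_table(conc, out / "concordance.tsv", seed=1)
    n_par = int(conc["paradoxical"].sum())
    print(f"methylation-expression concordance: "
          f"{int(conc['concordant'].sum())}/{len(conc)} concordant, "
          f"{n_par} paradoxical ({', '.join(conc.loc[conc['paradoxical'], 'gene'])})")


if __name__ == "__main__":
    main()
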