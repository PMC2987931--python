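#!/usr/bin/env python
"""Ridge-logistic LOOCV classification of DS versus control.

Uses the loci called by the differential-methylation screen as the
feature panel (the original protocol: panel selected on the full data
before cross-validation) with ridge lambda 1e-8, and scores the planted
mosaic sample against a model trained on the unambiguous samples.
"""

from pathlib import Path

from trisomethyl import io
from trisomethyl.classify import fit_logistic_ridge, loocv, score_sample

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    beta = io.read_beta_matrix(ROOT / "cohort" / "beta.tsv")
    sheet = io.read_sample_sheet(ROOT / "cohort" / "sample_sheet.tsv")
    calls = io.read_long_table(ROOT / "diffmeth" / "calls.tsv")
    out = ROOT / "classifier"
    out.mkdir(parents=True, exist_ok=True)

    panel = calls.loc[calls["passed"], "probe_id"].tolist()
    unique = sheet.unique_cases()
    features = beta.subset_probes(panel).subset_samples(
        unique.table["sample_id"].tolist()).values.T
    labels = unique.groups_for(list(features.index)).to_numpy()

    report = loocv(features, labels, ridge_lambda=1e-8)
    report.predictions.to_csv(out / "loocv_predictions.tsv", sep="\t", index=False)
    print(f"LOOCV over {report.n_folds} samples, {len(panel)}-locus panel, "
          f"lambda=1e-8:")
    print(f"  sensitivity {report.sensitivity:.0%}, "
          f"specificity {report.specificity:.0%}")
    print(f"  note: {report.note}")

    # the mosaic individual: expected to score between the two groups
    mosaic = sheet.table[(sheet.table["mosaic_fraction"] > 0)
                         & (sheet.table["mosaic_fraction"] < 1)]
    for _, row in mosaic.iterrows():
        sid = row["sample_id"]
        train = features.drop(index=sid, errors="ignore")
        train_labels = unique.groups_for(list(train.index)).to_numpy()
        model = fit_logistic_ridge(train, train_labels, ridge_lambda=1e-8)
        res = score_sample(model, features.loc[[sid]])
        print(f"  mosaic sample {sid} ({row['mosaic_fraction']:.0%} trisomic): "
              f"DS probability {res['probability']:.3f}"
              f"{' (intermediate)' if res['intermediate'] else ''}")


if __name__ == "__main__":
    main()
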