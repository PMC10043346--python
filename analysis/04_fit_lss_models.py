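"""Build limited-sampling equations by all-subsets regression.

Fits all 15 subsets of {C0, C1, C2, C4} against trapezoidal AUC(0-24),
retains those with adjusted r2 > 0.799, and compares them by AIC/BIC weights
-> results/lss_models.csv.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from taclss.io import read_cohort  # noqa: E402
from taclss.lss_builder import fit_all_subsets, wide_concentrations  # noqa: E402
from taclss.pk_exposure import exposure_table  # noqa: E402


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--threshold", type=float, default=0.799)
    parser.add_argument("--out", default="results/lss_models.csv")
    args = parser.parse_args()

    tables = read_cohort(args.cohort)
    expo = exposure_table(tables.metadata, tables.concentrations)
    wide = wide_concentrations(tables.concentrations)
    auc = expo.set_index("patient_id")["auc_0_24"]
    comparison, table = fit_all_subsets(wide, auc, threshold=args.threshold)
    table.to_csv(args.out, index=False)

    retained = table[table["retained"]]
    print(f"{len(table)} candidate models, {len(retained)} retained (adj r2 > {args.threshold}) -> {args.out}")
    for _, row in retained.iterrows():
        print(f"  model {int(row.model):2d}  adj r2 {row.adj_r2:.4f}  MAPE {row.mape_pct:4.1f}%  "
              f"AICw {row.aic_weight:.3f}  BICw {row.bic_weight:.3f}  {row.equation}")
    best = retained.loc[retained.aic_weight.idxmax()]
    print(f"best by AIC weight: model {int(best.model)} ({best.predictors})")


if __name__ == "__main__":
    main()
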