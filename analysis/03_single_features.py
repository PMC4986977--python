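"""Score each of the 12 lateralized ERP features on its own.

Reruns the LOSO dendrogram-SVM pipeline restricted to one feature column at
a time, and marks which single-feature accuracies clear the exact binomial
significance thresholds for the subject count.

Writes: single_feature_da.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from attnloc.evaluate import binomial_threshold, single_feature_da


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    features = pd.read_csv(args.features)
    das = single_feature_da(features)
    n_subjects = features["subject"].nunique()
    thr05 = binomial_threshold(n_subjects, 4, 0.05)
    thr01 = binomial_threshold(n_subjects, 4, 0.01)
    table = das.rename("da_pct").rename_axis("feature").to_frame()
    table["sig_p05_binomial"] = table["da_pct"] > thr05
    table["sig_p01_binomial"] = table["da_pct"] > thr01
    table.to_csv(args.out / "single_feature_da.csv")

    print(table.sort_values("da_pct", ascending=False).to_string())
    print(f"\nbinomial thresholds for n={n_subjects}: "
          f"p<.05 at {thr05:.1f}%, p<.01 at {thr01:.1f}% (chance 25%)")


if __name__ == "__main__":
    main()
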