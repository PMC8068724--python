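"""SVM classification of groups from nodal and connection features.

For each pairwise contrast (CN vs MDDNSI, CN vs MDDSI, MDDNSI vs MDDSI) and
each feature set -- hub and non-hub Dc/Ne/Bc, and rich/feeder/local edge
weights -- runs the t-filter + min-max + RBF-SVM pipeline under leave-one-out
cross-validation and reports accuracy, sensitivity, specificity and AUC.
"""

import pandas as pd
from study_config import make_config

from richconn.pipeline import run_pipeline

if __name__ == "__main__":
    config = make_config()
    out = run_pipeline(config, ["classify"])
    rep = pd.read_csv(out / "classify/classification_reports.tsv", sep="\t")
    print("LOOCV AUC by contrast and feature set:")
    print(
        rep.pivot(index="features", columns="contrast", values="auc")
        .round(3)
        .sort_index()
    )
    conn = rep[rep.features.str.endswith("_connections")]
    best = conn.loc[conn.groupby("contrast").auc.idxmax()]
    print("\nbest connection class per contrast:")
    for _, row in best.iterrows():
        print(f"  {row.contrast}: {row.features} (AUC {row.auc:.3f})")
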