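"""Group inference: nodal permutation tests, asymmetry, correlations, NBS.

Covariate-adjusted (age, sex, education) permutation tests on nodal Dc/Ne/Bc
with Bonferroni control over the 90 nodes; hemispheric asymmetry of
per-hemisphere metric sums; partial correlations of hub metrics with
HAMD/HAMA controlling age, sex, education and gray-matter volume; and the
network-based statistic over edges for all three pairwise group contrasts.
"""

import json

import pandas as pd
from study_config import make_config

from richconn.pipeline import run_pipeline

if __name__ == "__main__":
    config = make_config()
    out = run_pipeline(config, ["compare", "nbs"])
    tests = pd.read_csv(out / "compare/nodal_perm_tests.tsv", sep="\t")
    sig = tests[tests.significant_bonferroni]
    thr = 0.05 / tests.node_id.nunique()
    print(f"nodal tests significant after Bonferroni (p < {thr:.2g}):")
    if sig.empty:
        print("  none")
    else:
        for _, row in sig.iterrows():
            print(f"  {row.metric:>2} {row.node_id:<8} F={row.statistic:.2f} "
                  f"p={row.p_perm:.2g} {'(hub)' if row.is_hub else ''}")
    pc = pd.read_csv(out / "compare/partial_correlations.tsv", sep="\t")
    strongest = pc.loc[pc.groupby("score").r.idxmin()]
    print("\nstrongest negative hub-metric/score partial correlations:")
    for _, row in strongest.iterrows():
        print(f"  {row.metric} {row.node_id} vs {row.score}: "
              f"r={row.r:.3f}, p={row.p:.2g}")
    nbs_summary = json.loads((out / "nbs/nbs_summary.json").read_text())
    print("\nNBS components (edge p=0.01):")
    for tag, res in sorted(nbs_summary.items()):
        sizes = res["component_sizes"]
        ps = [round(p, 4) for p in res["p_fwe"]]
        print(f"  {tag}: sizes={sizes} p_fwe={ps}")
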