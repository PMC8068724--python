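"""Map NBS differential edges onto six depression-related circuits.

Circuits (DMN, salience, negative/positive affect, attention, cognitive
control) are resolved from AAL-style region labels; an edge is assigned to a
circuit when both endpoints belong to it. Edges outside every circuit are
reported as unassigned.
"""

import pandas as pd
from study_config import make_config

from richconn.pipeline import run_pipeline

if __name__ == "__main__":
    config = make_config()
    out = run_pipeline(config, ["circuits"])
    for tag in ("CN_vs_MDDNSI", "CN_vs_MDDSI", "MDDNSI_vs_MDDSI"):
        path = out / f"circuits/circuit_map_{tag}.tsv"
        mapped = pd.read_csv(path, sep="\t")
        if mapped.empty:
            print(f"{tag}: no differential edges")
            continue
        counts = mapped.circuit.value_counts()
        print(f"{tag}: {mapped[['node_i','node_j']].drop_duplicates().shape[0]} "
              f"differential edges -> circuits: {counts.to_dict()}")
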