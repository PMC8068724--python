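"""Simulate the study cohort: three groups of 90-node structural connectomes.

Generates controls (CN), depressed patients without suicidal ideation
(MDDNSI), and with suicidal ideation (MDDSI), with a planted 11-region rich
club (bilateral putamen, precuneus, thalamus, insula, caudate + left ACC)
and group effects confined to feeder and local connections. Writes the
cohort in the manifest + matrix-file layout under results/study/cohort/
along with the ground-truth record used by later drivers.
"""

import json
from pathlib import Path

from study_config import make_config

from richconn.pipeline import run_pipeline

if __name__ == "__main__":
    config = make_config()
    out = run_pipeline(config, ["simulate"])
    truth = json.loads((Path(out) / "cohort/ground_truth.json").read_text())
    print(f"cohort written under {out}/cohort")
    print(f"planted hubs ({len(truth['hub_set'])}): {', '.join(truth['hub_set'])}")
    print("group effect multipliers:")
    for grp, eff in truth["effect_map"].items():
        print(f"  {grp}: {eff or 'none (reference)'}")
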