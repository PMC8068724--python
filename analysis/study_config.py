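"""Shared configuration for the numbered analysis drivers.

One seed, one output directory, one set of analysis knobs — so every driver
operates on the same simulated study and the run is reproducible end to end.
Null-model and permutation counts are scaled to desk size (100 matched random
networks, 2000 permutations); raise them toward the protocol defaults (1000
and 10,000) for production-quality p-values.
"""

from richconn.pipeline import RunConfig

SEED = 2026
OUT_DIR = "results/study"

COHORT = {
    # three groups at one-third of the emulated clinical cohort sizes
    "n_per_group": {"CN": 17, "MDDNSI": 19, "MDDSI": 23},
    "seed": SEED,
}


def make_config() -> RunConfig:
    return RunConfig(
        out_dir=OUT_DIR,
        n_random=100,
        n_perm=2000,
        synthetic=COHORT,
        seed=SEED,
    )
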