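"""End-to-end orchestration of the rich-club connectome analysis.

``run_pipeline`` chains the stages -- simulate, metrics, richclub, compare,
nbs, circuits, classify -- over a single ``RunConfig`` whose defaults are the
study's stated analysis parameters (sparsity 0.05-0.20 in steps of 0.01,
streamline cutoff 3, 1000 matched random networks, 10,000 permutations, NBS
edge p = 0.01, 80% group-average occurrence, Bonferroni alpha = 0.05).
Every stage writes plain TSV/JSON into its own subdirectory, and a single
``run_manifest.json`` records the full configuration and seed so a run can
be reproduced exactly: identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuits as circuits_mod
from . import classify as classify_mod
from . import inference, metrics, richclub
from .core import (
    CohortDataset,
    integrate_curve,
    read_cohort,
    sparsity_binarize,
    sparsity_sweep,
    streamline_filter,
    write_cohort,
)
from .synthetic import SyntheticSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("richconn")

STAGES = ("simulate", "metrics", "richclub", "compare", "nbs", "circuits", "classify")


@dataclass
class RunConfig:
    """All analysis knobs in one place; defaults follow the study protocol."""

    out_dir: str = "results/run"
    manifest: str | None = None  # existing cohort manifest TSV (else simulate)
    node_table: str | None = None
    circuit_config: str | None = None  # YAML; default bundled circuits

    # network construction
    min_streamlines: int = 3
    s_min: float = 0.05
    s_max: float = 0.20
    s_step: float = 0.01
    reference_sparsity: float | None = None  # default: s_max

    # nulls and inference
    n_random: int = 1000  # matched random networks (rich club, sigma)
    n_perm: int = 10000  # permutation tests and NBS
    p_edge: float = 0.01
    occurrence: float = 0.8
    alpha: float = 0.05

    # classification
    svm_C: float = 1.0
    svm_gamma: "float | str" = "scale"
    tfilter_alpha: float = 0.05
    n_perm_svm: int = 0  # label permutations for accuracy p (0 = skip)

    # synthetic cohort (used only when no manifest is given)
    synthetic: dict = field(default_factory=dict)

    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def ref_sparsity(self) -> float:
        return self.s_max if self.reference_sparsity is None else self.reference_sparsity


def _stage_dir(out: Path, name: str) -> Path:
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _pairwise_contrasts(groups: list[str]) -> list[tuple[str, str]]:
    uniq = sorted(set(groups))
    return [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]


class StageError(RuntimeError):
    """Wraps an exception with the pipeline stage it occurred in."""


def _load_or_simulate(config: RunConfig, out: Path):
    if config.manifest:
        if not config.node_table:
            raise ValueError("node_table path required with an external manifest")
        cohort = read_cohort(config.manifest, config.node_table)
        truth = None
    else:
        spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
        cohort, truth = generate_cohort(spec)
        cdir = _stage_dir(out, "cohort")
        write_cohort(cohort, cdir)
        with open(cdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    filtered = [streamline_filter(s, config.min_streamlines) for s in cohort.subjects]
    cohort = CohortDataset(
        filtered, cohort.group, cohort.covariates, cohort.scores, cohort.node_table
    )
    return cohort, truth


def _stage_metrics(config: RunConfig, cohort: CohortDataset, out: Path) -> dict:
    """Global and nodal metrics per subject across the sparsity sweep.

    sigma (and gamma/lambda) are computed at the maximum sparsity only, where
    the small-world criterion applies; the remaining global metrics are
    reported at every sparsity, together with their sweep-integrated values.
    """
    d = _stage_dir(out, "metrics")
    rng = np.random.default_rng(config.seed + 1)
    global_rows, nodal_frames, sigma_rows = [], [], []
    for subj, grp in zip(cohort.subjects, cohort.group):
        sweep = sparsity_sweep(subj, config.s_min, config.s_max, config.s_step)
        per_metric: dict[str, list[float]] = {}
        for s, g in sweep:
            adj = g.adjacency
            dist = metrics.distance_matrix(adj)
            vals = {
                "C": metrics._clustering_mean(adj),
                "L": metrics._char_path_length(dist),
                "Eg": metrics._global_efficiency(dist),
                "Eloc": metrics._local_efficiency(adj),
                "Q": metrics.modularity_partition(g)[1] if g.n_edges else 0.0,
            }
            for k, v in vals.items():
                per_metric.setdefault(k, []).append(v)
                global_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": grp,
                        "sparsity": float(s),
                        "metric": k,
                        "value": v,
                    }
                )
            nodal_frames.append(
                metrics.nodal_metrics(g).assign(group=grp)
            )
        for k, series in per_metric.items():
            global_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": grp,
                    "sparsity": np.nan,
                    "metric": f"{k}_integrated",
                    "value": integrate_curve(series, config.s_step),
                }
            )
        gm = metrics.global_metrics(
            sweep.graphs[-1],
            n_random=config.n_random,
            seed=int(rng.integers(2**31)),
        )
        sigma_rows.append(
            {
                "subject_id": subj.subject_id,
                "group": grp,
                "sparsity": float(sweep.sparsities[-1]),
                "gamma": gm.gamma,
                "lambda": gm.lam,
                "sigma": gm.sigma,
            }
        )
    _write_tsv(pd.DataFrame(global_rows), d / "global_metrics.tsv")
    nodal = pd.concat(nodal_frames, ignore_index=True)
    _write_tsv(nodal, d / "nodal_metrics.tsv")
    sigma_df = pd.DataFrame(sigma_rows)
    ok, report = metrics.small_world_check(sigma_df["sigma"].to_numpy())
    sigma_df["small_world_pass"] = report["pass"].to_numpy()
    _write_tsv(sigma_df, d / "small_world.tsv")
    return {"nodal": nodal, "sigma": sigma_df, "all_pass_small_world": bool(ok)}


def _stage_richclub(config: RunConfig, cohort: CohortDataset, out: Path) -> dict:
    """Group-average networks, rich-club profiles, hubs, and edge classes."""
    d = _stage_dir(out, "richclub")
    rng = np.random.default_rng(config.seed + 2)
    ref_s = config.ref_sparsity
    groups = sorted(set(cohort.group))
    binarized = {
        sid: sparsity_binarize(subj, ref_s)
        for sid, subj in zip(cohort.subject_ids, cohort.subjects)
    }
    hub_sets, profiles, avg_graphs = {}, {}, {}
    for grp in groups:
        members = [
            binarized[sid]
            for sid, g in zip(cohort.subject_ids, cohort.group)
            if g == grp
        ]
        avg = richclub.group_average_network(members, config.occurrence)
        profile = richclub.rich_club_profile(
            avg, n_random=config.n_random, seed=int(rng.integers(2**31))
        )
        hubs = richclub.identify_hubs(avg, profile, k_star="auto")
        avg_graphs[grp], profiles[grp], hub_sets[grp] = avg, profile, hubs
        _write_tsv(profile.to_frame(), d / f"profile_{grp}.tsv")
    common_hubs = set.intersection(*hub_sets.values()) if hub_sets else set()
    with open(d / "hubs.json", "w") as fh:
        json.dump(
            {
                "per_group": {g: sorted(h) for g, h in hub_sets.items()},
                "common": sorted(common_hubs),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    # edge classes on each group-average network + per-subject integrated
    # class strengths against the common hub set
    class_rows = []
    for grp in groups:
        dec = richclub.classify_edges(avg_graphs[grp], common_hubs)
        for c in richclub.EDGE_CLASSES:
            class_rows.append(
                {
                    "group": grp,
                    "edge_class": c,
                    "count": dec.class_counts[c],
                    "proportion": dec.class_proportions[c],
                }
            )
    _write_tsv(pd.DataFrame(class_rows), d / "group_average_edge_classes.tsv")
    strength_rows = []
    for subj, grp in zip(cohort.subjects, cohort.group):
        sweep = sparsity_sweep(subj, config.s_min, config.s_max, config.s_step)
        integ = richclub.integrated_class_strengths(subj, sweep, common_hubs)
        for c, v in integ.items():
            strength_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": grp,
                    "edge_class": c,
                    "integrated_strength": v,
                }
            )
    strengths = pd.DataFrame(strength_rows)
    _write_tsv(strengths, d / "integrated_class_strengths.tsv")
    return {
        "hub_sets": hub_sets,
        "common_hubs": common_hubs,
        "profiles": profiles,
        "avg_graphs": avg_graphs,
        "strengths": strengths,
    }


def _stage_compare(
    config: RunConfig,
    cohort: CohortDataset,
    nodal: pd.DataFrame,
    common_hubs: set,
    out: Path,
) -> dict:
    """Permutation tests on nodal metrics with covariates, Bonferroni over
    nodes, and partial correlations of hub metrics with symptom scores."""
    d = _stage_dir(out, "compare")
    ref_s = config.ref_sparsity
    nod = nodal[np.isclose(nodal["sparsity"], ref_s)]
    cov = cohort.covariates[["age", "sex", "education"]].to_numpy()
    cov_names = ["age", "sex", "education"]
    groups = np.asarray(cohort.group)
    node_ids = cohort.subjects[0].node_ids
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    sig_sets: dict[str, list] = {}
    for metric_name in ("Dc", "Ne", "Bc"):
        wide = nod.pivot_table(
            index="subject_id", columns="node_id", values=metric_name, sort=False
        ).loc[cohort.subject_ids, node_ids]
        pvals = {}
        for nid in node_ids:
            res = inference.perm_test(
                wide[nid].to_numpy(),
                groups,
                n_perm=config.n_perm,
                covariates=cov,
                seed=int(rng.integers(2**31)),
                covariate_names=cov_names,
            )
            pvals[nid] = res.p_perm
            rows.append(
                {
                    "metric": metric_name,
                    "node_id": nid,
                    "statistic": res.statistic,
                    "p_perm": res.p_perm,
                    "design": res.design,
                    "is_hub": nid in common_hubs,
                }
            )
        sig_sets[metric_name] = inference.bonferroni_nodes(pvals, config.alpha)
    res_df = pd.DataFrame(rows)
    thr = config.alpha / len(node_ids)
    res_df["significant_bonferroni"] = res_df.apply(
        lambda r: r.node_id in sig_sets[r.metric], axis=1
    )
    _write_tsv(res_df, d / "nodal_perm_tests.tsv")

    # partial correlations: hub nodal metrics vs symptom scores, controlling
    # age, sex, education, and gray-matter volume
    pc_cov = cohort.covariates[["age", "sex", "education", "gm_volume"]].to_numpy()
    pc_rows = []
    for metric_name in ("Dc", "Ne", "Bc"):
        wide = nod.pivot_table(
            index="subject_id", columns="node_id", values=metric_name, sort=False
        ).loc[cohort.subject_ids]
        for nid in sorted(common_hubs):
            for score in cohort.scores.columns:
                r, p = inference.partial_correlation(
                    wide[nid].to_numpy(),
                    cohort.scores[score].to_numpy(),
                    pc_cov,
                )
                pc_rows.append(
                    {
                        "metric": metric_name,
                        "node_id": nid,
                        "score": score,
                        "r": r,
                        "p": p,
                    }
                )
    _write_tsv(pd.DataFrame(pc_rows), d / "partial_correlations.tsv")

    # hemispheric asymmetry of per-hemisphere metric sums, per subject
    asym_rows = []
    if cohort.node_table is not None:
        hemi = dict(
            zip(cohort.node_table.table["node_id"], cohort.node_table.table["hemisphere"])
        )
        left = [nid for nid in node_ids if hemi.get(nid) == "left"]
        right = [nid for nid in node_ids if hemi.get(nid) == "right"]
        for metric_name in ("Dc", "Ne", "Bc"):
            wide = nod.pivot_table(
                index="subject_id", columns="node_id", values=metric_name, sort=False
            ).loc[cohort.subject_ids]
            xl = wide[left].sum(axis=1).to_numpy()
            xr = wide[right].sum(axis=1).to_numpy()
            for sid, grp, a, b in zip(cohort.subject_ids, cohort.group, xl, xr):
                asym_rows.append(
                    {
                        "subject_id": sid,
                        "group": grp,
                        "metric": metric_name,
                        "asymmetry": metrics.hemispheric_asymmetry(a, b),
                    }
                )
        _write_tsv(pd.DataFrame(asym_rows), d / "hemispheric_asymmetry.tsv")
    return {"nodal_tests": res_df, "bonferroni_threshold": thr, "sig_sets": sig_sets}


def _stage_nbs(config: RunConfig, cohort: CohortDataset, out: Path) -> dict:
    d = _stage_dir(out, "nbs")
    rng = np.random.default_rng(config.seed + 4)
    node_ids = cohort.subjects[0].node_ids
    results = {}
    summary = {}
    for a, b in _pairwise_contrasts(cohort.group):
        res = inference.nbs(
            cohort,
            contrast=(a, b),
            p_edge=config.p_edge,
            n_perm=config.n_perm,
            seed=int(rng.integers(2**31)),
        )
        tag = f"{a}_vs_{b}"
        results[tag] = res
        _write_tsv(res.component_edge_table(node_ids), d / f"components_{tag}.tsv")
        summary[tag] = {
            "n_components": len(res.components),
            "component_sizes": res.component_sizes,
            "p_fwe": res.p_fwe,
            "n_perm": res.n_perm,
            "p_edge": res.p_edge_threshold,
        }
    with open(d / "nbs_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return results


def _stage_circuits(
    config: RunConfig, cohort: CohortDataset, nbs_results: dict, out: Path
) -> dict:
    d = _stage_dir(out, "circuits")
    if cohort.node_table is None:
        raise ValueError("circuit mapping requires a node table")
    if config.circuit_config:
        atlas = circuits_mod.load_circuit_atlas(
            config.circuit_config, cohort.node_table
        )
    else:
        atlas = circuits_mod.default_circuit_atlas(cohort.node_table)
        circuits_mod.write_default_circuit_config(d / "circuit_config.yaml")
    node_ids = cohort.subjects[0].node_ids
    out_tables = {}
    for tag, res in sorted(nbs_results.items()):
        edges = res.component_edge_table(node_ids)
        mapped = circuits_mod.map_edges_to_circuits(edges, atlas, rule="both")
        _write_tsv(mapped, d / f"circuit_map_{tag}.tsv")
        out_tables[tag] = mapped
    return {"atlas": atlas, "tables": out_tables}


def _class_edge_features(
    cohort: CohortDataset, hubs: set, ref_s: float
) -> dict[str, classify_mod.FeatureMatrix]:
    """Per-class edge-weight feature matrices on the pooled average network."""
    binarized = [sparsity_binarize(s, ref_s) for s in cohort.subjects]
    pooled = richclub.group_average_network(binarized, occurrence=0.5)
    dec = richclub.classify_edges(pooled, hubs)
    node_index = {nid: i for i, nid in enumerate(cohort.subjects[0].node_ids)}
    stack = cohort.weight_stack()
    feats = {}
    for c in richclub.EDGE_CLASSES:
        sub = dec.edge_table[dec.edge_table["edge_class"] == c]
        if sub.empty:
            continue
        ii = sub["node_i"].map(node_index).to_numpy()
        jj = sub["node_j"].map(node_index).to_numpy()
        X = stack[:, ii, jj]
        names = [f"{a}--{b}" for a, b in zip(sub["node_i"], sub["node_j"])]
        feats[c] = classify_mod.FeatureMatrix(
            X, names, np.asarray(cohort.group)
        )
    return feats


def _stage_classify(
    config: RunConfig,
    cohort: CohortDataset,
    nodal: pd.DataFrame,
    common_hubs: set,
    out: Path,
) -> dict:
    """Pairwise SVM classification from nodal-metric and edge-class features."""
    d = _stage_dir(out, "classify")
    ref_s = config.ref_sparsity
    nod = nodal[np.isclose(nodal["sparsity"], ref_s)]
    node_ids = cohort.subjects[0].node_ids
    hubs_sorted = sorted(common_hubs)
    nonhubs_sorted = [n for n in node_ids if n not in common_hubs]
    feature_sets: dict[str, classify_mod.FeatureMatrix] = {}
    for metric_name in ("Dc", "Ne", "Bc"):
        wide = nod.pivot_table(
            index="subject_id", columns="node_id", values=metric_name, sort=False
        ).loc[cohort.subject_ids]
        for part, cols in (("hub", hubs_sorted), ("nonhub", nonhubs_sorted)):
            if not cols:
                continue
            feature_sets[f"{metric_name}_{part}"] = classify_mod.FeatureMatrix(
                wide[cols].to_numpy(),
                [f"{metric_name}:{c}" for c in cols],
                np.asarray(cohort.group),
            )
    feature_sets.update(
        {
            f"{c}_connections": fm
            for c, fm in _class_edge_features(cohort, common_hubs, ref_s).items()
        }
    )
    rows = []
    for a, b in _pairwise_contrasts(cohort.group):
        mask = np.isin(np.asarray(cohort.group), [a, b])
        for fname, fm in feature_sets.items():
            sub = classify_mod.FeatureMatrix(
                fm.X[mask], fm.feature_names, fm.labels[mask]
            )
            report = classify_mod.loocv_svm(
                sub,
                C=config.svm_C,
                gamma=config.svm_gamma,
                tfilter_alpha=config.tfilter_alpha,
                compute_permutation_p=config.n_perm_svm,
                seed=config.seed + 5,
            )
            tag = f"{a}_vs_{b}"
            roc = pd.DataFrame(report.roc_points, columns=["fpr", "tpr"])
            _write_tsv(roc, d / f"roc_{tag}_{fname}.tsv")
            with open(d / f"report_{tag}_{fname}.json", "w") as fh:
                json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
            rows.append(
                {
                    "contrast": tag,
                    "features": fname,
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "auc": report.auc,
                    "p_perm": report.p_perm,
                }
            )
    reports = pd.DataFrame(rows)
    _write_tsv(reports, d / "classification_reports.tsv")
    return {"reports": reports}


def run_pipeline(config: RunConfig, stages: "list[str] | str" = "all") -> Path:
    """Run the requested stages; returns the output directory.

    ``stages`` is ``'all'`` or a subset of ``STAGES``; later stages consume
    earlier ones' in-memory results, so dependencies (e.g. metrics before
    compare) are run implicitly when needed.
    """
    if stages == "all":
        wanted = set(STAGES)
    else:
        wanted = set([stages] if isinstance(stages, str) else stages)
        unknown = wanted - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
    # implicit dependencies
    if wanted & {"compare", "classify"}:
        wanted |= {"metrics", "richclub"}
    if "circuits" in wanted:
        wanted |= {"nbs"}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the manifest records analysis parameters only -- not the output
    # location -- so runs into different directories stay byte-identical
    manifest_config = {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump({"config": manifest_config, "stages": sorted(wanted)}, fh,
                  indent=1, sort_keys=True)

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # annotate with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
        return result

    cohort, _truth = timed("simulate", _load_or_simulate, config, out)
    metrics_out = (
        timed("metrics", _stage_metrics, config, cohort, out)
        if "metrics" in wanted
        else None
    )
    rc_out = (
        timed("richclub", _stage_richclub, config, cohort, out)
        if "richclub" in wanted
        else None
    )
    if "compare" in wanted:
        timed(
            "compare",
            _stage_compare,
            config,
            cohort,
            metrics_out["nodal"],
            rc_out["common_hubs"],
            out,
        )
    nbs_out = (
        timed("nbs", _stage_nbs, config, cohort, out) if "nbs" in wanted else None
    )
    if "circuits" in wanted:
        timed("circuits", _stage_circuits, config, cohort, nbs_out, out)
    if "classify" in wanted:
        timed(
            "classify",
            _stage_classify,
            config,
            cohort,
            metrics_out["nodal"],
            rc_out["common_hubs"],
            out,
        )
    return out
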