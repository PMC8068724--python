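"""Synthetic three-group connectome cohorts with planted ground truth.

The generator emulates the study design the pipeline targets: 90-node
AAL-style structural connectomes in three groups (controls, depressed
without suicidal ideation, depressed with suicidal ideation), with a planted
rich-club core among 11 designated subcortical/midline hub regions and group
effects concentrated on feeder and local connections. Every random choice is
driven by a single seed, and the planted truth (hub set, affected edge
classes, effect sizes) is returned so that recovery can be scored exactly.

Generative model, per subject:

1. a shared template assigns each node pair a presence probability
   (``base_density``) and a log-normal base weight; edges touching hub nodes
   are up-weighted by ``sqrt(hub_core_boost)`` per hub endpoint, so hub-hub
   edges carry ``hub_core_boost`` times the base weight. Binarizing at any
   sparsity in the sweep therefore yields top-degree hubs with a dense core
   -- a rich club by construction;
2. group effects multiply the weights of a given edge class (rich / feeder /
   local) by a factor from ``effect_map``;
3. multiplicative log-normal noise (sigma = ``noise_sd``) models streamline
   count dispersion, and a small Bernoulli presence flip (``presence_noise``)
   perturbs the topology per subject;
4. covariates (age, sex, education, gray-matter volume) are drawn
   independently of group, and symptom scores follow a linear link from the
   nodal efficiency of two designated hub regions plus noise, giving partial
   correlations a known sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import (
    BinaryGraph,
    CohortDataset,
    ConnectomeMatrix,
    NodeTable,
    sparsity_binarize,
)
from .metrics import distance_matrix

__all__ = [
    "AAL90_REGIONS",
    "DEFAULT_HUB_REGIONS",
    "aal90_node_table",
    "SyntheticSpec",
    "generate_base_network",
    "generate_cohort",
]

# 45 bilateral AAL region abbreviations, in conventional atlas order.
AAL90_REGIONS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
]

# Planted rich-club hubs: bilateral putamen, precuneus, thalamus, insula,
# caudate, plus the left anterior cingulate (11 regions).
DEFAULT_HUB_REGIONS = [
    "PUT.L", "PUT.R", "PCUN.L", "PCUN.R", "THA.L", "THA.R",
    "INS.L", "INS.R", "CAU.L", "CAU.R", "ACG.L",
]


def aal90_node_table() -> NodeTable:
    """Node table for the 90-region AAL-style parcellation (L/R pairs)."""
    rows = []
    for region in AAL90_REGIONS:
        for hemi, tag in (("left", "L"), ("right", "R")):
            other = "R" if tag == "L" else "L"
            rows.append(
                {
                    "node_id": f"{region}.{tag}",
                    "label": region,
                    "hemisphere": hemi,
                    "homologue_id": f"{region}.{other}",
                }
            )
    return NodeTable(pd.DataFrame(rows))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the emulated study's conditions: 90 nodes, group sizes
    50/58/69 (CN / MDDNSI / MDDSI), 11 hubs, and weight reductions confined
    to feeder and local connections in the patient groups.
    """

    n_nodes: int = 90
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CN": 50, "MDDNSI": 58, "MDDSI": 69}
    )
    hub_fraction: float = 11 / 90
    base_density: float = 0.30
    hub_core_boost: float = 3.0
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CN": {},
            "MDDNSI": {"feeder": 0.85, "local": 0.90},
            "MDDSI": {"feeder": 0.75, "local": 0.85},
        }
    )
    noise_sd: float = 0.30
    presence_noise: float = 0.02
    weight_scale: float = 40.0  # median streamline count of a template edge
    score_model: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 30.0,
            "ne_slope": -40.0,
            "noise_sd": 3.0,
            "reference_sparsity": 0.20,
        }
    )
    group_score_offset: dict[str, float] = field(
        default_factory=lambda: {"CN": -22.0, "MDDNSI": 0.0, "MDDSI": 2.0}
    )
    confound_strength: float = 0.0  # optional group->age shift, for testing
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.base_density < 1:
            raise ValueError("base_density must be in (0, 1)")
        if not 0 <= self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in [0, 1)")
        if self.hub_core_boost <= 0:
            raise ValueError("hub_core_boost must be positive")
        for g, shifts in self.effect_map.items():
            if any(s <= 0 for s in shifts.values()):
                raise ValueError(f"effect shifts must be positive ({g})")
        n_hubs = round(self.hub_fraction * self.n_nodes)
        if self.n_nodes < 3 or (self.n_nodes - n_hubs) < 2:
            raise ValueError("infeasible node/hub combination")


def _node_ids(spec: SyntheticSpec) -> list[str]:
    if spec.n_nodes == 90:
        return aal90_node_table().node_ids
    return [f"R{i:03d}.{'L' if i % 2 == 0 else 'R'}" for i in range(spec.n_nodes)]


def generate_base_network(
    spec: SyntheticSpec,
) -> tuple[ConnectomeMatrix, list[str]]:
    """Template connectome plus the planted hub set.

    Edge presence is Bernoulli(``base_density``), except hub-hub pairs whose
    probability is boosted to ``min(0.95, base_density * hub_core_boost)`` --
    an excess density *beyond what the degree sequence implies*, which is
    exactly what degree-preserving null normalization detects. Weights are
    log-normal with median ``weight_scale``, multiplied by
    ``sqrt(hub_core_boost)`` per hub endpoint so that hub edges survive
    sparsity thresholding and hubs end up as the top-degree nodes. With
    ``hub_core_boost=1`` the template has no planted rich club (density and
    weights are exchangeable across nodes); with ``hub_fraction=0`` there are
    no hubs at all.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    node_ids = _node_ids(spec)
    n_hubs = round(spec.hub_fraction * n)
    if n == 90 and n_hubs == 11:
        hubs = list(DEFAULT_HUB_REGIONS)
    else:
        hubs = node_ids[:n_hubs]
    hub_mask = np.array([nid in hubs for nid in node_ids])

    iu, ju = np.triu_indices(n, k=1)
    n_hub_ends = hub_mask[iu].astype(int) + hub_mask[ju].astype(int)
    p_rich = min(0.95, spec.base_density * spec.hub_core_boost)
    p_edge = np.where(n_hub_ends == 2, p_rich, spec.base_density)
    present = rng.random(len(iu)) < p_edge
    base_w = spec.weight_scale * np.exp(rng.normal(0.0, 0.5, size=len(iu)))
    boost = (spec.hub_core_boost**0.75) ** n_hub_ends
    w_flat = np.where(present, base_w * boost, 0.0)
    w = np.zeros((n, n))
    w[iu, ju] = w_flat
    w += w.T
    return ConnectomeMatrix(w, node_ids, "template"), hubs


def _edge_class_matrix(node_ids: list[str], hubs: list[str]) -> np.ndarray:
    """N x N matrix of 0=local, 1=feeder, 2=rich by endpoint hub counts."""
    hub_mask = np.array([nid in hubs for nid in node_ids]).astype(int)
    return hub_mask[:, None] + hub_mask[None, :]


def _subject_scores(
    spec: SyntheticSpec,
    w: np.ndarray,
    node_ids: list[str],
    hubs: list[str],
    group: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """HAMD/HAMA from the nodal efficiency of two designated hub nodes."""
    sm = spec.score_model
    m = ConnectomeMatrix(w, node_ids, "tmp")
    g = sparsity_binarize(m, sm["reference_sparsity"])
    targets = hubs[:2] if len(hubs) >= 2 else node_ids[:2]
    idx = [node_ids.index(t) for t in targets]
    dist = distance_matrix(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    ne = inv[idx].sum(axis=1) / (len(node_ids) - 1)
    base = (
        sm["intercept"]
        + sm["ne_slope"] * float(ne.mean())
        + spec.group_score_offset.get(group, 0.0)
    )
    hamd = max(0.0, base + rng.normal(0.0, sm["noise_sd"]))
    hama = max(0.0, 0.8 * base + rng.normal(0.0, sm["noise_sd"]))
    si = rng.normal(12.0, 4.0) if group == "MDDSI" else 0.0
    return {"HAMD": hamd, "HAMA": hama, "SI_severity": max(0.0, si)}


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[CohortDataset, dict[str, Any]]:
    """Three-group cohort plus a ground-truth record.

    Returns ``(cohort, truth)`` where ``truth`` holds the planted hub set,
    the per-group edge-class effect multipliers, and the seed -- everything a
    recovery test needs to score the pipeline against construction.
    """
    rng = np.random.default_rng(spec.seed)
    template, hubs = generate_base_network(spec)
    node_ids = template.node_ids
    n = spec.n_nodes
    class_mat = _edge_class_matrix(node_ids, hubs)  # 0/1/2 hub endpoints
    class_names = np.array(["local", "feeder", "rich"])
    iu, ju = np.triu_indices(n, k=1)
    tmpl_flat = template.weights[iu, ju]
    pos_weights = tmpl_flat[tmpl_flat > 0]

    subjects: list[ConnectomeMatrix] = []
    groups: list[str] = []
    cov_rows = []
    score_rows = []
    affected: dict[str, dict[str, float]] = {}
    for group in spec.n_per_group:
        shifts = spec.effect_map.get(group, {})
        affected[group] = dict(shifts)
        factor_by_class = np.array(
            [shifts.get(c, 1.0) for c in class_names]
        )
        edge_factor = factor_by_class[class_mat[iu, ju]]
        for s_idx in range(spec.n_per_group[group]):
            sid = f"{group}_{s_idx:03d}"
            w_flat = tmpl_flat * edge_factor
            if spec.noise_sd > 0:
                w_flat = w_flat * np.exp(
                    rng.normal(0.0, spec.noise_sd, size=len(w_flat))
                )
            if spec.presence_noise > 0:
                flip = rng.random(len(w_flat)) < spec.presence_noise
                was_present = w_flat > 0
                # toggle off existing edges; toggle on absent ones with a
                # weak weight drawn from the template distribution
                new_on = flip & ~was_present
                w_flat = np.where(flip & was_present, 0.0, w_flat)
                if new_on.any() and len(pos_weights):
                    w_flat[new_on] = 0.5 * rng.choice(
                        pos_weights, size=int(new_on.sum())
                    )
            w = np.zeros((n, n))
            w[iu, ju] = w_flat
            w += w.T
            subjects.append(ConnectomeMatrix(w, list(node_ids), sid))
            groups.append(group)
            age = rng.normal(40.0, 11.0) + spec.confound_strength * (
                0.0 if group == "CN" else 5.0
            )
            cov_rows.append(
                {
                    "age": float(np.clip(age, 18, 75)),
                    "sex": float(rng.integers(0, 2)),
                    "education": float(np.clip(rng.normal(12.0, 3.0), 3, 22)),
                    "gm_volume": float(rng.normal(600.0, 50.0)),
                }
            )
            score_rows.append(
                _subject_scores(spec, w, node_ids, hubs, group, rng)
            )
    node_table = (
        aal90_node_table()
        if spec.n_nodes == 90
        else NodeTable(
            pd.DataFrame(
                {
                    "node_id": node_ids,
                    "label": [nid.rsplit(".", 1)[0] for nid in node_ids],
                    "hemisphere": [
                        "left" if nid.endswith(".L") else "right"
                        for nid in node_ids
                    ],
                    "homologue_id": ["" for _ in node_ids],
                }
            )
        )
    )
    cohort = CohortDataset(
        subjects,
        groups,
        pd.DataFrame(cov_rows),
        pd.DataFrame(score_rows),
        node_table,
    )
    truth: dict[str, Any] = {
        "hub_set": sorted(hubs),
        "effect_map": affected,
        "hub_core_boost": spec.hub_core_boost,
        "base_density": spec.base_density,
        "noise_sd": spec.noise_sd,
        "presence_noise": spec.presence_noise,
        "seed": spec.seed,
    }
    return cohort, truth
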