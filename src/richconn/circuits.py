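"""Depression-related circuit definitions over an AAL-style parcellation.

Six large-scale circuits implicated in depression are represented as named
region sets: the default mode network (DMN), salience circuit (SC), negative
affect circuit (NAC), positive affect circuit (PAC), attention circuit (AC),
and cognitive control circuit (CCC). Circuits may overlap (e.g. the anterior
cingulate belongs to both the salience and cognitive control circuits).
Differential edges from group comparisons are assigned to circuits either
when both endpoints belong to the circuit (default) or when any endpoint
does.

The bundled default configuration is an approximate transcription of the
published circuit descriptions onto AAL-90 region labels; users studying a
specific cohort should supply their own mask configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import NodeTable

__all__ = [
    "CircuitAtlas",
    "CIRCUIT_NAMES",
    "DEFAULT_CIRCUIT_REGIONS",
    "default_circuit_atlas",
    "load_circuit_atlas",
    "write_default_circuit_config",
    "map_edges_to_circuits",
]

CIRCUIT_NAMES = ("DMN", "SC", "NAC", "PAC", "AC", "CCC")

# Region *labels* (hemisphere-less AAL abbreviations); both hemispheres are
# included when resolving against a node table. Approximate by design.
DEFAULT_CIRCUIT_REGIONS: dict[str, list[str]] = {
    # anterior medial prefrontal + posterior cingulate + angular gyrus
    "DMN": ["SFGmed", "ORBsupmed", "PCG", "ANG"],
    # anterior cingulate, anterior insula, extended amygdala
    "SC": ["ACG", "INS", "AMYG"],
    # amygdala/hippocampus/insula plus dorsal and ventral prefrontal nodes
    "NAC": ["AMYG", "HIP", "INS", "MFG", "ORBinf"],
    # ventral striatum and its orbitofrontal / medial prefrontal projections
    "PAC": ["CAU", "PUT", "PAL", "ORBsup", "ORBmid", "ORBsupmed", "SFGmed"],
    # medial superior frontal, anterior insula, inferior parietal, precuneus
    "AC": ["SFGmed", "INS", "IPL", "PCUN"],
    # dorsolateral prefrontal, anterior cingulate, dorsal parietal, precentral
    "CCC": ["MFG", "ACG", "SPG", "PreCG"],
}


@dataclass
class CircuitAtlas:
    circuits: dict[str, set[str]]  # circuit name -> node_id set
    source: str = "default"
    unresolved: dict[str, list[str]] = field(default_factory=dict)

    def circuits_of(self, node_id: str) -> set[str]:
        return {c for c, members in self.circuits.items() if node_id in members}


def _resolve(
    circuit_regions: dict[str, list[str]], nodes: NodeTable
) -> tuple[dict[str, set[str]], dict[str, list[str]]]:
    by_label: dict[str, list[str]] = {}
    for nid, label in zip(nodes.table["node_id"], nodes.table["label"]):
        by_label.setdefault(label, []).append(nid)
        # also index the hemisphere-less stem (PUT.L -> PUT)
        stem = nid.rsplit(".", 1)[0]
        by_label.setdefault(stem, []).append(nid)
    resolved: dict[str, set[str]] = {}
    unresolved: dict[str, list[str]] = {}
    node_id_set = set(nodes.node_ids)
    for circuit, labels in circuit_regions.items():
        members: set[str] = set()
        missing: list[str] = []
        for lab in labels:
            if lab in node_id_set:
                members.add(lab)
            elif lab in by_label:
                members.update(by_label[lab])
            else:
                missing.append(lab)
        if not members:
            raise ValueError(f"circuit {circuit!r} resolved to no nodes")
        resolved[circuit] = members
        if missing:
            unresolved[circuit] = missing
    return resolved, unresolved


def default_circuit_atlas(nodes: NodeTable) -> CircuitAtlas:
    circuits, unresolved = _resolve(DEFAULT_CIRCUIT_REGIONS, nodes)
    return CircuitAtlas(circuits, "default", unresolved)


def load_circuit_atlas(config_path: str | Path, nodes: NodeTable) -> CircuitAtlas:
    """Load a circuit -> region-label mapping from a YAML config.

    Labels may be bare region stems (``PUT``, expanded to both hemispheres),
    full node ids (``PUT.L``), or atlas label strings from the node table.
    Unknown labels are collected in ``atlas.unresolved`` rather than raised.
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"{config_path}: empty circuit config")
    if not isinstance(raw, dict):
        raise ValueError(f"{config_path}: expected a circuit -> label-list mapping")
    circuits, unresolved = _resolve(
        {str(k): [str(x) for x in v] for k, v in raw.items()}, nodes
    )
    return CircuitAtlas(circuits, str(config_path), unresolved)


def write_default_circuit_config(path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: list(v) for k, v in DEFAULT_CIRCUIT_REGIONS.items()},
            fh,
            sort_keys=True,
        )
    return path


def map_edges_to_circuits(
    edges: pd.DataFrame, atlas: CircuitAtlas, rule: str = "both"
) -> pd.DataFrame:
    """Annotate differential edges with the circuits they fall in.

    ``edges`` needs ``node_i``/``node_j`` columns (extra columns such as the
    edge t statistic pass through). ``rule='both'`` assigns an edge to a
    circuit only when both endpoints belong to it; ``rule='any'`` when either
    does. Edges matching no circuit get circuit = 'unassigned'. One output
    row per (edge, circuit) pair, deterministic in circuit order.
    """
    if rule not in ("both", "any"):
        raise ValueError("rule must be 'both' or 'any'")
    rows = []
    order = [c for c in CIRCUIT_NAMES if c in atlas.circuits] + sorted(
        set(atlas.circuits) - set(CIRCUIT_NAMES)
    )
    for rec in edges.to_dict("records"):
        ci = atlas.circuits_of(rec["node_i"])
        cj = atlas.circuits_of(rec["node_j"])
        hits = ci & cj if rule == "both" else ci | cj
        if not hits:
            rows.append({**rec, "circuit": "unassigned"})
        else:
            for c in order:
                if c in hits:
                    rows.append({**rec, "circuit": c})
    return pd.DataFrame(rows)
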