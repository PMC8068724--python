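"""Connectome data model, file I/O, and sparsity thresholding.

A structural connectome is a symmetric, nonnegative N x N weight matrix
(streamline counts or FA-weighted) over a fixed node set (here typically the
90 cortical/subcortical regions of an AAL-style parcellation). Group analyses
binarize each subject's matrix at a sweep of sparsity levels -- sparsity being
the number of retained edges divided by N(N-1)/2 -- and integrate metrics over
the sweep so that results do not hinge on a single arbitrary threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeMatrix",
    "NodeTable",
    "BinaryGraph",
    "ThresholdSweep",
    "CohortDataset",
    "read_connectome",
    "read_node_table",
    "read_cohort",
    "write_cohort",
    "streamline_filter",
    "sparsity_binarize",
    "sparsity_sweep",
    "integrate_curve",
]

_SYM_TOL = 1e-6


@dataclass
class NodeTable:
    """Region bookkeeping: identifier, atlas label, hemisphere, homologue.

    The homologue relation (left/right counterpart) is used by the
    hemispheric-asymmetry index and must be symmetric where present.
    """

    table: pd.DataFrame  # columns: node_id, label, hemisphere, homologue_id

    def __post_init__(self) -> None:
        required = {"node_id", "label", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"node table missing columns: {sorted(missing)}")
        ids = self.table["node_id"]
        if ids.duplicated().any():
            raise ValueError("node_id values must be unique")
        bad_hemi = ~self.table["hemisphere"].isin(["left", "right"])
        if bad_hemi.any():
            raise ValueError(
                "hemisphere must be 'left' or 'right'; offending rows: "
                f"{self.table.loc[bad_hemi, 'node_id'].tolist()}"
            )
        if "homologue_id" in self.table.columns:
            homo = dict(
                zip(self.table["node_id"], self.table["homologue_id"])
            )
            for a, b in homo.items():
                if isinstance(b, str) and b and homo.get(b) != a:
                    raise ValueError(f"homologue relation not symmetric at {a} <-> {b}")

    @property
    def node_ids(self) -> list[str]:
        return self.table["node_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def hemisphere_of(self, node_id: str) -> str:
        row = self.table.loc[self.table["node_id"] == node_id]
        if row.empty:
            raise KeyError(node_id)
        return row["hemisphere"].iloc[0]


@dataclass
class ConnectomeMatrix:
    """Per-subject symmetric weighted adjacency with node identity."""

    weights: np.ndarray
    node_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValueError("connectome needs at least 3 nodes")
        if len(self.node_ids) != n:
            raise ValueError(
                f"node_ids length {len(self.node_ids)} != matrix size {n}"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        if np.isnan(w).any():
            raise ValueError("weights contain NaN")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(w - w.T).max() > 1e-9:
            raise ValueError("weights not symmetric within 1e-9")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy_with(self, weights: np.ndarray) -> "ConnectomeMatrix":
        return ConnectomeMatrix(weights, list(self.node_ids), self.subject_id)


@dataclass
class BinaryGraph:
    """Unweighted graph obtained by thresholding a weighted connectome."""

    adjacency: np.ndarray
    sparsity: float
    source_subject: str = ""
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency not symmetric")
        vals = np.unique(a)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("adjacency must be 0/1")
        a = a.astype(np.int8)
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        return nx.from_numpy_array(self.adjacency)


@dataclass
class ThresholdSweep:
    """A family of binary graphs at strictly increasing sparsity levels."""

    sparsities: np.ndarray
    graphs: list[BinaryGraph]
    step: float

    def __post_init__(self) -> None:
        s = np.asarray(self.sparsities, dtype=float)
        if len(s) != len(self.graphs):
            raise ValueError("sparsities and graphs length mismatch")
        if len(s) > 1 and not (np.diff(s) > 0).all():
            raise ValueError("sparsities must be strictly increasing")
        self.sparsities = s

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(zip(self.sparsities, self.graphs))


@dataclass
class CohortDataset:
    """Subjects x (connectome, group label, covariates, symptom scores)."""

    subjects: list[ConnectomeMatrix]
    group: list[str]
    covariates: pd.DataFrame  # per-subject rows; e.g. age, sex, education, gm_volume
    scores: pd.DataFrame  # per-subject rows; e.g. HAMD, HAMA, SI_severity
    node_table: NodeTable | None = None

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if len(self.group) != n:
            raise ValueError("group labels must cover every subject")
        if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in self.group):
            raise ValueError("missing group labels")
        if len(self.covariates) != n or len(self.scores) != n:
            raise ValueError("covariates/scores must have one row per subject")
        if n:
            ref = self.subjects[0].node_ids
            for s in self.subjects[1:]:
                if s.node_ids != ref:
                    raise ValueError(
                        f"subject {s.subject_id} node ordering differs from cohort"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.group) == label)

    def weight_stack(self) -> np.ndarray:
        """Subjects x N x N array of raw weights."""
        return np.stack([s.weights for s in self.subjects])


# ---------------------------------------------------------------------------
# I/O


def read_node_table(path: str | Path) -> NodeTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return NodeTable(df)


def read_connectome(
    path: str | Path, node_table: NodeTable, subject_id: str | None = None
) -> ConnectomeMatrix:
    """Read a delimited N x N weight matrix (no header) and validate it.

    Small asymmetries (<= 1e-6 in absolute value) are repaired by averaging
    with the transpose; anything larger is treated as a directed input and
    rejected.
    """
    path = Path(path)
    w = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {w.shape})")
    if w.shape[0] != len(node_table):
        raise ValueError(
            f"{path}: matrix size {w.shape[0]} does not match node table "
            f"({len(node_table)} rows)"
        )
    if np.isnan(w).any():
        raise ValueError(f"{path}: NaN entries")
    if (w < 0).any():
        raise ValueError(f"{path}: negative weights")
    asym = np.abs(w - w.T).max()
    if asym > _SYM_TOL:
        raise ValueError(f"{path}: asymmetry {asym:g} exceeds tolerance {_SYM_TOL:g}")
    w = (w + w.T) / 2.0
    return ConnectomeMatrix(
        w, node_table.node_ids, subject_id or path.stem
    )


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None  # whitespace


def read_cohort(manifest_path: str | Path, node_table_path: str | Path) -> CohortDataset:
    """Load a cohort from a manifest TSV.

    The manifest has columns ``subject_id``, ``matrix_path``, ``group``, then
    covariate columns prefixed ``cov_`` and score columns prefixed ``score_``.
    Matrix paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    nodes = read_node_table(node_table_path)
    man = pd.read_csv(manifest_path, sep="\t")
    for col in ("subject_id", "matrix_path", "group"):
        if col not in man.columns:
            raise ValueError(f"manifest missing column {col!r}")
    base = manifest_path.parent
    subjects = [
        read_connectome(base / row.matrix_path, nodes, subject_id=str(row.subject_id))
        for row in man.itertuples()
    ]
    cov_cols = [c for c in man.columns if c.startswith("cov_")]
    score_cols = [c for c in man.columns if c.startswith("score_")]
    covariates = man[cov_cols].rename(columns=lambda c: c[4:]).astype(float)
    scores = man[score_cols].rename(columns=lambda c: c[6:]).astype(float)
    return CohortDataset(
        subjects, man["group"].astype(str).tolist(), covariates, scores, nodes
    )


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort in the manifest + matrix-file layout read_cohort expects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    rows = []
    for subj, grp in zip(cohort.subjects, cohort.group):
        rel = f"matrices/{subj.subject_id}.tsv"
        np.savetxt(out_dir / rel, subj.weights, delimiter="\t", fmt="%.6g")
        rows.append({"subject_id": subj.subject_id, "matrix_path": rel, "group": grp})
    man = pd.DataFrame(rows)
    for c in cohort.covariates.columns:
        man[f"cov_{c}"] = cohort.covariates[c].to_numpy()
    for c in cohort.scores.columns:
        man[f"score_{c}"] = cohort.scores[c].to_numpy()
    man_path = out_dir / "manifest.tsv"
    man.to_csv(man_path, sep="\t", index=False)
    if cohort.node_table is not None:
        cohort.node_table.table.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
    return man_path


# ---------------------------------------------------------------------------
# Thresholding


def streamline_filter(
    m: ConnectomeMatrix, min_streamlines: int = 3
) -> ConnectomeMatrix:
    """Zero out connections with streamline count <= min_streamlines.

    The cutoff is strict: an edge survives only if its count exceeds the
    threshold, which suppresses spurious single-fiber connections produced by
    deterministic tractography noise.
    """
    w = m.weights.copy()
    w[w <= min_streamlines] = 0.0
    return m.copy_with(w)


def _ranked_edges(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges ordered by descending weight, ties by (i, j)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def sparsity_binarize(m: ConnectomeMatrix, sparsity: float) -> BinaryGraph:
    """Keep the E = round(sparsity * N(N-1)/2) strongest edges as a binary graph.

    Sparsity is the retained-edge fraction of all possible edges. Ties at the
    cut rank are broken by ascending (i, j) node-pair order so the result is
    reproducible. If fewer than E positive weights exist, all of them are kept
    and the achieved (smaller) sparsity is recorded, with a warning.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = m.n_nodes
    max_edges = n * (n - 1) // 2
    target = int(round(sparsity * max_edges))
    ii, jj, ww = _ranked_edges(m.weights)
    n_pos = int((ww > 0).sum())
    if target > n_pos:
        warnings.warn(
            f"requested {target} edges but only {n_pos} nonzero weights; "
            "keeping all nonzero edges",
            stacklevel=2,
        )
        target = n_pos
    adj = np.zeros((n, n), dtype=np.int8)
    keep_i, keep_j = ii[:target], jj[:target]
    adj[keep_i, keep_j] = 1
    adj[keep_j, keep_i] = 1
    achieved = target / max_edges
    return BinaryGraph(adj, achieved, m.subject_id, list(m.node_ids))


def sparsity_sweep(
    m: ConnectomeMatrix,
    s_min: float = 0.05,
    s_max: float = 0.20,
    step: float = 0.01,
) -> ThresholdSweep:
    """Binarize across a sparsity range (defaults: 0.05-0.20 in steps of 0.01).

    With the defaults this yields 16 nested graphs; the edge set at a lower
    sparsity is always contained in the edge set at a higher one because both
    are prefixes of the same deterministic edge ranking.
    """
    if s_min > s_max:
        raise ValueError("s_min must be <= s_max")
    if s_min == s_max:
        levels = np.array([s_min])
    else:
        n_steps = (s_max - s_min) / step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("step must divide the range")
        levels = s_min + step * np.arange(round(n_steps) + 1)
    mean_deg_min = 2 * round(levels[0] * m.n_nodes * (m.n_nodes - 1) / 2) / m.n_nodes
    if mean_deg_min <= np.log(m.n_nodes):
        warnings.warn(
            f"mean degree {mean_deg_min:.2f} at the minimum sparsity does not "
            f"exceed ln(N) = {np.log(m.n_nodes):.2f}; sparse-graph metrics may "
            "be unstable",
            stacklevel=2,
        )
    graphs = [sparsity_binarize(m, float(s)) for s in levels]
    return ThresholdSweep(levels, graphs, step)


def integrate_curve(
    values: Sequence[float], step: float, method: str = "trapezoid"
) -> float:
    """Area under a metric-vs-sparsity curve.

    ``method='trapezoid'`` (default) uses the trapezoidal rule on the evenly
    spaced sweep; ``method='sum'`` returns the plain Riemann sum (value * step),
    which some connectome toolboxes use for integrated ("AUC") metrics.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a nonempty 1-D sequence")
    if len(v) == 1:
        return float(v[0] * step)
    if method == "trapezoid":
        return float(np.trapezoid(v, dx=step))
    if method == "sum":
        return float(v.sum() * step)
    raise ValueError(f"unknown method {method!r}")
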