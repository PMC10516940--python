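"""Embedding-based, AI-assisted annotation workflow.

Cells are clustered on their embedding vectors by deterministic
agglomerative clustering (average linkage, Euclidean by default; cosine
exposed because CNN embeddings are often directionally structured).  A human
labeler then batch-labels whole clusters, overriding individual cells where
needed; sample metadata constrains which labels are permitted (e.g. fetal
cell classes are disallowed for cells from non-pregnant adult donors).
Quality control compares independent labelers and flags a run when their
mismatch rate exceeds 5% (strictly).  Hard-example mining selects cells a
weaker model misclassified, most confidently wrong first, to rebalance the
next training round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "LabelTaxonomy",
    "LabelConstraint",
    "AnnotationSession",
    "ClusterResult",
    "hierarchical_clusters",
    "allowed_labels",
    "batch_assign",
    "labeler_mismatch",
    "mine_hard_examples",
    "suggest_labels",
]

MISMATCH_QC_THRESHOLD = 0.05


@dataclass(frozen=True)
class LabelTaxonomy:
    """Cell-class labels with lineage links.

    ``parents`` maps a label to its parent, so a cell annotated with a leaf
    implicitly carries every ancestor annotation on its lineage path.
    """

    labels: frozenset[str]
    parents: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(self.labels))
        parents = dict(self.parents)
        object.__setattr__(self, "parents", parents)
        for child, parent in parents.items():
            if child not in self.labels or parent not in self.labels:
                raise ValueError(f"lineage link {child!r}->{parent!r} uses unknown labels")
        for label in parents:
            seen = {label}
            node = label
            while node in parents:
                node = parents[node]
                if node in seen:
                    raise ValueError(f"lineage cycle through {label!r}")
                seen.add(node)

    def lineage_path(self, label: str) -> tuple[str, ...]:
        """Label plus all its ancestors, leaf first."""
        if label not in self.labels:
            raise KeyError(f"unknown label {label!r}")
        path = [label]
        while path[-1] in self.parents:
            path.append(self.parents[path[-1]])
        return tuple(path)


@dataclass(frozen=True)
class LabelConstraint:
    """Disallow a label subset when a sample-metadata predicate matches.

    ``when`` maps metadata fields to required values (all must match); a
    field referenced by the rule but absent from the metadata is an error,
    not a silent non-match.
    """

    when: Mapping[str, object]
    disallowed: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "when", dict(self.when))
        object.__setattr__(self, "disallowed", frozenset(self.disallowed))

    def matches(self, metadata: Mapping[str, object]) -> bool:
        for key, value in self.when.items():
            if key not in metadata:
                raise KeyError(f"constraint {self.name!r} references unknown metadata field {key!r}")
            if metadata[key] != value:
                return False
        return True


def allowed_labels(
    sample_metadata: Mapping[str, object],
    taxonomy: LabelTaxonomy,
    constraints: Sequence[LabelConstraint],
) -> frozenset[str]:
    """Taxonomy labels minus the union of disallowed sets of matching rules."""
    disallowed: set[str] = set()
    for c in constraints:
        unknown = c.disallowed - taxonomy.labels
        if unknown:
            raise ValueError(f"constraint {c.name!r} disallows unknown labels {sorted(unknown)}")
        if c.matches(sample_metadata):
            disallowed |= c.disallowed
    return taxonomy.labels - disallowed


@dataclass(frozen=True)
class ClusterResult:
    assignment: np.ndarray  # dense cluster ids from 0, in order of first appearance
    merge_tree: np.ndarray  # scipy linkage matrix (empty for n == 1)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


def hierarchical_clusters(
    embeddings: np.ndarray,
    n_clusters: Optional[int] = None,
    distance_cut: Optional[float] = None,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Deterministic agglomerative clustering of embedding vectors.

    Exactly one of ``n_clusters`` (cut the merge tree to that many flat
    clusters) or ``distance_cut`` (cut at a cophenetic-distance height) must
    be given.  Cluster ids are renumbered densely from 0 in order of first
    appearance.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("embeddings must be a non-empty n x d matrix")
    n = X.shape[0]
    if (n_clusters is None) == (distance_cut is None):
        raise ValueError("give exactly one of n_clusters or distance_cut")
    if n_clusters is not None and not (1 <= n_clusters <= n):
        raise ValueError(f"n_clusters must lie in [1, {n}]")
    if n == 1:
        return ClusterResult(assignment=np.zeros(1, dtype=int),
                             merge_tree=np.empty((0, 4)))
    Z = linkage(pdist(X, metric=metric), method=method)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=distance_cut, criterion="distance")
    _, dense = np.unique(raw, return_inverse=True)
    # renumber in order of first appearance for stable, input-order ids
    first_seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(dense):
        out[i] = first_seen.setdefault(int(c), len(first_seen))
    return ClusterResult(assignment=out, merge_tree=Z)


@dataclass(frozen=True)
class AnnotationSession:
    """State of one labeling session over a clustered cohort."""

    cell_ids: tuple[str, ...]
    embeddings: np.ndarray
    clusters: np.ndarray
    sample_metadata: Mapping[str, object] = field(default_factory=dict)
    taxonomy: Optional[LabelTaxonomy] = None
    constraints: tuple[LabelConstraint, ...] = ()
    labels: tuple[Optional[str], ...] = ()
    provenance: tuple[Optional[str], ...] = ()  # "batch" | "override" | None
    labeler: str = ""

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        object.__setattr__(self, "sample_metadata", dict(self.sample_metadata))
        clusters = np.asarray(self.clusters, dtype=int)
        if clusters.shape != (n,):
            raise ValueError("clusters must align with cell_ids")
        uniq = np.unique(clusters)
        if uniq.size and (uniq.min() != 0 or not np.array_equal(uniq, np.arange(uniq.size))):
            raise ValueError("cluster ids must be dense from 0")
        object.__setattr__(self, "clusters", clusters)
        if not self.labels:
            object.__setattr__(self, "labels", (None,) * n)
        if not self.provenance:
            object.__setattr__(self, "provenance", (None,) * n)
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValueError("labels/provenance must align with cell_ids")
        allowed = self.allowed
        for cid, lab in zip(self.cell_ids, self.labels):
            if lab is not None and allowed is not None and lab not in allowed:
                raise ValueError(f"cell {cid!r} carries disallowed label {lab!r}")

    @property
    def allowed(self) -> Optional[frozenset[str]]:
        """Labels permitted under the active constraints; None if no taxonomy."""
        if self.taxonomy is None:
            return None
        return allowed_labels(self.sample_metadata, self.taxonomy, self.constraints)

    @property
    def n_labeled(self) -> int:
        return sum(lab is not None for lab in self.labels)


def batch_assign(
    session: AnnotationSession,
    cluster_label_map: Mapping[int, str],
    overrides: Optional[Mapping[str, str]] = None,
) -> AnnotationSession:
    """Label whole clusters at once, with per-cell overrides.

    Validation is atomic: if any assignment would violate the active
    constraints the session is returned untouched and the error names the
    first offending cell.  Cells in unmapped clusters keep their previous
    label; counts are conserved (labeled + unlabeled = n).
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(session.cell_ids)
    if unknown:
        raise KeyError(f"override for unknown cells: {sorted(unknown)}")
    known_clusters = set(np.unique(session.clusters).tolist())
    bad = set(cluster_label_map) - known_clusters
    if bad:
        raise KeyError(f"unknown cluster ids: {sorted(bad)}")

    allowed = session.allowed
    new_labels = list(session.labels)
    new_prov = list(session.provenance)
    staged: list[tuple[int, str, str]] = []
    for i, (cid, cluster) in enumerate(zip(session.cell_ids, session.clusters)):
        label: Optional[str] = None
        prov = ""
        if cid in overrides:
            label, prov = overrides[cid], "override"
        elif int(cluster) in cluster_label_map:
            label, prov = cluster_label_map[int(cluster)], "batch"
        if label is None:
            continue
        if allowed is not None and label not in allowed:
            raise ValueError(
                f"label {label!r} is not allowed for cell {cid!r} under active constraints"
            )
        staged.append((i, label, prov))
    for i, label, prov in staged:
        new_labels[i] = label
        new_prov[i] = prov
    return replace(session, labels=tuple(new_labels), provenance=tuple(new_prov))


def labeler_mismatch(
    labels_a: Mapping[str, str], labels_b: Mapping[str, str]
) -> tuple[float, bool]:
    """Disagreement rate between two labelers and the re-labeling QC flag.

    The flag is raised only when the rate strictly exceeds 5%: 5/100 passes,
    6/100 is queued back for re-labeling.
    """
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("labelers share no cells")
    for cid in common:
        if labels_a[cid] is None or labels_b[cid] is None:
            raise ValueError(f"cell {cid!r} is unlabeled")
    n_mismatch = sum(labels_a[c] != labels_b[c] for c in common)
    rate = n_mismatch / len(common)
    return rate, rate > MISMATCH_QC_THRESHOLD


def mine_hard_examples(
    records: Sequence,
    weak_predictions: Sequence[tuple[str, float]],
    per_class_quota: int | Mapping[str, int],
) -> list[str]:
    """Select misclassified cells for the next annotation/training round.

    ``weak_predictions`` aligns with ``records`` as (predicted_label,
    confidence) pairs, confidence being the weak model's score for its own
    call.  Per true class, wrong calls are ranked most-confident first and
    truncated to the quota.  Ties keep input order (stable sort).
    """
    if len(weak_predictions) != len(records):
        raise ValueError("weak_predictions must align with records")

    def quota_for(label: str) -> int:
        q = per_class_quota if isinstance(per_class_quota, int) else per_class_quota.get(label, 0)
        if q < 0:
            raise ValueError("quota must be >= 0")
        return q

    by_class: dict[str, list[tuple[float, int, str]]] = {}
    for i, (rec, (pred, conf)) in enumerate(zip(records, weak_predictions)):
        if pred == rec.true_label:
            continue
        by_class.setdefault(rec.true_label, []).append((-float(conf), i, rec.cell_id))
    selected: list[str] = []
    for label in sorted(by_class):
        ranked = sorted(by_class[label])  # by descending confidence, then input order
        selected.extend(cid for _, _, cid in ranked[: quota_for(label)])
    return selected


def suggest_labels(
    session: AnnotationSession,
    distance_ceiling: Optional[float] = None,
) -> dict[str, str]:
    """Nearest-labeled-neighbour suggestions for unlabeled cells.

    The second annotation mode: propose for each unlabeled cell the label of
    its nearest already-labeled cell, but only within a distance ceiling
    (default: the 90th percentile of within-cluster pairwise distances).
    Suggestions only — nothing is assigned.
    """
    labeled_idx = [i for i, lab in enumerate(session.labels) if lab is not None]
    unlabeled_idx = [i for i, lab in enumerate(session.labels) if lab is None]
    if not labeled_idx or not unlabeled_idx:
        return {}
    X = np.asarray(session.embeddings, dtype=float)
    if distance_ceiling is None:
        within: list[np.ndarray] = []
        for c in np.unique(session.clusters):
            members = X[session.clusters == c]
            if members.shape[0] >= 2:
                within.append(pdist(members))
        distance_ceiling = float(np.percentile(np.concatenate(within), 90)) if within else np.inf
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=1).fit(X[labeled_idx])
    dist, nbr = nn.kneighbors(X[unlabeled_idx])
    out: dict[str, str] = {}
    for row, (d, j) in enumerate(zip(dist[:, 0], nbr[:, 0])):
        if d <= distance_ceiling:
            i = unlabeled_idx[row]
            out[session.cell_ids[i]] = session.labels[labeled_idx[int(j)]]  # type: ignore[index]
    return out
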