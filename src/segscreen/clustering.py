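"""Hierarchical clustering of phenotypic vectors.

Dissimilarity is the correlation distance 1 - Pearson(r) between 12-score
vectors; agglomeration is average linkage (UPGMA-style) with deterministic
lexicographic tie-breaking, so cluster output is independent of input row
order and platform.  Flat clusters are cut at a correlation cutoff c,
i.e. at distance threshold 1 - c.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .model import PhenotypicVector, ScreenTable
from .ranking import summarize_treatment

logger = logging.getLogger(__name__)

CLUSTER_LABELS = ("first_class", "secondary_tail", "seg_plus_morph", "other")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step.  Node ids: leaves are 0..n-1 in label order,
    internal nodes are n, n+1, ... in merge order."""

    node_a: int
    node_b: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    labels: Tuple[str, ...]
    merges: Tuple[Merge, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaves_under(self, node: int) -> List[int]:
        n = self.n_leaves
        if node < n:
            return [node]
        m = self.merges[node - n]
        return self.leaves_under(m.node_a) + self.leaves_under(m.node_b)


def distance_matrix(
    vectors: Dict[str, PhenotypicVector]
) -> Tuple[List[str], np.ndarray, List[str]]:
    """Pairwise correlation distances between labeled, nonconstant vectors.

    Constant vectors carry no correlation information and are excluded;
    their labels are returned separately.  Labels are sorted so the matrix
    (and everything downstream) is independent of input order.
    """
    if len(vectors) < 2:
        raise InsufficientDataError("need at least 2 vectors")
    labels = sorted(vectors)
    excluded = [lab for lab in labels if vectors[lab].is_constant]
    kept = [lab for lab in labels if lab not in set(excluded)]
    if excluded:
        logger.info("distance_matrix: excluded %d constant vectors", len(excluded))
    if len(kept) < 2:
        raise InsufficientDataError("fewer than 2 nonconstant vectors")
    mat = np.array([vectors[lab].scores for lab in kept], dtype=float)
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0  # BLAS output is symmetric only to the ULP
    np.fill_diagonal(dist, 0.0)
    return kept, dist, excluded


def average_linkage(
    dist: np.ndarray, labels: Optional[Sequence[str]] = None
) -> Dendrogram:
    """UPGMA-style agglomeration: repeatedly merge the pair of clusters with
    minimal mean inter-cluster distance (Lance-Williams update).

    Among tied pairs, the one whose (smallest-leaf-label, smallest-leaf-label)
    pair is lexicographically earliest is merged first.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValidationError("distances must be nonnegative")
    if labels is None:
        labels = [f"L{i:04d}" for i in range(n)]
    labels = tuple(labels)
    if len(labels) != n:
        raise ValidationError("label count must match matrix size")

    if n == 1:
        return Dendrogram(labels=labels, merges=())

    work = dist.astype(float).copy()
    work = (work + work.T) / 2.0  # exact symmetry so ties pair up
    np.fill_diagonal(work, np.inf)
    active = {i: i for i in range(n)}       # position -> current node id
    sizes = {i: 1 for i in range(n)}        # position -> cluster size
    rep = {i: labels[i] for i in range(n)}  # position -> smallest leaf label
    merges: List[Merge] = []
    next_id = n
    for _ in range(n - 1):
        positions = sorted(active)
        sub = work[np.ix_(positions, positions)]
        m = sub.min()
        ii, jj = np.where(sub == m)
        candidates = []
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            pa, pb = positions[a], positions[b]
            la, lb = sorted((rep[pa], rep[pb]))
            candidates.append(((la, lb), pa, pb))
        candidates.sort()
        _, pa, pb = candidates[0]
        # order children so the smaller-label cluster comes first
        if rep[pb] < rep[pa]:
            pa, pb = pb, pa
        height = work[pa, pb]
        merges.append(
            Merge(
                node_a=active[pa],
                node_b=active[pb],
                height=float(height),
                size=sizes[pa] + sizes[pb],
            )
        )
        # Lance-Williams average-linkage update into position pa
        na, nb = sizes[pa], sizes[pb]
        new_row = (na * work[pa, :] + nb * work[pb, :]) / (na + nb)
        work[pa, :] = new_row
        work[:, pa] = new_row
        work[pa, pa] = np.inf
        work[pb, :] = np.inf
        work[:, pb] = np.inf
        sizes[pa] = na + nb
        rep[pa] = min(rep[pa], rep[pb])
        active[pa] = next_id
        del active[pb], sizes[pb], rep[pb]
        next_id += 1
    return Dendrogram(labels=labels, merges=tuple(merges))


@dataclass
class ClusterAssignment:
    assignment: Dict[str, int]
    cutoff_correlation: float
    excluded_constant: List[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> List[str]:
        return sorted(k for k, v in self.assignment.items() if v == cluster_id)

    def cluster_ids(self) -> List[int]:
        return sorted(set(self.assignment.values()))


def cut_clusters(
    dend: Dendrogram, cutoff_correlation: float = 0.6
) -> ClusterAssignment:
    """Flat clusters: maximal subtrees whose merge heights are all at or
    below the distance threshold 1 - cutoff_correlation."""
    if not -1.0 <= cutoff_correlation <= 1.0:
        raise ValidationError("cutoff_correlation must be in [-1, 1]")
    threshold = 1.0 - cutoff_correlation
    n = dend.n_leaves
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_leaf = {i: i for i in range(n)}  # node id -> one contained leaf
    for k, m in enumerate(dend.merges):
        la, lb = node_leaf[m.node_a], node_leaf[m.node_b]
        node_leaf[n + k] = la
        if m.height <= threshold:
            parent[find(la)] = find(lb)
    groups: Dict[int, List[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    # renumber clusters by their smallest member label for determinism
    ordered = sorted(groups.values(), key=lambda g: min(dend.labels[i] for i in g))
    assignment = {
        dend.labels[leaf]: cid for cid, g in enumerate(ordered) for leaf in g
    }
    return ClusterAssignment(
        assignment=assignment, cutoff_correlation=cutoff_correlation
    )


@dataclass
class ClusterProfile:
    cluster_id: int
    members: List[str]
    mean_vector: Tuple[float, ...]
    seg_mean: float
    morph_mean: float
    label: str


def cluster_vectors_from_table(
    table: ScreenTable, include_all_zero: bool = False
) -> Dict[str, PhenotypicVector]:
    """Treatment vectors eligible for clustering: analyzable and, by default,
    showing at least one nonzero score (all-zero treatments carry no
    correlation signal)."""
    out = {}
    for r in table.analyzable_records():
        if not include_all_zero and not r.vector.any_defect:
            continue
        out[r.treatment_id] = r.vector
    return out


def cluster_profiles(
    assign: ClusterAssignment,
    table: ScreenTable,
    secondary_tail_min: float = 1.5,
    seg_plus_morph_min_seg: float = 1.0,
    seg_plus_morph_min_morph: float = 2.0,
) -> List[ClusterProfile]:
    """Characterize each flat cluster by its elementwise mean vector and
    assign a descriptive label.

    Labels (mutually exclusive, in precedence order):
      - first_class: the cluster (size >= 2) maximizing
        seg_mean / (morph_mean + 1) — most segmentation-specific;
      - secondary_tail: secondary-tail (S) and tail-shape (T) means are the
        two dominant signals among the morphology codes plus S, each above
        `secondary_tail_min`;
      - seg_plus_morph: substantial segmentation signal on top of strong
        general-morphology defects;
      - other.
    """
    record_map = table.record_map()
    schema = table.schema
    n_morph = len(schema.morphology_codes)
    profiles: List[ClusterProfile] = []
    for cid in assign.cluster_ids():
        members = assign.members(cid)
        vectors = [
            record_map[m].vector for m in members if m in record_map
        ]
        vectors = [v for v in vectors if v is not None]
        if not vectors:
            logger.warning("cluster %d has no resolvable members; skipped", cid)
            continue
        mean_vec = np.mean([v.scores for v in vectors], axis=0)
        morph_mean = float(np.mean(mean_vec[:n_morph]))
        seg_mean = float(np.mean(mean_vec[n_morph:]))
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                members=members,
                mean_vector=tuple(float(x) for x in mean_vec),
                seg_mean=seg_mean,
                morph_mean=morph_mean,
                label="other",
            )
        )

    # first_class: argmax of seg/(morph+1) among clusters with >= 2 members
    eligible = [p for p in profiles if len(p.members) >= 2]
    best = None
    if eligible:
        best = max(
            eligible,
            key=lambda p: (p.seg_mean / (p.morph_mean + 1.0), -p.cluster_id),
        )
    codes = list(schema.codes)
    s_idx = codes.index("S")
    t_idx = codes.index("T")
    tail_signal_idx = list(range(n_morph)) + [s_idx]
    for p in profiles:
        if best is not None and p.cluster_id == best.cluster_id:
            p.label = "first_class"
            continue
        signals = {i: p.mean_vector[i] for i in tail_signal_idx}
        top2 = sorted(signals, key=lambda i: -signals[i])[:2]
        if (
            set(top2) == {s_idx, t_idx}
            and p.mean_vector[s_idx] >= secondary_tail_min
            and p.mean_vector[t_idx] >= secondary_tail_min
        ):
            p.label = "secondary_tail"
        elif (
            p.seg_mean >= seg_plus_morph_min_seg
            and p.morph_mean >= seg_plus_morph_min_morph
        ):
            p.label = "seg_plus_morph"
    return profiles


def select_pulse_candidates(
    assign: ClusterAssignment,
    profiles: List[ClusterProfile],
    label: str,
    k: int,
    seed: int,
    table: Optional[ScreenTable] = None,
) -> List[str]:
    """Uniform random sample (without replacement) of k distinct compounds
    from the clusters carrying the requested label; deterministic per seed."""
    labeled = [p for p in profiles if p.label == label]
    if not labeled:
        raise ValidationError(f"no cluster labeled {label!r}")
    record_map = table.record_map() if table is not None else None
    compounds = set()
    for p in labeled:
        for member in p.members:
            if record_map is not None and member in record_map:
                compounds.add(record_map[member].compound_id)
            else:
                compounds.add(member.split("@", 1)[0])
    pool = sorted(compounds)
    if k > len(pool):
        raise ValidationError(
            f"k={k} exceeds cluster compound count {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=k, replace=False)
    return sorted(pool[i] for i in picked)


_NEWICK_UNSAFE = re.compile(r"[\s()\[\],:;']")


def _newick_label(label: str) -> str:
    return _NEWICK_UNSAFE.sub("_", label)


def to_newick(dend: Dendrogram) -> str:
    """Export as Newick with the ultrametric height-splitting convention:
    each node sits at half its merge height, leaves at 0, so two leaves
    merged at height h are rendered '(A:h/2,B:h/2);'."""
    n = dend.n_leaves
    if n == 1:
        return f"{_newick_label(dend.labels[0])};"

    elevation = {i: 0.0 for i in range(n)}
    for k, m in enumerate(dend.merges):
        elevation[n + k] = m.height / 2.0

    def render(node: int, parent_elev: float) -> str:
        branch = parent_elev - elevation[node]
        if node < n:
            return f"{_newick_label(dend.labels[node])}:{branch:g}"
        m = dend.merges[node - n]
        inner = (
            f"({render(m.node_a, elevation[node])},"
            f"{render(m.node_b, elevation[node])})"
        )
        return f"{inner}:{branch:g}"

    root = n + len(dend.merges) - 1
    m = dend.merges[-1]
    body = (
        f"({render(m.node_a, elevation[root])},"
        f"{render(m.node_b, elevation[root])})"
    )
    return f"{body};"
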