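"""Distance-based phylogeny: Poisson-corrected protein distances,
Saitou-Nei neighbor joining, nonparametric bootstrap, clade assignment.

Queries are placed among labeled reference transposases by building a
joint alignment, an NJ tree with bootstrap supports, rooting on a
designated outgroup, and assigning each query to the clade of the smallest
well-supported (>80) monophyletic group that contains it and references of
exactly one clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import ProtSequence, center_star_msa

SUPPORT_THRESHOLD = 80.0
SATURATION_P = 0.95
SATURATION_CAP = 5.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray | None = None  # boolean mask of capped entries

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map; leaves carry labels.

    ``supports`` maps canonical bipartitions (frozenset of leaf labels on
    the side not containing the reference leaf) to bootstrap percentages.
    """

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels reachable from v without crossing the edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                out.add(self.leaf_labels[x])
            for y, _ in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Canonical nontrivial splits (side excluding the reference leaf)."""
        ref = min(self.labels)
        out = set()
        done = set()
        for u in self.adjacency:
            for v, _ in self.adjacency[u]:
                if (v, u) in done or (u, v) in done:
                    continue
                done.add((u, v))
                side = self._side_leaves(u, v)
                if ref in side:
                    side = set(self.labels) - side
                if 2 <= len(side) <= len(self.labels) - 2:
                    out.add(frozenset(side))
        return out

    def distance(self, a: str, b: str) -> float:
        ids = {lbl: i for i, lbl in self.leaf_labels.items()}
        start, goal = ids[a], ids[b]
        stack = [(start, 0.0, -1)]
        while stack:
            node, acc, prev = stack.pop()
            if node == goal:
                return acc
            for nxt, ln in self.adjacency[node]:
                if nxt != prev:
                    stack.append((nxt, acc + ln, node))
        raise KeyError(f"no path between {a} and {b}")

    def newick(self, root: int | None = None) -> str:
        if root is None:
            root = max(self.adjacency, key=lambda k: len(self.adjacency[k]))

        def fmt(node: int, parent: int, length: float | None) -> str:
            children = [(c, l) for c, l in self.adjacency[node] if c != parent]
            if not children:
                body = self.leaf_labels[node]
            else:
                inner = ",".join(fmt(c, node, l) for c, l in children)
                label = ""
                if self.supports and parent != -1:
                    side = self._side_leaves(parent, node)
                    ref = min(self.labels)
                    key = frozenset(
                        side if ref not in side else set(self.labels) - side
                    )
                    if key in self.supports:
                        label = f"{self.supports[key]:.0f}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(root, -1, None) + ";"


# ---------------------------------------------------------------------------
# Distances


def _msa_array(rows: list[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)


def pairwise_p_distances(rows: list[str], labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = _msa_array(rows)
    gap = np.uint8(ord("-"))
    n = len(rows)
    p = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != gap) & (arr[j] != gap)
            ns = int(valid.sum())
            shared[i, j] = shared[j, i] = ns
            if ns == 0:
                raise ValueError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no ungapped columns"
                )
            mism = int((arr[i][valid] != arr[j][valid]).sum())
            p[i, j] = p[j, i] = mism / ns
    return p, shared


def protein_distance(rows: list[str], labels: list[str]) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared ungapped columns.

    p >= 0.95 is capped at SATURATION_CAP and flagged.
    """
    p, _ = pairwise_p_distances(rows, labels)
    sat = p >= SATURATION_P
    d = np.where(sat, SATURATION_CAP, -np.log(np.clip(1.0 - p, 1e-12, None)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(labels), d=d, saturated=sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the smallest (row, column) index
    pair; negative branch lengths are clamped to zero with the deficit
    moved to the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    node_ids = list(range(n))
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = dict(enumerate(dm.labels))
    next_id = n

    def connect(a: int, b: int, length: float) -> None:
        length = max(0.0, length)
        adjacency.setdefault(a, []).append((b, length))
        adjacency.setdefault(b, []).append((a, length))

    while len(node_ids) > 2:
        m = len(node_ids)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest index pair on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        u = next_id
        next_id += 1
        connect(u, node_ids[i], li)
        connect(u, node_ids[j], lj)
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        node_ids = [node_ids[k] for k in keep] + [u]
    connect(node_ids[0], node_ids[1], D[0, 1])
    return PhyloTree(adjacency=adjacency, leaf_labels=leaf_labels)


def bootstrap_support(
    rows: list[str],
    labels: list[str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree on the full alignment with supports from column resampling.

    Support of an internal edge = percentage of replicate NJ trees that
    contain the same bipartition.
    """
    ncol = len(rows[0])
    if ncol < 10:
        raise ValueError("alignment too short to bootstrap (need >= 10 columns)")
    base = nj_tree(protein_distance(rows, labels))
    target = base.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    arr = _msa_array(rows)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(chr(c) for c in arr[i, cols]) for i in range(len(rows))]
        try:
            rep = nj_tree(protein_distance(rep_rows, labels))
        except ValueError:  # a pair may share no columns in a resample
            continue
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    base.supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return base


# ---------------------------------------------------------------------------
# Clade assignment


@dataclass
class CladeAssignment:
    query: str
    clade: str  # one of the reference clades, or "unassigned"
    support: float


def build_protein_msa(seqs: list[ProtSequence]) -> tuple[list[str], list[str]]:
    """Center-star alignment of proteins; the longest sequence is the center."""
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i].id))
    center = seqs[order[0]]
    others = [seqs[i] for i in order[1:]]
    rows = center_star_msa(
        center.residues.rstrip("*"),
        [o.residues.rstrip("*") for o in others],
        protein=True,
    )
    labels = [center.id] + [o.id for o in others]
    return rows, labels


def assign_clades(
    queries: list[ProtSequence],
    references: list[tuple[ProtSequence, str]],
    outgroup: list[ProtSequence],
    n_replicates: int = 200,
    seed: int = 0,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> list[CladeAssignment]:
    """Place queries among labeled references by supported monophyly.

    The tree is rooted on the (first) outgroup leaf; a query is assigned
    to clade X when the smallest ancestor with bootstrap support above the
    threshold contains references of clade X only.
    """
    if not outgroup:
        raise ValueError("an outgroup is required for rooting")
    clade_counts: dict[str, int] = {}
    for _, c in references:
        clade_counts[c] = clade_counts.get(c, 0) + 1
    if any(v < 2 for v in clade_counts.values()):
        raise ValueError("each reference clade needs at least 2 members")

    all_seqs = queries + [r for r, _ in references] + outgroup
    rows, labels = build_protein_msa(all_seqs)
    tree = bootstrap_support(rows, labels, n_replicates=n_replicates, seed=seed)

    ref_clade = {r.id: c for r, c in references}
    out_ids = {o.id for o in outgroup}
    ids = {lbl: i for i, lbl in tree.leaf_labels.items()}
    root_leaf = ids[outgroup[0].id]
    parent: dict[int, int] = {root_leaf: -1}
    stack = [root_leaf]
    while stack:
        u = stack.pop()
        for v, _ in tree.adjacency[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)

    def subtree_leaves(node: int) -> set[str]:
        out, st = set(), [node]
        seen = {parent[node]}
        while st:
            x = st.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in tree.leaf_labels:
                out.add(tree.leaf_labels[x])
            st.extend(v for v, _ in tree.adjacency[x])
        return out

    ref_leaf = min(tree.labels)
    results = []
    for q in queries:
        node = parent[ids[q.id]]
        assigned, support = "unassigned", 0.0
        while node != -1 and parent[node] != -1:
            leaves = subtree_leaves(node)
            key = frozenset(
                leaves if ref_leaf not in leaves else set(tree.labels) - leaves
            )
            sup = tree.supports.get(key)
            refs_in = {ref_clade[l] for l in leaves if l in ref_clade}
            if sup is not None and sup > support_threshold and refs_in:
                if len(refs_in) == 1 and not (leaves & out_ids):
                    assigned, support = next(iter(refs_in)), sup
                break
            node = parent[node]
        results.append(CladeAssignment(query=q.id, clade=assigned, support=support))
    return results
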