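"""Distance-based phylogeny: Poisson-corrected amino-acid distances,
neighbor-joining with deterministic tie-breaking, nonparametric bootstrap
supports, and reference-guided subfamily assignment.

The distance model is the Poisson correction d = -ln(1 - p), where p is
the proportion of differing amino acids over pairwise comparable sites.
Gap handling follows the "partial deletion" convention: an alignment
column is retained when it is gap-free in at least ``site_coverage`` of
the sequences (default 95%), and within a pair only retained columns
where both sequences are ungapped are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = {"-", ".", "X", "*"}
SITE_COVERAGE = 0.95


class SaturationError(ValueError):
    """Raised when a distance matrix contains saturated (p >= 1) entries."""


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-pair usable-site counts.

    Saturated pairs (p >= 1 under the Poisson correction) carry ``inf``.
    """

    labels: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix not symmetric")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not math.isfinite(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def poisson_distance(
    msa: list[tuple[str, str]], site_coverage: float = SITE_COVERAGE
) -> DistanceMatrix:
    """Poisson-corrected pairwise distances from an aligned protein MSA."""
    if len(msa) < 2:
        raise ValueError("need at least two sequences")
    labels = [name for name, _ in msa]
    seqs = [seq.upper() for _, seq in msa]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")
    if length == 0:
        raise ValueError("empty alignment")

    arr = np.array([list(s) for s in seqs])
    is_gap = np.isin(arr, sorted(GAP_CHARS))
    coverage = 1.0 - is_gap.mean(axis=0)
    keep = coverage >= site_coverage
    arr = arr[:, keep]
    is_gap = is_gap[:, keep]

    n = len(labels)
    d = np.zeros((n, n))
    n_sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~is_gap[i] & ~is_gap[j]
            m = int(both.sum())
            n_sites[i, j] = n_sites[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = math.inf
                continue
            p = float((arr[i, both] != arr[j, both]).mean())
            d[i, j] = d[j, i] = math.inf if p >= 1.0 else -math.log(1.0 - p)
    return DistanceMatrix(labels=labels, d=d, n_sites=n_sites)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


class PhyloTree:
    """An unrooted tree stored with a (trifurcating) root node."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.labels = sorted(root.leaf_names())

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, each as the side not containing the first label."""
        all_leaves = frozenset(self.labels)
        anchor = self.labels[0]
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(child.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    splits.add(canon)
                walk(child)

        walk(self.root)
        return splits

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode):
            for child in node.children:
                if not child.is_leaf:
                    out.append(child)
                    walk(child)

        walk(self.root)
        return out

    def patristic_distances(self) -> dict[str, dict[str, float]]:
        """Leaf-to-leaf path lengths along branches."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: TreeNode):
            nid = id(node)
            names[nid] = node.name if node.is_leaf else None
            adj.setdefault(nid, [])
            for child in node.children:
                cid = id(child)
                adj[nid].append((cid, child.length))
                adj.setdefault(cid, []).append((nid, child.length))
                walk(child)

        walk(self.root)
        leaves = [nid for nid, nm in names.items() if nm is not None]
        out: dict[str, dict[str, float]] = {}
        for start in leaves:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            out[names[start]] = {
                names[nid]: dist[nid] for nid in leaves if names[nid] is not None
            }
        return out


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining.

    Q-matrix minimization with lexicographic tie-breaking; negative branch
    lengths are clamped to zero with the deficit moved to the sister edge
    so the joined pair's distance is preserved.
    """
    if len(dm.labels) < 3:
        raise ValueError("need at least three taxa")
    sat = dm.saturated_pairs
    if sat:
        raise SaturationError(f"saturated distances for pairs: {sat}")

    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.d.astype(float).copy()

    def clamp_transfer(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically first minimal (i, j), i < j
        best = (math.inf, -1, -1)
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp_transfer(li, lj)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent = TreeNode(children=[ni, nj_])

        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    if len(nodes) == 3:
        d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
        lengths = [
            (d01 + d02 - d12) / 2.0,
            (d01 + d12 - d02) / 2.0,
            (d02 + d12 - d01) / 2.0,
        ]
        for node, ln in zip(nodes, lengths):
            node.length = max(ln, 0.0)
        root = TreeNode(children=list(nodes))
    else:  # 2 nodes: single edge
        nodes[0].length = nodes[1].length = d[0, 1] / 2.0
        root = TreeNode(children=list(nodes))
    return PhyloTree(root)


def bootstrap_support(
    msa: list[tuple[str, str]],
    n_reps: int = 1000,
    seed: int | None = None,
    site_coverage: float = SITE_COVERAGE,
) -> PhyloTree:
    """NJ tree with internal-edge bootstrap supports (% of replicates).

    Columns are resampled with replacement per replicate; replicates whose
    resampled distances saturate are dropped from the denominator.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrap")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = len(msa[0][1])
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")

    ref = nj_tree(poisson_distance(msa, site_coverage))
    ref_splits = {split: 0 for split in ref.bipartitions()}

    rng = np.random.default_rng(seed)
    valid = 0
    names = [name for name, _ in msa]
    cols = np.array([list(seq.upper()) for _, seq in msa])
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        rep_msa = [(nm, "".join(row)) for nm, row in zip(names, cols[:, idx])]
        try:
            rep_tree = nj_tree(poisson_distance(rep_msa, site_coverage))
        except (SaturationError, ValueError):
            continue
        valid += 1
        rep_splits = rep_tree.bipartitions()
        for split in ref_splits:
            if split in rep_splits:
                ref_splits[split] += 1

    denom = valid if valid else 1
    all_leaves = frozenset(ref.labels)
    anchor = ref.labels[0]
    for node in ref.internal_nodes():
        side = frozenset(node.leaf_names())
        if not 1 < len(side) < len(all_leaves) - 1:
            continue
        canon = side if anchor not in side else all_leaves - side
        node.support = 100.0 * ref_splits.get(canon, 0) / denom
    return ref


# ---------------------------------------------------------------------------
# Subfamily assignment
# ---------------------------------------------------------------------------


def assign_subfamily(
    tree: PhyloTree, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Assign each unlabeled leaf the subfamily of its enclosing clade.

    For every leaf, the smallest bipartition side (over all edges of the
    unrooted tree) containing the leaf and at least one labeled reference
    supplies a majority vote among its references; vote ties fall back to
    the nearest reference by patristic distance.
    """
    refs = {lbl: fam for lbl, fam in reference_labels.items() if lbl in set(tree.labels)}
    if not refs:
        raise ValueError("no reference labels present in tree")

    all_leaves = frozenset(tree.labels)
    sides: list[frozenset[str]] = [all_leaves]

    def walk(node: TreeNode):
        for child in node.children:
            side = frozenset(child.leaf_names())
            sides.append(side)
            sides.append(all_leaves - side)
            walk(child)

    walk(tree.root)
    patristic = tree.patristic_distances()

    out: dict[str, str] = {}
    for leaf in tree.labels:
        if leaf in refs:
            continue
        candidates = [
            s for s in sides if leaf in s and any(r in s for r in refs)
        ]
        best = min(candidates, key=len)
        fams: dict[str, int] = {}
        for r in refs:
            if r in best:
                fams[refs[r]] = fams.get(refs[r], 0) + 1
        top = max(fams.values())
        winners = sorted(f for f, c in fams.items() if c == top)
        if len(winners) == 1:
            out[leaf] = winners[0]
        else:
            nearest = min(
                (r for r in refs if r in best and refs[r] in winners),
                key=lambda r: (patristic[leaf][r], r),
            )
            out[leaf] = refs[nearest]
    return out
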