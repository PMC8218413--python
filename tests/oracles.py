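"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores
by exhaustive path enumeration, tree selection by least-squares fit over
all topologies, pI by fine-grid charge scan, codon difference counts by
explicit pathway enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Alignment score by exhaustive enumeration
# ---------------------------------------------------------------------------


def brute_force_align_score(
    a: str, b: str, open_cost: float = 10.0, ext_cost: float = 0.5
) -> float:
    """Max global alignment score over every monotone alignment path.

    A gap of length L costs open + (L-1)*ext; end gaps are penalized.
    """
    best = -math.inf

    def rec(i: int, j: int, state: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "m", score + BLOSUM62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "ga", score - (ext_cost if state == "ga" else open_cost))
        if j < len(b):
            rec(i, j + 1, "gb", score - (ext_cost if state == "gb" else open_cost))

    rec(0, 0, "m", 0.0)
    return best


# ---------------------------------------------------------------------------
# Five-taxon least-squares topology oracle
# ---------------------------------------------------------------------------


def five_taxon_topologies(labels: list[str]) -> list[list[tuple[str, str]]]:
    """All 15 unrooted binary topologies on 5 labels, as edge lists.

    Built by inserting leaves into every edge of the smaller trees.
    Internal nodes are named I0, I1, I2.
    """
    assert len(labels) == 5
    a, b, c, d, e = labels
    base = [(a, "I0"), (b, "I0"), (c, "I0")]  # 3-leaf star
    trees4 = []
    for edge in list(base):
        edges = [x for x in base if x != edge]
        u, v = edge
        edges += [(u, "I1"), ("I1", v), (d, "I1")]
        trees4.append(edges)
    trees5 = []
    for t4 in trees4:
        for edge in list(t4):
            edges = [x for x in t4 if x != edge]
            u, v = edge
            edges += [(u, "I2"), ("I2", v), (e, "I2")]
            trees5.append(edges)
    return trees5


def _leaf_paths(edges: list[tuple[str, str]], leaves: list[str]):
    adj: dict[str, list[tuple[str, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for start in leaves:
        seen = {start: []}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, idx in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + [idx]
                    stack.append(v)
        for end in leaves:
            if end != start:
                paths[(start, end)] = seen[end]
    return paths


def tree_bipartitions(edges: list[tuple[str, str]], leaves: list[str]):
    """Nontrivial splits of an edge-list tree, canonicalized like PhyloTree."""
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    anchor = sorted(leaves)[0]
    all_leaves = frozenset(leaves)
    splits = set()
    for u, v in edges:
        # leaves on the v-side of edge (u, v)
        seen = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != u and y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(lf for lf in leaves if lf in seen)
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side if anchor not in side else all_leaves - side)
    return splits


def least_squares_topology(labels: list[str], dmatrix: np.ndarray):
    """Bipartitions of the best least-squares topology for a 5x5 matrix."""
    pairs = list(itertools.combinations(range(5), 2))
    best = (math.inf, None)
    for edges in five_taxon_topologies(labels):
        paths = _leaf_paths(edges, labels)
        design = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            for idx in paths[(labels[i], labels[j])]:
                design[r, idx] = 1.0
            y[r] = dmatrix[i, j]
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((design @ sol - y) ** 2).sum())
        if rss < best[0]:
            best = (rss, edges)
    return tree_bipartitions(best[1], labels)


def random_additive_matrix(labels: list[str], rng: np.random.Generator):
    """A random 5-taxon tree and its additive distance matrix."""
    topos = five_taxon_topologies(labels)
    edges = topos[rng.integers(0, len(topos))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _leaf_paths(edges, labels)
    d = np.zeros((5, 5))
    for i in range(5):
        for j in range(i + 1, 5):
            d[i, j] = d[j, i] = sum(
                lengths[idx] for idx in paths[(labels[i], labels[j])]
            )
    return edges, d


# ---------------------------------------------------------------------------
# pI by fine-grid charge scan
# ---------------------------------------------------------------------------


def grid_scan_pi(protein: str, net_charge_fn, resolution: float = 1e-4) -> float:
    """pH grid point with the smallest absolute net charge."""
    phs = np.arange(0.0, 14.0 + resolution, resolution)
    charges = np.abs(net_charge_fn(protein, phs))
    return float(phs[int(np.argmin(charges))])


# ---------------------------------------------------------------------------
# Codon pathway enumeration
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def enumerate_pathway_counts(codon_a: str, codon_b: str, code: dict):
    """(Sd, Nd) by explicit enumeration of mutation orderings.

    Pathways through stop codons are discarded; if all are, every pathway
    counts. ``code`` maps sense codons to amino acids.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []
    fallback = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = codon_a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if code.get(nxt) == code.get(cur) and nxt not in _STOPS and cur not in _STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if blocked else results).append((sd, nd))
    use = results or fallback
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd
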