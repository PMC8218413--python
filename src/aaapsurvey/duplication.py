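"""Tandem and segmental duplication detection.

Tandem duplicates are family members on one chromosome separated by at
most ``max_sep`` intervening genes (intervening = ordinal gap minus one)
with protein similarity strictly greater than ``min_sim`` percent;
qualifying pairs are merged into groups by transitive closure.

Segmental duplicates are detected from collinear blocks: chains of
homologous gene pairs (anchors) whose ordinals run strictly monotonically
on both chromosomes, found by dynamic-programming chaining in the spirit
of MCScanX (unit anchor score, linear gap penalty — a documented
simplification of its full model), with the MCScanX-style defaults of at
least 5 anchors per block and at most 25 genes between consecutive
anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .family_model import GeneModel

logger = logging.getLogger(__name__)

MAX_TANDEM_SEPARATION = 5
MIN_TANDEM_SIMILARITY = 50.0
MIN_BLOCK_ANCHORS = 5
MAX_ANCHOR_GAP = 25


@dataclass
class TandemGroup:
    chromosome: str
    members: list[str]  # gene ids ordered by ordinal
    evidence: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class AnchorHit:
    """A homologous gene pair with chromosome/ordinal context."""

    gene_a: str
    chrom_a: str
    ordinal_a: int
    gene_b: str
    chrom_b: str
    ordinal_b: int
    similarity: float = 100.0


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    score: float
    orientation: str  # "same" | "inverted"


@dataclass(frozen=True)
class DuplicationSummary:
    n_total: int
    n_tandem: int
    n_segmental: int

    @property
    def n_duplicated(self) -> int:
        return self.n_tandem + self.n_segmental

    @property
    def pct_duplicated(self) -> float:
        return 100.0 * self.n_duplicated / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# Tandem detection
# ---------------------------------------------------------------------------


def find_tandem(
    genes: Sequence[GeneModel],
    similarity_fn: Callable[[str, str], float],
    max_sep: int = MAX_TANDEM_SEPARATION,
    min_sim: float = MIN_TANDEM_SIMILARITY,
) -> list[TandemGroup]:
    """Group family genes into tandem arrays by transitive closure.

    ``similarity_fn(gene_id_a, gene_id_b)`` must be symmetric and return
    percent protein similarity. The similarity condition is strict
    (> min_sim); the separation condition is inclusive (<= max_sep
    intervening genes).
    """
    for g in genes:
        if g.ordinal is None:
            raise ValueError(f"gene {g.gene_id} has no ordinal")

    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    evidence: dict[tuple[str, str], float] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom, members in by_chrom.items():
        members = sorted(members, key=lambda g: g.ordinal)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                intervening = abs(b.ordinal - a.ordinal) - 1
                if intervening > max_sep:
                    break  # sorted by ordinal: later j only farther
                sim = similarity_fn(a.gene_id, b.gene_id)
                if sim > min_sim:
                    evidence[(a.gene_id, b.gene_id)] = sim
                    parent[find(a.gene_id)] = find(b.gene_id)

    clusters: dict[str, list[GeneModel]] = {}
    for g in genes:
        clusters.setdefault(find(g.gene_id), []).append(g)

    groups = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda g: g.ordinal)
        ids = [g.gene_id for g in members]
        ev = {
            pair: sim
            for pair, sim in evidence.items()
            if pair[0] in ids and pair[1] in ids
        }
        groups.append(
            TandemGroup(chromosome=members[0].chromosome, members=ids, evidence=ev)
        )
    groups.sort(key=lambda g: (g.chromosome, g.members))
    return groups


# ---------------------------------------------------------------------------
# Collinear block detection
# ---------------------------------------------------------------------------


def _chain(hits: list[AnchorHit], sign: int, max_gap: int, gap_penalty: float):
    """Best monotone chain over hits by DP; returns (score, chain_indices)."""
    order = sorted(
        range(len(hits)), key=lambda k: (hits[k].ordinal_a, sign * hits[k].ordinal_b)
    )
    best_score = [1.0] * len(hits)
    prev = [-1] * len(hits)
    for oi, k in enumerate(order):
        hk = hits[k]
        for k2 in order[:oi]:
            h2 = hits[k2]
            da = hk.ordinal_a - h2.ordinal_a
            db = sign * (hk.ordinal_b - h2.ordinal_b)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            cand = best_score[k2] + 1.0 - gap_penalty * (da - 1 + db - 1)
            if cand > best_score[k]:
                best_score[k] = cand
                prev[k] = k2
    end = max(range(len(hits)), key=lambda k: best_score[k])
    chain = []
    k = end
    while k != -1:
        chain.append(k)
        k = prev[k]
    chain.reverse()
    return best_score[end], chain


def find_collinear_blocks(
    anchors: Iterable[AnchorHit],
    min_block: int = MIN_BLOCK_ANCHORS,
    max_gap: int = MAX_ANCHOR_GAP,
    gap_penalty: float = 0.01,
) -> list[CollinearBlock]:
    """Chain anchor hits into maximal collinear blocks per chromosome pair.

    Chains shorter than ``min_block`` anchors are discarded; overlapping
    chains are resolved greedily by score.
    """
    by_pair: dict[tuple[str, str], list[AnchorHit]] = {}
    for hit in anchors:
        if hit.gene_a == hit.gene_b:
            continue
        key = (hit.chrom_a, hit.chrom_b)
        if (hit.chrom_b, hit.chrom_a) in by_pair and key not in by_pair:
            hit = AnchorHit(
                hit.gene_b, hit.chrom_b, hit.ordinal_b,
                hit.gene_a, hit.chrom_a, hit.ordinal_a, hit.similarity,
            )
            key = (hit.chrom_a, hit.chrom_b)
        by_pair.setdefault(key, []).append(hit)

    blocks: list[CollinearBlock] = []
    for (ca, cb), hits in sorted(by_pair.items()):
        if ca == cb:
            # dedupe mirrored within-chromosome hits; keep ordinal_a < ordinal_b
            seen = set()
            uniq = []
            for h in hits:
                key = tuple(sorted([h.gene_a, h.gene_b]))
                if key in seen:
                    continue
                seen.add(key)
                if h.ordinal_a > h.ordinal_b:
                    h = AnchorHit(
                        h.gene_b, h.chrom_b, h.ordinal_b,
                        h.gene_a, h.chrom_a, h.ordinal_a, h.similarity,
                    )
                uniq.append(h)
            hits = uniq
        remaining = list(hits)
        while len(remaining) >= min_block:
            candidates = []
            for sign, orient in ((1, "same"), (-1, "inverted")):
                score, chain = _chain(remaining, sign, max_gap, gap_penalty)
                candidates.append((score, len(chain), orient, chain))
            score, length, orient, chain = max(candidates, key=lambda c: (c[0], c[1]))
            if length < min_block:
                break
            chain_hits = [remaining[k] for k in chain]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=[(h.gene_a, h.gene_b) for h in chain_hits],
                    score=score,
                    orientation=orient,
                )
            )
            used = set(chain)
            remaining = [h for k, h in enumerate(remaining) if k not in used]
    return blocks


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_duplications(
    family_genes: Sequence[str],
    tandem_groups: Sequence[TandemGroup],
    blocks: Sequence[CollinearBlock],
) -> tuple[dict[str, str], DuplicationSummary]:
    """Label each family gene tandem / segmental / none.

    Tandem takes precedence when a gene appears in both a tandem group and
    a collinear block (logged as a warning).
    """
    family = list(family_genes)
    fam_set = set(family)
    tandem_ids = {gid for grp in tandem_groups for gid in grp.members if gid in fam_set}
    segmental_ids = set()
    for blk in blocks:
        for ga, gb in blk.anchors:
            for gid in (ga, gb):
                if gid in fam_set:
                    segmental_ids.add(gid)

    labels: dict[str, str] = {}
    for gid in family:
        if gid in tandem_ids:
            if gid in segmental_ids:
                logger.warning(
                    "gene %s is in both a tandem group and a collinear block; "
                    "labeled tandem",
                    gid,
                )
            labels[gid] = "tandem"
        elif gid in segmental_ids:
            labels[gid] = "segmental"
        else:
            labels[gid] = "none"

    summary = DuplicationSummary(
        n_total=len(family),
        n_tandem=sum(1 for v in labels.values() if v == "tandem"),
        n_segmental=sum(1 for v in labels.values() if v == "segmental"),
    )
    return labels, summary
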