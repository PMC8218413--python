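"""Nei-Gojobori (1986) Ka/Ks estimation and molecular-clock dating.

Synonymous (S) and nonsynonymous (N) site counts per codon are computed
by classifying the nine single-nucleotide mutants of each codon; mutants
that create a stop codon are excluded and the position's synonymous
fraction renormalized over the remaining changes, so S + N = 3 for every
sense codon. Differences between codon pairs are averaged over all
minimum-mutation pathways that avoid stop codons. Proportions are
corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), applied to both the synonymous and the
nonsynonymous class. Duplication dates follow the molecular clock
T = Ks / (2 lambda) with lambda the synonymous substitution rate per
site per year (default 6.96e-9), reported in million years (Mya).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

CLOCK_RATE = 6.96e-9  # synonymous substitutions / site / year
NEUTRAL_BAND = 0.01

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_CODE = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _CODE.get(codon)


@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each codon position contributes 1 site, split by the fraction of its
    non-stop single-nucleotide changes that are synonymous.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in _STOPS:
                continue
            tot += 1
            if _aa(mutant) == aa0:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averaged over all orderings of the differing positions whose
    intermediate codons are not stops; if every pathway passes through a
    stop, all pathways are used (degenerate fallback).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            if _aa(nxt) is not None and _aa(cur) is not None and _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o, False) for o in permutations(diff)) if r is not None]
    if not results:
        results = [walk(o, True) for o in permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; inf when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class ParalogPair:
    """Ka/Ks decomposition for one pair of coding sequences."""

    gene_a: str
    gene_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int
    n_skipped: int  # codon columns skipped (gap or stop)

    @property
    def ps(self) -> float:
        return self.sd / self.s_sites if self.s_sites else 0.0

    @property
    def pn(self) -> float:
        return self.nd / self.n_sites if self.n_sites else 0.0

    @property
    def ks(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def ka(self) -> float:
        return jukes_cantor(self.pn)

    @property
    def omega(self) -> float:
        """Ka/Ks; nan when undefined (Ks = 0 or saturated)."""
        ks, ka = self.ks, self.ka
        if ks == 0 or not math.isfinite(ks) or not math.isfinite(ka):
            return math.nan
        return ka / ks


def ng_pairwise(
    codon_aln_a: str, codon_aln_b: str, gene_a: str = "a", gene_b: str = "b"
) -> ParalogPair:
    """NG86 site and difference counts over a pairwise codon alignment.

    Only codon columns where both sequences are gap-free sense codons are
    compared; skipped columns are counted. S and N are the means of the
    two sequences' per-codon site totals.
    """
    if len(codon_aln_a) != len(codon_aln_b):
        raise ValueError("codon alignments differ in length")
    if len(codon_aln_a) % 3:
        raise ValueError("codon alignment length not divisible by 3")

    s_a = s_b = sd = nd = 0.0
    n_codons = n_skipped = 0
    for k in range(0, len(codon_aln_a), 3):
        ca = codon_aln_a[k : k + 3].upper()
        cb = codon_aln_b[k : k + 3].upper()
        if (
            "-" in ca or "-" in cb
            or any(x not in _BASES for x in ca + cb)
            or ca in _STOPS or cb in _STOPS
        ):
            n_skipped += 1
            continue
        n_codons += 1
        sa, _ = ng_site_counts(ca)
        sb, _ = ng_site_counts(cb)
        s_a += sa
        s_b += sb
        dsd, dnd = ng_codon_differences(ca, cb)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise ValueError("no comparable codon columns")

    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    return ParalogPair(
        gene_a=gene_a,
        gene_b=gene_b,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        n_codons=n_codons,
        n_skipped=n_skipped,
    )


def selection_call(omega: float, neutral_band: float = NEUTRAL_BAND) -> str:
    """purifying / neutral / positive from Ka/Ks (undetermined if non-finite)."""
    if not math.isfinite(omega):
        return "undetermined"
    if abs(omega - 1.0) <= neutral_band:
        return "neutral"
    return "purifying" if omega < 1.0 else "positive"


def duplication_time(ks: float, clock_rate: float = CLOCK_RATE) -> float:
    """Molecular-clock duplication date T = Ks/(2 lambda), in Mya."""
    if ks < 0:
        raise ValueError("negative Ks")
    if clock_rate <= 0:
        raise ValueError("clock rate must be positive")
    return ks / (2.0 * clock_rate) / 1e6
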