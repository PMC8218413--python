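"""Protein physicochemical characterization.

Average molecular weight, isoelectric point (Henderson-Hasselbalch charge
sum solved by bisection), transmembrane-segment prediction by a
Kyte-Doolittle hydropathy window, and family-level summary statistics.

The TM predictor is a deliberately simple hydropathy stand-in for a
trained membrane-topology HMM: a residue position is membrane-like when
the mean Kyte-Doolittle hydropathy of the centred window (default 19
residues) reaches the cutoff (default 1.6); maximal runs of such
positions, expanded to full windows and merged when overlapping, are the
reported segments. Counts from this rule correlate with, but do not
exactly reproduce, published TMHMM counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .family_model import FamilyTableRow

# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

WATER_MW = 18.01524

#: Average residue masses (Da), monomer minus one water.
RESIDUE_MW = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Ambiguity codes resolved as the mean of their candidate residues.
_AMBIGUOUS = {
    "B": ("N", "D"),
    "Z": ("Q", "E"),
    "J": ("I", "L"),
    "X": tuple(RESIDUE_MW),
    "U": ("C",),  # selenocysteine approximated by cysteine mass
}


def molecular_weight(protein: str) -> float:
    """Average-isotope molecular weight in Daltons (residues + one water)."""
    if not protein:
        raise ValueError("empty protein sequence")
    total = WATER_MW
    for pos, aa in enumerate(protein.upper()):
        if aa in RESIDUE_MW:
            total += RESIDUE_MW[aa]
        elif aa in _AMBIGUOUS:
            warnings.warn(f"ambiguous residue {aa!r} at position {pos + 1}; using mean mass")
            cands = _AMBIGUOUS[aa]
            total += sum(RESIDUE_MW[c] for c in cands) / len(cands)
        else:
            raise ValueError(f"non-amino-acid character {aa!r} at position {pos + 1}")
    return total


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

#: pK sets: (n_term, c_term, side-chain pKs). The default set is the one
#: used by the ExPASy ProtParam tool (Bjellqvist); alternates selectable.
PK_SETS = {
    "bjellqvist": {
        "n_term": 7.5, "c_term": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
    "lehninger": {
        "n_term": 9.69, "c_term": 2.34,
        "D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07,
        "H": 6.0, "K": 10.5, "R": 12.4,
    },
}

_ACIDIC = ("c_term", "D", "E", "C", "Y")
_BASIC = ("n_term", "H", "K", "R")


def net_charge(protein: str, ph, pk_set: str = "bjellqvist"):
    """Net charge at pH (scalar or array) from the Henderson-Hasselbalch sum.

    Ambiguous residues are treated as non-ionizable. Termini always count.
    """
    pks = PK_SETS[pk_set]
    protein = protein.upper()
    counts = {aa: protein.count(aa) for aa in "DECYHKR"}
    counts["n_term"] = 1
    counts["c_term"] = 1
    ph = np.asarray(ph, dtype=float)
    charge = np.zeros_like(ph)
    for grp in _BASIC:
        charge = charge + counts.get(grp, 0) / (1.0 + 10.0 ** (ph - pks[grp]))
    for grp in _ACIDIC:
        charge = charge - counts.get(grp, 0) / (1.0 + 10.0 ** (pks[grp] - ph))
    return charge if charge.ndim else float(charge)


def isoelectric_point(
    protein: str, pk_set: str = "bjellqvist", tol: float = 0.002
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pk_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Transmembrane segments (Kyte-Doolittle stand-in)
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def predict_tm_segments(
    protein: str, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Predicted membrane-spanning segments as 0-based half-open spans.

    A centre position qualifies when its window-mean hydropathy is at
    least ``threshold``; runs of qualifying centres are expanded by half a
    window on each side and overlapping spans merged, so every reported
    segment is at least ``window`` residues long.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 9:
        raise ValueError("window must be >= 9")
    protein = protein.upper()
    n = len(protein)
    if n < window:
        return []
    scores = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    kernel = np.ones(window) / window
    means = np.convolve(scores, kernel, mode="valid")  # centre i+half
    half = window // 2
    qualifying = means >= threshold

    segments: list[tuple[int, int]] = []
    i = 0
    m = len(qualifying)
    while i < m:
        if qualifying[i]:
            j = i
            while j + 1 < m and qualifying[j + 1]:
                j += 1
            start, end = i, j + window  # expand centres to full windows
            if segments and start <= segments[-1][1]:
                segments[-1] = (segments[-1][0], end)
            else:
                segments.append((start, end))
            i = j + 1
        else:
            i += 1
    return segments


@dataclass(frozen=True)
class ProteinProperties:
    """Characterization of one protein (one table row, right half)."""

    length_aa: int
    mw_da: float
    pi: float
    tm_segments: list[tuple[int, int]]

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)

    @property
    def is_basic(self) -> bool:
        return self.pi > 7.0


def characterize(protein: str, pk_set: str = "bjellqvist") -> ProteinProperties:
    return ProteinProperties(
        length_aa=len(protein),
        mw_da=molecular_weight(protein),
        pi=isoelectric_point(protein, pk_set=pk_set),
        tm_segments=predict_tm_segments(protein),
    )


# ---------------------------------------------------------------------------
# Family summary
# ---------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (table-report convention, unlike banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FamilySummary:
    """Family-level ranges and percentages (unrounded)."""

    n_genes: int
    orf_min: int
    orf_max: int
    mw_min_kda: float
    mw_max_kda: float
    pi_min: float
    pi_max: float
    pct_basic: float
    pct_single_exon: float
    pct_tm_8_to_11: float

    def rounded(self, pct_basic_decimals: int = 0, decimals: int = 2) -> dict:
        """Report-style values rounded half-up to printed precision."""
        return {
            "n_genes": self.n_genes,
            "orf_min": self.orf_min,
            "orf_max": self.orf_max,
            "mw_min_kda": round_half_up(self.mw_min_kda, decimals),
            "mw_max_kda": round_half_up(self.mw_max_kda, decimals),
            "pi_min": round_half_up(self.pi_min, decimals),
            "pi_max": round_half_up(self.pi_max, decimals),
            "pct_basic": round_half_up(self.pct_basic, pct_basic_decimals),
            "pct_single_exon": round_half_up(self.pct_single_exon, decimals),
            "pct_tm_8_to_11": round_half_up(self.pct_tm_8_to_11, decimals),
        }


def summarize_family(rows: Sequence[FamilyTableRow]) -> FamilySummary:
    """Ranges and percentages over the whole family table.

    ``pct_basic`` counts pI > 7.0; ``pct_tm_8_to_11`` counts TM counts in
    the closed range [8, 11].
    """
    if not rows:
        raise ValueError("empty row list")
    n = len(rows)
    orfs = [r.orf_bp for r in rows]
    mws = [r.mw_da for r in rows]
    pis = [r.pi for r in rows]
    return FamilySummary(
        n_genes=n,
        orf_min=min(orfs),
        orf_max=max(orfs),
        mw_min_kda=min(mws) / 1000.0,
        mw_max_kda=max(mws) / 1000.0,
        pi_min=min(pis),
        pi_max=max(pis),
        pct_basic=100.0 * sum(r.pi > 7.0 for r in rows) / n,
        pct_single_exon=100.0 * sum(r.exon_count == 1 for r in rows) / n,
        pct_tm_8_to_11=100.0 * sum(8 <= r.tm_count <= 11 for r in rows) / n,
    )
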