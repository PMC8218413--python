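"""Global protein alignment, percent identity/similarity, and
protein-guided codon alignment back-threading.

Alignment is Needleman-Wunsch with affine gaps (BLOSUM62 by default,
gap open 10, extend 0.5; a gap of length L costs open + (L-1)*extend,
end gaps included), delegated to Biopython's PairwiseAligner. Percent
similarity counts columns whose residue pair is identical or scores
positively in the substitution matrix, over the full alignment length
(gap columns count in the denominator). This is the evidence used for
the tandem-duplication criterion (> 50% protein similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .family_model import strip_terminal_stop, translate_cds

DEFAULT_MATRIX = "BLOSUM62"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    matrix_name: str = DEFAULT_MATRIX

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    @property
    def pct_identity(self) -> float:
        n = len(self.aligned_a)
        if n == 0:
            raise ValueError("zero-length alignment")
        ident = sum(a == b and a != "-" for a, b in zip(self.aligned_a, self.aligned_b))
        return 100.0 * ident / n

    @property
    def pct_similarity(self) -> float:
        return percent_similarity(self)


def _aligner(matrix: str = DEFAULT_MATRIX, gap_open: float = GAP_OPEN,
             gap_extend: float = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap costs.

    Among co-optimal alignments the first in Biopython's deterministic
    traceback order is returned, so repeated calls agree exactly.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = aln[0], aln[1]
    return PairwiseAlignment(
        seq_a_id=id_a,
        seq_b_id=id_b,
        aligned_a=str(aligned_a),
        aligned_b=str(aligned_b),
        score=float(aln.score),
        matrix_name=matrix,
    )


def percent_similarity(alignment: PairwiseAlignment) -> float:
    """100 x (identical or positive-scoring columns) / alignment length."""
    n = len(alignment.aligned_a)
    if n == 0:
        raise ValueError("zero-length alignment")
    matrix = substitution_matrices.load(alignment.matrix_name)
    similar = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y or matrix[x, y] > 0:
            similar += 1
    return 100.0 * similar / n


def similarity(a: str, b: str, **kwargs) -> float:
    """Convenience: percent similarity of the optimal global alignment."""
    return percent_similarity(global_align(a, b, **kwargs))


def backthread_codon_alignment(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Thread CDSs through a protein alignment, codon per residue.

    Protein gaps become ``---``. CDS lengths must be 3x the ungapped
    protein lengths after stop stripping, and translations must match.
    """
    cds_a = strip_terminal_stop(cds_a)
    cds_b = strip_terminal_stop(cds_b)
    out = []
    for name, aligned, cds in (("a", aligned_a, cds_a), ("b", aligned_b, cds_b)):
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"sequence {name}: CDS length {len(cds)} != 3 x protein length {len(protein)}"
            )
        trans = translate_cds(cds)
        for pos, (p, t) in enumerate(zip(protein, trans)):
            if p != t and p != "X" and t != "X":
                raise ValueError(
                    f"sequence {name}: translation mismatch at residue {pos + 1} "
                    f"({t!r} from CDS vs {p!r} in alignment)"
                )
        codons = []
        k = 0
        for p in aligned:
            if p == "-":
                codons.append("---")
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out.append("".join(codons))
    return out[0], out[1]
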