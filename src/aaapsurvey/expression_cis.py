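"""Expression-profile processing and promoter cis-element scanning.

Expression matrices are genes x conditions abundance tables (RPKM/FPKM).
The display transform is log10(x + 1); detection calls use the raw scale
(detected at >= 1, highly expressed at >= 10 by default). Genes are
clustered by average-linkage hierarchical clustering on 1 - Pearson
correlation of transformed profiles.

Promoters are the upstream flank of each gene (default 2,000 bp,
strand-aware); cis-elements are exact IUPAC consensus matches reported on
both strands, all overlapping occurrences included.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .family_model import GeneModel, reverse_complement

DETECT_RPKM = 1.0
HIGH_RPKM = 10.0
PROMOTER_LENGTH = 2000

# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValueError(f"duplicate condition ids: {dupes}")
    neg = matrix.lt(0)
    if neg.any().any():
        gene = neg.any(axis=1).idxmax()
        cond = neg.loc[gene].idxmax()
        raise ValueError(f"negative abundance at gene {gene!r}, condition {cond!r}")


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(x + 1) on a nonnegative abundance matrix."""
    validate_matrix(matrix)
    return np.log10(matrix + 1.0)


def expression_calls(
    matrix: pd.DataFrame,
    detect: float = DETECT_RPKM,
    high: float = HIGH_RPKM,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene detection and high-expression calls on the raw scale.

    Returns a per-gene frame (detected_any, detected_all, n_high) plus a
    family-level summary with counts and percentages.
    """
    validate_matrix(matrix)
    detected = matrix.ge(detect)
    high_mask = matrix.ge(high)
    calls = pd.DataFrame(
        {
            "detected_any": detected.any(axis=1),
            "detected_all": detected.all(axis=1),
            "n_high": high_mask.sum(axis=1),
        }
    )
    n = len(calls)
    summary = {
        "n_genes": n,
        "n_detected_any": int(calls.detected_any.sum()),
        "pct_detected_any": 100.0 * calls.detected_any.sum() / n,
        "n_detected_all": int(calls.detected_all.sum()),
        "pct_detected_all": 100.0 * calls.detected_all.sum() / n,
        "n_high_any": int((calls.n_high > 0).sum()),
        "pct_high_any": 100.0 * (calls.n_high > 0).sum() / n,
    }
    return calls, summary


def cluster_genes(
    transformed: pd.DataFrame, k: int = 3
) -> tuple[list[str], pd.Series]:
    """Group genes by expression pattern.

    Average-linkage agglomeration on 1 - Pearson correlation across
    conditions, cut into ``k`` flat groups. Constant-profile genes have no
    defined correlation; they are clustered by a Euclidean fallback on the
    transformed values (with a warning). Returns the dendrogram leaf order
    and a gene -> group-label Series (labels 1..k).
    """
    if len(transformed) < k:
        raise ValueError(f"need at least k={k} genes, got {len(transformed)}")
    values = transformed.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-expression gene(s); "
            "using Euclidean distance fallback"
        )
        dist = pdist(values, metric="euclidean")
    else:
        dist = pdist(values, metric="correlation")
    z = linkage(dist, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    order = [transformed.index[i] for i in leaves_list(z)]
    return order, pd.Series(labels, index=transformed.index, name="group")


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    length: int = PROMOTER_LENGTH,
) -> list[tuple[str, str]]:
    """Strand-aware upstream flanks (``length`` bp) of each gene.

    For minus-strand genes the window downstream in genome coordinates is
    reverse-complemented. Windows truncated at chromosome edges trigger a
    warning.
    """
    out = []
    for g in genes:
        chrom = genome.get(g.chromosome)
        if chrom is None:
            raise ValueError(f"chromosome {g.chromosome!r} missing from genome")
        if g.strand == "+":
            lo = g.start - length
            if lo < 0:
                warnings.warn(f"{g.gene_id}: promoter truncated at chromosome start")
                lo = 0
            seq = chrom[lo : g.start]
        else:
            hi = g.end + length
            if hi > len(chrom):
                warnings.warn(f"{g.gene_id}: promoter truncated at chromosome end")
                hi = len(chrom)
            seq = reverse_complement(chrom[g.end : hi])
        out.append((g.gene_id, seq.upper()))
    return out


# ---------------------------------------------------------------------------
# Cis-element scanning
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    element: str
    matched: str  # sequence on the hit strand (revcomp of the + slice for '-')
    offset: int  # 0-based position of the match on the forward promoter
    strand: str  # '+' | '-'


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        body = "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {pattern!r}") from None
    return re.compile(f"(?=({body}))")  # lookahead: overlapping occurrences


def scan_promoters(
    promoters: Iterable[tuple[str, str]],
    motif_dictionary: Mapping[str, str],
) -> tuple[list[MotifHit], dict[str, int]]:
    """Exact IUPAC matching of each element on both promoter strands.

    Returns all hits plus per-gene total counts over all elements.
    """
    compiled = {
        name: (_iupac_regex(pat), _iupac_regex(reverse_complement(pat)), len(pat))
        for name, pat in motif_dictionary.items()
    }
    hits: list[MotifHit] = []
    counts: dict[str, int] = {}
    for gene_id, seq in promoters:
        seq = seq.upper()
        before = len(hits)
        for name, (fwd, rev, _width) in compiled.items():
            for m in fwd.finditer(seq):
                hits.append(MotifHit(gene_id, name, m.group(1), m.start(), "+"))
            for m in rev.finditer(seq):
                hits.append(
                    MotifHit(
                        gene_id, name, reverse_complement(m.group(1)), m.start(), "-"
                    )
                )
        counts[gene_id] = len(hits) - before
    return hits, counts
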