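"""Core data model and I/O for the gene-family survey.

Holds the domain types shared by every stage (gene models with exon
structure, characterization-table rows, search hits), FASTA/GFF3 readers
and writers, the E-value candidate filter, and the packaged transcriptions
of the published family table (53 genes) and paralog-pair table (7 pairs).

Internal genomic coordinates are 0-based half-open; GFF3 I/O converts at
the boundary (GFF3 itself is 1-based inclusive).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed input files."""


# sha256 of the packaged fixture files; load_* refuse corrupted copies.
_FIXTURE_SHA256 = {
    "table1_caaaap.tsv": None,  # filled below at import from _checksums
    "table3_paralogs.tsv": None,
}

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene's coordinates, exon structure and sequences.

    ``start``/``end`` and exon coordinates are 0-based half-open on the
    forward strand. ``ordinal`` is the 1-based rank of the gene along its
    chromosome by start position (used for tandem-separation counting).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str | None = None
    protein: str | None = None
    ordinal: int | None = None

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: start/end out of order")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if self.cds is not None:
            cds = strip_terminal_stop(self.cds)
            if len(cds) % 3:
                raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
            if self.protein is not None and translate_cds(self.cds) != self.protein:
                raise ValueError(f"{self.gene_id}: CDS does not translate to protein")


@dataclass(frozen=True)
class FamilyTableRow:
    """One row of the family characterization table."""

    gene_id: str
    locus_id: str
    chromosome: str
    orf_bp: int
    exon_count: int
    protein_length_aa: int
    mw_da: float
    pi: float
    tm_count: int
    subfamily: str | None = None

    @property
    def orf_consistent(self) -> bool:
        """ORF length equals 3 x (protein length + stop codon)."""
        return self.orf_bp == 3 * (self.protein_length_aa + 1)

    def __post_init__(self):
        if not 0 < self.pi < 14:
            raise ValueError(f"{self.gene_id}: pI {self.pi} outside (0,14)")
        if self.tm_count < 0:
            raise ValueError(f"{self.gene_id}: negative TM count")


@dataclass(frozen=True)
class SearchHit:
    """A candidate-search hit (HMM domain scan or homology search)."""

    gene_id: str
    source: str  # "hmm" | "homology"
    evalue: float
    domain_start: int | None = None  # 1-based protein coordinates
    domain_end: int | None = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"{self.gene_id}: negative E-value {self.evalue}")
        if self.source not in ("hmm", "homology"):
            raise ValueError(f"unknown hit source {self.source!r}")
        if (
            self.domain_start is not None
            and self.domain_end is not None
            and self.domain_start > self.domain_end
        ):
            raise ValueError(f"{self.gene_id}: domain_start > domain_end")


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}


def strip_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code), stripping one trailing stop codon."""
    return str(Seq(strip_terminal_stop(cds)).translate(table=1))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` in file order.

    The id is the first whitespace-delimited token of the header. Empty
    files and duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3 reading
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    genome: Mapping[str, str] | str | Path | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS with ID/Parent).

    One :class:`GeneModel` per gene; when a gene has several mRNAs the one
    with the longest total CDS is the representative. Ordinals are assigned
    by start position within each chromosome, over all genes in the file.
    If ``genome`` (mapping or FASTA path) is given, CDS sequences are
    extracted strand-aware and translated.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features(featuretype=("CDS", "exon")):
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise FormatError(
                    f"{feat.featuretype} parent {parent_id!r} not found in {path}"
                )

    if genome is not None and not isinstance(genome, Mapping):
        genome = dict(read_fasta(genome))

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        containers = mrnas if mrnas else [gene]

        best = None
        for tx in containers:
            cds_feats = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
            exon_feats = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
            span = sum(f.end - f.start + 1 for f in cds_feats) or sum(
                f.end - f.start + 1 for f in exon_feats
            )
            if best is None or span > best[0]:
                best = (span, tx, exon_feats, cds_feats)
        _, tx, exon_feats, cds_feats = best

        strands = {f.strand for f in exon_feats + cds_feats} | {gene.strand}
        strands.discard(".")
        if len(strands) > 1:
            raise FormatError(f"mixed-strand exons in gene {gene.id}")
        strand = strands.pop() if strands else "+"

        exons = [(f.start - 1, f.end) for f in exon_feats]
        if not exons and cds_feats:
            exons = [(f.start - 1, f.end) for f in cds_feats]

        cds_seq = protein = None
        if genome is not None and cds_feats:
            chrom_seq = genome.get(gene.seqid)
            if chrom_seq is None:
                raise FormatError(f"chromosome {gene.seqid!r} missing from genome")
            parts = [chrom_seq[f.start - 1 : f.end] for f in cds_feats]
            cds_seq = "".join(parts).upper()
            if strand == "-":
                cds_seq = reverse_complement(cds_seq)
            protein = translate_cds(cds_seq)

        gm = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=strand,
            start=gene.start - 1,
            end=gene.end,
            exons=exons,
            cds=cds_seq,
            protein=protein,
        )
        gm.validate()
        genes.append(gm)

    assign_ordinals(genes)
    return genes


def assign_ordinals(genes: Sequence[GeneModel]) -> None:
    """Assign 1-based per-chromosome ordinals by start position, in place."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(members, start=1):
            g.ordinal = rank


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

HMM_EVALUE_CUTOFF = 1e-2
HOMOLOGY_EVALUE_CUTOFF = 1e-10


def filter_candidates(
    hits: Iterable[SearchHit],
    hmm_cutoff: float = HMM_EVALUE_CUTOFF,
    homology_cutoff: float = HOMOLOGY_EVALUE_CUTOFF,
) -> set[str]:
    """Union of gene ids passing their source-specific E-value cutoff."""
    if hmm_cutoff <= 0 or homology_cutoff <= 0:
        raise ValueError("E-value cutoffs must be positive")
    cutoffs = {"hmm": hmm_cutoff, "homology": homology_cutoff}
    kept: set[str] = set()
    for hit in hits:
        if hit.evalue < 0:
            raise ValueError(f"negative E-value for {hit.gene_id}")
        if hit.evalue <= cutoffs[hit.source]:
            kept.add(hit.gene_id)
    return kept


def parse_domtblout(path: str | Path) -> list[SearchHit]:
    """Parse hmmscan ``--domtblout`` rows into hmm-source hits.

    Uses the per-domain independent E-value (column 13), not the
    full-sequence E-value; configurable by post-filtering on the returned
    hits if the other convention is wanted.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 23:
                raise FormatError(f"short domtblout line in {path}: {line[:50]!r}")
            hits.append(
                SearchHit(
                    gene_id=f[3],
                    source="hmm",
                    evalue=float(f[12]),
                    domain_start=int(f[17]),
                    domain_end=int(f[18]),
                )
            )
    return hits


def parse_homology_table(path: str | Path) -> list[SearchHit]:
    """Parse a tabular homology search (qseqid sseqid evalue bitscore ...).

    The subject (column 2) is the candidate gene; lines starting with '#'
    are skipped.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise FormatError(f"homology table needs >= 4 columns in {path}")
            hits.append(SearchHit(gene_id=f[1], source="homology", evalue=float(f[2])))
    return hits


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(resources.files("aaapsurvey").joinpath("data", name))


def _check_fixture(name: str) -> Path:
    path = _fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if expected is not None and digest != expected:
        raise FormatError(f"packaged fixture {name} is corrupted (sha256 {digest})")
    return path


def load_table1_fixture() -> list[FamilyTableRow]:
    """The 53-gene family characterization table, as printed."""
    path = _check_fixture("table1_caaaap.tsv")
    df = pd.read_csv(path, sep="\t")
    return [
        FamilyTableRow(
            gene_id=r.gene_id,
            locus_id=r.locus_id,
            chromosome=r.chromosome,
            orf_bp=int(r.orf_bp),
            exon_count=int(r.exon_count),
            protein_length_aa=int(r.protein_length_aa),
            mw_da=float(r.mw_da),
            pi=float(r.pi),
            tm_count=int(r.tm_count),
            subfamily=r.subfamily,
        )
        for r in df.itertuples()
    ]


def load_table3_fixture() -> pd.DataFrame:
    """The 7 paralog pairs with printed S/N sites, Ka, Ks, type and time."""
    path = _check_fixture("table3_paralogs.tsv")
    return pd.read_csv(path, sep="\t")


def load_cis_element_dictionary() -> dict[str, str]:
    """Consensus IUPAC patterns for the named stress-responsive elements."""
    path = _fixture_path("cis_elements.tsv")
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["name"], df["iupac"]))


_FIXTURE_SHA256["table1_caaaap.tsv"] = "816bc49c698edf75d4eccb7f4480a875004f0717575d11013a3a56a0630af3bf"
_FIXTURE_SHA256["table3_paralogs.tsv"] = "87228e8beaa07c436d9688fc318681a964ea39c17f4a55ac25d1b3e5d878de7e"
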