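"""I/O, data-model invariants, and packaged-table fixtures."""

import textwrap

import pytest

from aaapsurvey import (
    FamilyTableRow,
    SearchHit,
    filter_candidates,
    read_fasta,
    read_gff3,
    translate_cds,
    write_fasta,
)
from aaapsurvey.family_model import FormatError, assign_ordinals, strip_terminal_stop
from conftest import random_protein


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">g1\nACGT\n")
        assert read_fasta(p) == [("g1", "ACGT")]

    def test_wrapped_equals_unwrapped(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        flat = tmp_path / "flat.fa"
        flat.write_text(f">g1\n{seq}\n")
        wrapped = tmp_path / "wrapped.fa"
        wrapped.write_text(">g1\n" + "\n".join(textwrap.wrap(seq, 80)) + "\n")
        assert read_fasta(flat) == read_fasta(wrapped)

    def test_duplicate_id_is_error(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(FormatError, match="a"):
            read_fasta(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_round_trip(self, tmp_path, rng):
        records = [
            (f"g{i}", random_protein(rng, int(rng.integers(5, 150))))
            for i in range(8)
        ]
        p = tmp_path / "rt.fa"
        write_fasta(records, p)
        assert read_fasta(p) == records


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3\n"


def _gff_gene(chrom, gid, start, end, strand, exons):
    lines = [
        f"{chrom}\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}",
        f"{chrom}\ttest\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gid}.t;Parent={gid}",
    ]
    for i, (s, e) in enumerate(exons, 1):
        lines.append(
            f"{chrom}\ttest\texon\t{s}\t{e}\t.\t{strand}\t.\tID={gid}.e{i};Parent={gid}.t"
        )
        lines.append(
            f"{chrom}\ttest\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID={gid}.c{i};Parent={gid}.t"
        )
    return "\n".join(lines) + "\n"


class TestGff3:
    def test_exon_count_and_ordinals(self, tmp_path):
        exons7 = [(i * 100 + 1, i * 100 + 50) for i in range(7)]
        gff = GFF_HEADER
        gff += _gff_gene("chr1", "gA", 1, 650, "+", exons7)
        gff += _gff_gene("chr1", "gB", 1000, 1100, "+", [(1000, 1100)])
        (tmp_path / "t.gff3").write_text(gff)
        genes = {g.gene_id: g for g in read_gff3(tmp_path / "t.gff3")}
        assert genes["gA"].exon_count == 7
        assert genes["gB"].exon_count == 1
        assert genes["gA"].ordinal == 1 and genes["gB"].ordinal == 2

    def test_orphan_cds_parent_is_error(self, tmp_path):
        gff = GFF_HEADER + "chr1\tt\tCDS\t1\t30\t.\t+\t0\tID=c1;Parent=ghost\n"
        (tmp_path / "bad.gff3").write_text(gff)
        with pytest.raises(FormatError, match="ghost"):
            read_gff3(tmp_path / "bad.gff3")

    def test_mixed_strand_exons_are_error(self, tmp_path):
        gff = GFF_HEADER
        gff += "chr1\tt\tgene\t1\t200\t.\t+\t.\tID=g1\n"
        gff += "chr1\tt\tmRNA\t1\t200\t.\t+\t.\tID=g1.t;Parent=g1\n"
        gff += "chr1\tt\texon\t1\t90\t.\t+\t.\tID=e1;Parent=g1.t\n"
        gff += "chr1\tt\texon\t100\t200\t.\t-\t.\tID=e2;Parent=g1.t\n"
        (tmp_path / "mix.gff3").write_text(gff)
        with pytest.raises(FormatError, match="mixed-strand"):
            read_gff3(tmp_path / "mix.gff3")

    def test_cds_extraction_translates(self, tmp_path):
        # ATG AAA TGC TAA on the minus strand
        cds = "ATGAAATGCTAA"
        genome = {"chr1": "GG" + str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(cds).reverse_complement()) + "AA"}
        gff = GFF_HEADER + _gff_gene("chr1", "g1", 3, 14, "-", [(3, 14)])
        (tmp_path / "m.gff3").write_text(gff)
        (genes,) = read_gff3(tmp_path / "m.gff3", genome=genome)
        assert genes.cds == cds
        assert genes.protein == "MKC"

    def test_longest_cds_is_representative(self, tmp_path):
        gff = GFF_HEADER
        gff += "chr1\tt\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        gff += "chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        gff += "chr1\tt\texon\t1\t90\t.\t+\t.\tID=a;Parent=g1.t1\n"
        gff += "chr1\tt\tCDS\t1\t90\t.\t+\t0\tID=ac;Parent=g1.t1\n"
        gff += "chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=g1.t2;Parent=g1\n"
        gff += "chr1\tt\texon\t1\t150\t.\t+\t.\tID=b;Parent=g1.t2\n"
        gff += "chr1\tt\tCDS\t1\t150\t.\t+\t0\tID=bc;Parent=g1.t2\n"
        gff += "chr1\tt\texon\t200\t250\t.\t+\t.\tID=b2;Parent=g1.t2\n"
        gff += "chr1\tt\tCDS\t200\t250\t.\t+\t0\tID=b2c;Parent=g1.t2\n"
        (tmp_path / "iso.gff3").write_text(gff)
        (gene,) = read_gff3(tmp_path / "iso.gff3")
        assert gene.exon_count == 2  # the two-exon isoform has the longer CDS


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------


class TestFilterCandidates:
    def test_source_specific_cutoffs_and_dedup(self):
        hits = [
            SearchHit("kept_hmm", "hmm", 1e-3),
            SearchHit("lost_homology", "homology", 1e-9),
            SearchHit("both", "hmm", 1e-5),
            SearchHit("both", "homology", 1e-12),
        ]
        kept = filter_candidates(hits)
        assert kept == {"kept_hmm", "both"}

    def test_bad_cutoff_is_error(self):
        with pytest.raises(ValueError):
            filter_candidates([], hmm_cutoff=0)


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def test_translation_strips_single_stop():
    assert strip_terminal_stop("ATGTGA") == "ATG"
    assert translate_cds("ATGAAATGCTAA") == "MKC"


def test_ordinals_sort_by_start():
    from aaapsurvey import GeneModel

    genes = [
        GeneModel("b", "chr1", "+", 500, 600),
        GeneModel("a", "chr1", "+", 100, 200),
        GeneModel("c", "chr2", "+", 50, 80),
    ]
    assign_ordinals(genes)
    ranks = {g.gene_id: g.ordinal for g in genes}
    assert ranks == {"a": 1, "b": 2, "c": 1}


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


class TestFixtures:
    def test_family_table_has_53_genes(self, table1):
        assert len(table1) == 53
        assert len({r.gene_id for r in table1}) == 53

    def test_family_table_extrema_match_print(self, table1):
        orfs = [r.orf_bp for r in table1]
        pis = [r.pi for r in table1]
        assert (min(orfs), max(orfs)) == (669, 2532)
        assert (min(pis), max(pis)) == (4.27, 10.06)

    def test_orf_lengths_include_stop_codon(self, table1):
        # ORF = 3 x (protein length + 1) for every printed row
        assert all(r.orf_consistent for r in table1)

    def test_paralog_table_rows(self, table3):
        assert len(table3) == 7
        row = table3[(table3.gene_a == "CaANT1") & (table3.gene_b == "CaANT4")]
        assert float(row.ks.iloc[0]) == 0.82
        assert row.dup_type.iloc[0] == "segmental"

    def test_row_validation_rejects_bad_pi(self):
        with pytest.raises(ValueError):
            FamilyTableRow("x", "x", "chr1", 300, 1, 99, 1e4, 15.0, 3)
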