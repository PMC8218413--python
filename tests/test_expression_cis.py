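"""Expression transforms/calls/clustering and promoter motif scanning."""

import numpy as np
import pandas as pd
import pytest

from aaapsurvey import (
    GeneModel,
    cluster_genes,
    expression_calls,
    extract_promoters,
    log_transform,
    scan_promoters,
)
from aaapsurvey.expression_cis import _iupac_regex
from aaapsurvey.family_model import reverse_complement
from aaapsurvey.synthetic_data import generate_expression, generate_promoters


def _matrix(values, genes=None, conds=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    conds = conds or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=conds)


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_pseudocount_values(self, raw, expected):
        out = log_transform(_matrix([[raw]]))
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_negative_value_names_cell(self):
        with pytest.raises(ValueError, match="g1.*c0|c0.*g1"):
            log_transform(_matrix([[1.0], [-2.0]], genes=["g0", "g1"]))

    def test_strictly_monotone(self, rng):
        x = np.sort(rng.uniform(0, 100, size=50))
        out = log_transform(_matrix(x[None, :])).to_numpy().ravel()
        assert (np.diff(out) >= 0).all()


class TestExpressionCalls:
    def test_below_threshold_not_detected(self):
        calls, _ = expression_calls(_matrix([[0.9, 0.5]]))
        assert not calls.detected_any.iloc[0]

    def test_threshold_is_inclusive(self):
        calls, _ = expression_calls(_matrix([[1.0, 0.0]]))
        assert calls.detected_any.iloc[0]
        assert not calls.detected_all.iloc[0]

    def test_detected_all_implies_any(self, rng):
        m = _matrix(rng.uniform(0, 20, size=(30, 5)))
        calls, _ = expression_calls(m)
        assert (calls.detected_any | ~calls.detected_all).all()

    def test_summary_percentages(self):
        m = _matrix([[5.0, 5.0], [0.2, 0.1], [12.0, 0.0], [1.0, 1.0]])
        _, summary = expression_calls(m)
        assert summary["n_detected_any"] == 3
        assert summary["pct_detected_any"] == pytest.approx(75.0)
        assert summary["n_detected_all"] == 2

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            expression_calls(pd.DataFrame())


class TestClustering:
    def test_recovers_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        arch = [[2.0, 0.1, 0.1], [0.1, 2.0, 0.1], [0.1, 0.1, 2.0]]
        matrix, truth = generate_expression(30, ["a", "b", "c"], arch, 0.1, seed=4)
        _, labels = cluster_genes(log_transform(matrix), k=3)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        m = _matrix(np.eye(4) * 5 + 0.1)
        _, labels = cluster_genes(log_transform(m), k=4)
        assert labels.nunique() == 4

    def test_condition_permutation_invariance(self):
        arch = [[2.0, 0.1, 0.4, 1.0], [0.1, 2.0, 1.0, 0.2]]
        matrix, _ = generate_expression(12, list("abcd"), arch, 0.05, seed=9)
        t = log_transform(matrix)
        _, l1 = cluster_genes(t, k=2)
        _, l2 = cluster_genes(t[["c", "a", "d", "b"]], k=2)
        assert (l1 == l2).all()

    def test_constant_gene_falls_back_with_warning(self):
        m = _matrix(
            [[5.0, 1.0, 0.2], [4.0, 0.8, 0.1], [1.0, 1.0, 1.0], [0.1, 2.0, 8.0]]
        )
        with pytest.warns(UserWarning, match="constant"):
            _, labels = cluster_genes(log_transform(m), k=2)
        assert len(labels) == 4


class TestPromoterExtraction:
    def _gene(self, gid, strand, start, end):
        return GeneModel(gid, "chr1", strand, start, end, exons=[(start, end)])

    def test_plus_strand_window(self):
        genome = {"chr1": "A" * 3000 + "C" * 2000 + "G" * 100}
        (rec,) = extract_promoters(genome, [self._gene("g", "+", 5000, 5100)])
        assert rec == ("g", "C" * 2000)

    def test_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "A" * 100 + "GGGG" + "ACGT" * 25}
        (rec,) = extract_promoters(
            genome, [self._gene("g", "-", 0, 104)], length=100
        )
        assert rec[1] == reverse_complement("ACGT" * 25)

    def test_truncation_warns(self):
        genome = {"chr1": "ACGT" * 100}
        with pytest.warns(UserWarning, match="truncated"):
            (rec,) = extract_promoters(genome, [self._gene("g", "+", 100, 200)])
        assert len(rec[1]) == 100

    def test_missing_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chr1"):
            extract_promoters({}, [self._gene("g", "+", 100, 200)])


class TestMotifScan:
    def test_planted_motif_and_its_reverse_complement(self):
        promoters = [("p1", "AAAAATGACGAAAAA")]
        motifs = {"TGACG-motif": "TGACG", "CGTCA-motif": "CGTCA"}
        hits, counts = scan_promoters(promoters, motifs)
        by_elem = {(h.element, h.strand): h for h in hits}
        assert ("TGACG-motif", "+") in by_elem
        assert ("CGTCA-motif", "-") in by_elem
        assert by_elem[("TGACG-motif", "+")].offset == 5
        assert counts["p1"] == 2

    def test_poly_a_promoter_has_no_hits(self):
        hits, counts = scan_promoters([("p", "A" * 500)], {"MBS": "CAACTG"})
        assert hits == [] and counts["p"] == 0

    def test_overlapping_occurrences_reported(self):
        hits, _ = scan_promoters([("p", "ACGTACGTACGT")], {"m": "ACGTACGT"})
        offsets = sorted(h.offset for h in hits if h.strand == "+")
        assert offsets == [0, 4]

    def test_iupac_degeneracy(self):
        hits, _ = scan_promoters([("p", "TTCAACTGTT")], {"m": "CAAYTG"})
        assert any(h.strand == "+" and h.matched == "CAACTG" for h in hits)

    def test_invalid_iupac_letter_is_error(self):
        with pytest.raises(ValueError, match="'O'"):
            _iupac_regex("ACGO")

    def test_planted_promoters_full_recall(self):
        plan = {
            0: [("ABRE", "ACGTG"), ("MBS", "CAACTG")],
            2: [("GARE-motif", "TCTGTTG")],
        }
        records, planted = generate_promoters(3, 400, plan, seed=21)
        motifs = {"ABRE": "ACGTG", "MBS": "CAACTG", "GARE-motif": "TCTGTTG"}
        hits, counts = scan_promoters(records, motifs)
        found = {(h.gene_id, h.element, h.offset) for h in hits if h.strand == "+"}
        for pid, name, offset, matched in planted:
            assert (pid, name, offset) in found
        # every reported hit re-verified against the raw sequence
        seqs = dict(records)
        for h in hits:
            window = seqs[h.gene_id][h.offset : h.offset + len(h.matched)]
            expected = h.matched if h.strand == "+" else reverse_complement(h.matched)
            assert window == expected
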