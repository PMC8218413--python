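"""End-to-end survey pipeline and report writers.

Orchestrates candidate filtering, protein characterization, phylogeny,
duplication detection, Ka/Ks with clock dating, expression profiling and
promoter scanning over one config, writing TSV/newick reports and a run
manifest. Reruns with identical inputs, config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .duplication import (
    AnchorHit,
    classify_duplications,
    find_collinear_blocks,
    find_tandem,
)
from .expression_cis import (
    cluster_genes,
    expression_calls,
    extract_promoters,
    log_transform,
    scan_promoters,
)
from .family_model import (
    filter_candidates,
    load_cis_element_dictionary,
    parse_domtblout,
    parse_homology_table,
    read_fasta,
    read_gff3,
)
from .pairwise import backthread_codon_alignment, global_align, percent_similarity
from .phylogeny import bootstrap_support
from .protein_props import characterize, round_half_up, summarize_family
from .selection import CLOCK_RATE, duplication_time, ng_pairwise, selection_call
from .family_model import FamilyTableRow

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one survey run."""

    gff: str
    cds_fasta: str
    protein_fasta: str
    outdir: str
    genome_fasta: str | None = None
    protein_msa: str | None = None
    expression_tsv: str | None = None
    hmm_hits: str | None = None
    homology_hits: str | None = None
    family_ids: str | None = None

    hmm_evalue: float = 1e-2
    homology_evalue: float = 1e-10
    tandem_max_sep: int = 5
    tandem_min_sim: float = 50.0
    min_block: int = 5
    max_gap: int = 25
    anchor_min_sim: float = 50.0
    detect_rpkm: float = 1.0
    high_rpkm: float = 10.0
    expression_groups: int = 3
    clock_rate: float = CLOCK_RATE
    promoter_length: int = 2000
    site_coverage: float = 0.95
    bootstrap_reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "hmm_evalue", "homology_evalue", "tandem_min_sim", "anchor_min_sim",
            "detect_rpkm", "high_rpkm", "clock_rate", "promoter_length",
            "site_coverage", "bootstrap_reps", "min_block",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config {name} must be positive")
        for name in ("gff", "cds_fasta", "protein_fasta"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"input file for {name!r} not found: {p}")
        for name in (
            "genome_fasta", "protein_msa", "expression_tsv",
            "hmm_hits", "homology_hits", "family_ids",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file for {name!r} not found: {p}")


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

_TABLE1_COLUMNS = [
    "gene_id", "locus_id", "chromosome", "orf_bp", "exon_count",
    "protein_length_aa", "mw_da", "pi", "tm_count",
]
_TABLE3_COLUMNS = [
    "gene_a", "gene_b", "s_sites", "n_sites", "ka", "ks", "ka_ks",
    "selection", "dup_type", "time_mya",
]


def write_table1_report(rows: list[dict], path: str | Path) -> None:
    """Characterization table TSV, two-decimal numerics, sorted by gene id."""
    df = pd.DataFrame(rows, columns=_TABLE1_COLUMNS)
    df = df.sort_values("gene_id", kind="mergesort")
    for col in ("mw_da", "pi"):
        df[col] = df[col].map(lambda x: f"{round_half_up(float(x), 2):.2f}")
    df.to_csv(path, sep="\t", index=False)


def write_table3_report(rows: list[dict], path: str | Path) -> None:
    """Paralog-pair TSV (sites, rates, selection, type, time), two decimals."""
    df = pd.DataFrame(rows, columns=_TABLE3_COLUMNS)
    df = df.sort_values(["gene_a", "gene_b"], kind="mergesort")
    for col in ("s_sites", "n_sites", "ka", "ks", "ka_ks", "time_mya"):
        df[col] = df[col].map(
            lambda x: "NA" if pd.isna(x) else f"{round_half_up(float(x), 2):.2f}"
        )
    df.to_csv(path, sep="\t", index=False)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full survey; returns a result bundle of key objects.

    Any stage failure writes a FAILED marker naming the stage (partial
    outputs are retained) and re-raises as :class:`StageError`.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "read_inputs"
        genome = dict(read_fasta(config.genome_fasta)) if config.genome_fasta else None
        genes = read_gff3(config.gff, genome=genome)
        cds = dict(read_fasta(config.cds_fasta))
        proteins = dict(read_fasta(config.protein_fasta))
        by_id = {g.gene_id: g for g in genes}
        for gid, g in by_id.items():
            if g.cds is None and gid in cds:
                g.cds = cds[gid]
            if g.protein is None and gid in proteins:
                g.protein = proteins[gid]

        stage = "candidates"
        if config.hmm_hits or config.homology_hits:
            hits = []
            if config.hmm_hits:
                hits += parse_domtblout(config.hmm_hits)
            if config.homology_hits:
                hits += parse_homology_table(config.homology_hits)
            family = sorted(
                filter_candidates(hits, config.hmm_evalue, config.homology_evalue)
                & set(by_id)
            )
        elif config.family_ids:
            family = sorted(
                line.strip()
                for line in Path(config.family_ids).read_text().splitlines()
                if line.strip()
            )
        else:
            family = sorted(gid for gid in by_id if by_id[gid].protein)
        results["family"] = family
        logger.info("family members: %d of %d genes", len(family), len(by_id))

        # ---- characterization -------------------------------------------
        stage = "protein_props"
        t1_rows = []
        fixture_rows = []
        for gid in family:
            g = by_id[gid]
            props = characterize(proteins[gid])
            t1_rows.append(
                {
                    "gene_id": gid,
                    "locus_id": gid,
                    "chromosome": g.chromosome,
                    "orf_bp": len(g.cds) if g.cds else 3 * (props.length_aa + 1),
                    "exon_count": g.exon_count,
                    "protein_length_aa": props.length_aa,
                    "mw_da": props.mw_da,
                    "pi": props.pi,
                    "tm_count": props.tm_count,
                }
            )
            fixture_rows.append(
                FamilyTableRow(
                    gene_id=gid, locus_id=gid, chromosome=g.chromosome,
                    orf_bp=t1_rows[-1]["orf_bp"], exon_count=g.exon_count,
                    protein_length_aa=props.length_aa, mw_da=props.mw_da,
                    pi=props.pi, tm_count=props.tm_count,
                )
            )
        write_table1_report(t1_rows, outdir / "characterization.tsv")
        results["summary"] = summarize_family(fixture_rows)

        # ---- phylogeny ---------------------------------------------------
        stage = "phylogeny"
        if config.protein_msa:
            msa = read_fasta(config.protein_msa)
        else:
            fam_prot = [(gid, proteins[gid]) for gid in family]
            lengths = {len(s) for _, s in fam_prot}
            if len(lengths) != 1:
                raise ValueError(
                    "family proteins are not equal-length; supply protein_msa "
                    "with a multiple alignment"
                )
            msa = fam_prot
        if len(msa) >= 3:
            tree = bootstrap_support(
                msa,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
                site_coverage=config.site_coverage,
            )
            (outdir / "family_tree.nwk").write_text(tree.newick() + "\n")
            results["tree"] = tree

        # ---- duplications ------------------------------------------------
        stage = "duplication"
        sim_cache: dict[tuple[str, str], float] = {}

        def sim(a: str, b: str) -> float:
            key = (a, b) if a <= b else (b, a)
            if key not in sim_cache:
                aln = global_align(proteins[key[0]], proteins[key[1]])
                sim_cache[key] = percent_similarity(aln)
            return sim_cache[key]

        fam_models = [by_id[gid] for gid in family]
        tandem = find_tandem(
            fam_models, sim, config.tandem_max_sep, config.tandem_min_sim
        )
        all_ids = sorted(by_id)
        anchors = []
        for i, a in enumerate(all_ids):
            for b in all_ids[i + 1 :]:
                ga, gb = by_id[a], by_id[b]
                if ga.protein is None or gb.protein is None:
                    continue
                s = sim(a, b)
                if s >= config.anchor_min_sim:
                    anchors.append(
                        AnchorHit(
                            a, ga.chromosome, ga.ordinal,
                            b, gb.chromosome, gb.ordinal, s,
                        )
                    )
        blocks = find_collinear_blocks(anchors, config.min_block, config.max_gap)
        labels, dup_summary = classify_duplications(family, tandem, blocks)
        results.update(tandem=tandem, blocks=blocks, dup_labels=labels,
                       dup_summary=dup_summary)

        pd.DataFrame(
            [
                {"group": i + 1, "chromosome": grp.chromosome, "gene_id": gid}
                for i, grp in enumerate(tandem)
                for gid in grp.members
            ],
            columns=["group", "chromosome", "gene_id"],
        ).to_csv(outdir / "tandem_groups.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "block": i + 1, "chrom_a": blk.chrom_a, "chrom_b": blk.chrom_b,
                    "orientation": blk.orientation, "gene_a": ga, "gene_b": gb,
                }
                for i, blk in enumerate(blocks)
                for ga, gb in blk.anchors
            ],
            columns=["block", "chrom_a", "chrom_b", "orientation", "gene_a", "gene_b"],
        ).to_csv(outdir / "collinear_blocks.tsv", sep="\t", index=False)

        # ---- Ka/Ks -------------------------------------------------------
        stage = "selection"
        pairs: list[tuple[str, str, str]] = []
        for grp in tandem:
            for i in range(len(grp.members)):
                for j in range(i + 1, len(grp.members)):
                    pairs.append((grp.members[i], grp.members[j], "tandem"))
        fam_set = set(family)
        for blk in blocks:
            for ga, gb in blk.anchors:
                if ga in fam_set and gb in fam_set:
                    pairs.append((ga, gb, "segmental"))
        t3_rows = []
        for ga, gb, dup_type in sorted(set(pairs)):
            aln = global_align(proteins[ga], proteins[gb], id_a=ga, id_b=gb)
            cod_a, cod_b = backthread_codon_alignment(
                aln.aligned_a, aln.aligned_b, by_id[ga].cds, by_id[gb].cds
            )
            pair = ng_pairwise(cod_a, cod_b, ga, gb)
            t3_rows.append(
                {
                    "gene_a": ga, "gene_b": gb,
                    "s_sites": pair.s_sites, "n_sites": pair.n_sites,
                    "ka": pair.ka, "ks": pair.ks, "ka_ks": pair.omega,
                    "selection": selection_call(pair.omega),
                    "dup_type": dup_type,
                    "time_mya": duplication_time(pair.ks, config.clock_rate),
                }
            )
        write_table3_report(t3_rows, outdir / "paralog_pairs.tsv")
        results["paralog_pairs"] = t3_rows

        # ---- expression --------------------------------------------------
        if config.expression_tsv:
            stage = "expression"
            matrix = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
            transformed = log_transform(matrix)
            transformed.round(4).to_csv(outdir / "expression_log10.tsv", sep="\t")
            calls, summary = expression_calls(
                matrix, config.detect_rpkm, config.high_rpkm
            )
            calls.to_csv(outdir / "expression_calls.tsv", sep="\t")
            if len(matrix) >= config.expression_groups:
                order, groups = cluster_genes(transformed, config.expression_groups)
                groups.loc[order].to_csv(outdir / "expression_groups.tsv", sep="\t")
                results["expression_groups"] = groups
            results["expression_summary"] = summary

        # ---- cis-elements ------------------------------------------------
        if genome is not None:
            stage = "cis_elements"
            promoters = extract_promoters(
                genome, fam_models, config.promoter_length
            )
            hits, counts = scan_promoters(promoters, load_cis_element_dictionary())
            pd.DataFrame(
                [dataclasses.asdict(h) for h in hits],
                columns=["gene_id", "element", "matched", "offset", "strand"],
            ).to_csv(outdir / "cis_hits.tsv", sep="\t", index=False)
            pd.Series(counts, name="n_elements").rename_axis("gene_id").to_csv(
                outdir / "cis_counts.tsv", sep="\t"
            )
            results["cis_counts"] = counts

        # ---- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "aaapsurvey",
            "version": __version__,
            "seed": config.seed,
            "config": {
                f.name: getattr(config, f.name)
                for f in dataclasses.fields(config)
                if f.name != "outdir"
            },
            "input_sha256": {
                name: _sha256(getattr(config, name))
                for name in (
                    "gff", "cds_fasta", "protein_fasta", "genome_fasta",
                    "protein_msa", "expression_tsv",
                )
                if getattr(config, name)
            },
        }
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True)
        )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
    return results
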