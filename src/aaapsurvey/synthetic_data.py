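"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are pure functions of (specification, seed): codon-sequence
pairs diverged to a target synonymous rate under a chosen dN/dS, family
genomes laid out on chromosomes with planted tandem arrays and segmental
blocks, log-normal expression matrices with group archetypes, and random
promoters with planted cis-element motifs.

The codon simulator uses acceptance thinning rather than a full
rate-matrix CTMC: single-nucleotide proposals (uniform site, uniform
alternative base) are accepted always when synonymous and with
probability omega when nonsynonymous (for omega > 1 the rule is
reciprocal: nonsynonymous always, synonymous with probability 1/omega);
proposals creating stops are rejected. A lineage stops once its accepted
synonymous substitutions per synonymous site reach target_ks / 2. There
is no transition/transversion bias and no indel process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .family_model import (
    GeneModel,
    STOP_CODONS,
    assign_ordinals,
    reverse_complement,
    translate_cds,
    write_fasta,
)
from .selection import ng_site_counts

_BASES = "ACGT"

_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


def _check_ancestor(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("ancestor CDS length not divisible by 3")
    for k in range(0, len(cds), 3):
        if cds[k : k + 3] in STOP_CODONS:
            raise ValueError(f"ancestor has internal stop at nt {k + 1}")
    return cds


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS with uniform codon usage."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


# ---------------------------------------------------------------------------
# Codon divergence simulator
# ---------------------------------------------------------------------------


def _synonymous_sites(cds: str) -> float:
    return sum(ng_site_counts(cds[k : k + 3])[0] for k in range(0, len(cds), 3))


_CODON_AA = {c: translate_cds(c) for c in _SENSE_CODONS}


def _evolve_lineage(
    cds: str, target_syn: float, omega: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    seq = list(cds)
    syn = nonsyn = 0
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_non = min(omega, 1.0)
    while syn < target_syn:
        site = int(rng.integers(0, len(seq)))
        old = seq[site]
        base = [b for b in _BASES if b != old][int(rng.integers(0, 3))]
        ci = site // 3 * 3
        codon = "".join(seq[ci : ci + 3])
        mutant = codon[: site - ci] + base + codon[site - ci + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = _CODON_AA[codon] == _CODON_AA[mutant]
        p = p_syn if synonymous else p_non
        if p < 1.0 and rng.random() >= p:
            continue
        seq[site] = base
        if synonymous:
            syn += 1
        else:
            nonsyn += 1
    return "".join(seq), syn, nonsyn


def simulate_codon_divergence(
    ancestor_cds: str, target_ks: float, omega: float, seed: int
) -> tuple[str, str, dict]:
    """Evolve two lineages from an ancestor to a target synonymous rate.

    Returns (cds_a, cds_b, truth) where truth records the ancestor's
    synonymous-site count and each lineage's realized accepted
    substitution counts.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    cds = _check_ancestor(ancestor_cds)
    s_sites = _synonymous_sites(cds)
    rng = np.random.default_rng(seed)
    target_syn = target_ks / 2.0 * s_sites
    cds_a, syn_a, non_a = _evolve_lineage(cds, target_syn, omega, rng)
    cds_b, syn_b, non_b = _evolve_lineage(cds, target_syn, omega, rng)
    truth = {
        "s_sites_ancestor": s_sites,
        "n_sites_ancestor": len(cds) - s_sites,
        "syn_substitutions": syn_a + syn_b,
        "nonsyn_substitutions": non_a + non_b,
        "realized_ks": (syn_a + syn_b) / s_sites,
        "realized_ka": (non_a + non_b) / (len(cds) - s_sites),
        "target_ks": target_ks,
        "omega": omega,
        "seed": seed,
    }
    return cds_a, cds_b, truth


# ---------------------------------------------------------------------------
# Family genome generator
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """Layout of planted duplication events.

    ``tandem_arrays``: (chromosome, array size, intervening background
    genes between consecutive members); intervening must respect the
    detector threshold (<= 5) with the family similarity margin coming
    from ``family_ks``. ``segmental_blocks``: (source chromosome,
    destination chromosome, anchors); a run of ``anchors`` genes
    (including ``family_per_block`` family members) is copied in order to
    the destination.
    """

    tandem_arrays: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr1", 3, 2)]
    )
    segmental_blocks: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("chr2", "chr3", 6)]
    )
    n_singletons: int = 2
    family_per_block: int = 1
    family_ks: float = 0.08
    copy_ks: float = 0.04
    omega: float = 0.2
    family_codons: int = 300
    background_codons: tuple[int, int] = (100, 500)
    intergenic: tuple[int, int] = (200, 500)


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic genome."""

    family_genes: list[str]
    tandem_groups: list[list[str]]
    segmental_blocks: list[list[tuple[str, str]]]
    seed: int


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    genome: dict[str, str]
    truth: TruthTable

    @property
    def proteins(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.protein) for g in self.genes]

    @property
    def cds(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.cds) for g in self.genes]

    def family_models(self) -> list[GeneModel]:
        fam = set(self.truth.family_genes)
        return [g for g in self.genes if g.gene_id in fam]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.genome.items()), outdir / "genome.fa")
        write_fasta(self.cds, outdir / "cds.fa")
        write_fasta(self.proteins, outdir / "proteins.fa")
        write_gff3(self.genes, outdir / "genes.gff3")
        rows = []
        for i, grp in enumerate(self.truth.tandem_groups, 1):
            for gid in grp:
                rows.append(("tandem", f"group{i}", gid, ""))
        for i, blk in enumerate(self.truth.segmental_blocks, 1):
            for ga, gb in blk:
                rows.append(("segmental", f"block{i}", ga, gb))
        pd.DataFrame(
            rows, columns=["event", "unit", "gene_a", "gene_b"]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write single-transcript gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chromosome}\tsynthetic\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={gid}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f".\tID={mid}.exon{k};Parent={mid}\n"
                )
                fh.write(
                    f"{g.chromosome}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"0\tID={mid}.cds{k};Parent={mid}\n"
                )


def generate_family_genome(
    n_background: int = 30,
    family_spec: FamilySpec | None = None,
    seed: int = 0,
) -> SyntheticGenome:
    """Build a genome with planted tandem arrays and segmental blocks.

    Background genes are mutually non-homologous random CDSs; family
    members all derive from one ancestor at ``family_ks`` divergence, so
    their pairwise protein similarity clears the tandem threshold with a
    wide margin. Segmental blocks copy a gene run (family members plus
    background) to another chromosome at ``copy_ks`` divergence.
    """
    spec = family_spec or FamilySpec()
    rng = np.random.default_rng(seed)
    fam_ancestor = random_cds(spec.family_codons, rng)

    def new_family_cds() -> str:
        a, _, _ = simulate_codon_divergence(
            fam_ancestor, spec.family_ks, spec.omega, int(rng.integers(0, 2**31 - 1))
        )
        return a

    def new_background_cds() -> str:
        n = int(rng.integers(*spec.background_codons))
        return random_cds(n, rng)

    def copy_of(cds: str) -> str:
        a, _, _ = simulate_codon_divergence(
            cds, spec.copy_ks, spec.omega, int(rng.integers(0, 2**31 - 1))
        )
        return a

    # chromosome -> ordered list of (gene_id, cds, is_family)
    layout: dict[str, list[tuple[str, str, bool]]] = {}
    counters = {"fam": 0, "bg": 0}

    def fam_id() -> str:
        counters["fam"] += 1
        return f"FAM{counters['fam']:02d}"

    def bg_id() -> str:
        counters["bg"] += 1
        return f"BG{counters['bg']:03d}"

    truth_tandem: list[list[str]] = []
    truth_blocks: list[list[tuple[str, str]]] = []
    family_ids: list[str] = []

    for chrom, size, intervening in spec.tandem_arrays:
        members = []
        run = layout.setdefault(chrom, [])
        for i in range(size):
            if i > 0:
                for _ in range(intervening):
                    run.append((bg_id(), new_background_cds(), False))
            gid = fam_id()
            members.append(gid)
            family_ids.append(gid)
            run.append((gid, new_family_cds(), True))
        truth_tandem.append(members)

    for chrom_src, chrom_dst, n_anchors in spec.segmental_blocks:
        n_fam = min(spec.family_per_block, n_anchors)
        src_run: list[tuple[str, str, bool]] = []
        # family slots spaced > 5 apart so block membership alone never
        # satisfies the tandem criterion
        candidates = list(range(0, n_anchors, 7))
        fam_slots = set(candidates[:n_fam])
        if len(fam_slots) < n_fam:
            raise ValueError(
                "block too short to space family members beyond the tandem "
                "separation threshold"
            )
        for i in range(n_anchors):
            if i in fam_slots:
                gid = fam_id()
                family_ids.append(gid)
                src_run.append((gid, new_family_cds(), True))
            else:
                src_run.append((bg_id(), new_background_cds(), False))
        pairs = []
        dst_run = []
        for gid, cds, is_fam in src_run:
            cid = fam_id() if is_fam else bg_id()
            if is_fam:
                family_ids.append(cid)
            dst_run.append((cid, copy_of(cds), is_fam))
            pairs.append((gid, cid))
        layout.setdefault(chrom_src, []).extend(src_run)
        layout.setdefault(chrom_dst, []).extend(dst_run)
        truth_blocks.append(pairs)

    singleton_chrom = f"chr{len(layout) + 1}"
    for i in range(spec.n_singletons):
        run = layout.setdefault(singleton_chrom, [])
        if i > 0:  # keep singletons beyond the tandem separation threshold
            for _ in range(7):
                run.append((bg_id(), new_background_cds(), False))
        gid = fam_id()
        family_ids.append(gid)
        run.append((gid, new_family_cds(), True))

    # scatter remaining background genes across chromosomes, appended after
    # planted structures so planted separations are untouched
    chroms = sorted(layout)
    for i in range(n_background):
        chrom = chroms[i % len(chroms)]
        layout[chrom].append((bg_id(), new_background_cds(), False))

    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    for chrom in sorted(layout):
        pos = 0
        parts: list[str] = []
        for gid, cds, _is_fam in layout[chrom]:
            spacer = "".join(
                rng.choice(list(_BASES), size=int(rng.integers(*spec.intergenic)))
            )
            parts.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.8 else "-"
            gene_seq = cds if strand == "+" else reverse_complement(cds)
            start, end = pos, pos + len(cds)
            parts.append(gene_seq)
            pos = end
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=[(start, end)],
                    cds=cds,
                    protein=translate_cds(cds),
                )
            )
        tail = "".join(rng.choice(list(_BASES), size=int(rng.integers(*spec.intergenic))))
        parts.append(tail)
        genome[chrom] = "".join(parts)

    assign_ordinals(genes)
    truth = TruthTable(
        family_genes=family_ids,
        tandem_groups=truth_tandem,
        segmental_blocks=truth_blocks,
        seed=seed,
    )
    return SyntheticGenome(genes=genes, genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------


def generate_expression(
    n_genes: int,
    conditions: Sequence[str],
    group_archetypes: Sequence[Sequence[float]],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression matrix around per-group archetypes.

    Archetypes are per-condition mean log10 abundances; values are
    10^(archetype + N(0, noise_sd)) - 1, clipped at 0. Genes are assigned
    to archetype groups round-robin. Returns (matrix, group labels 1..k).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    arch = np.asarray(group_archetypes, dtype=float)
    if arch.shape[1] != len(conditions):
        raise ValueError("archetype length must match number of conditions")
    rng = np.random.default_rng(seed)
    labels = np.array([i % len(arch) + 1 for i in range(n_genes)])
    logs = arch[labels - 1] + rng.normal(0.0, noise_sd, size=(n_genes, len(conditions)))
    values = np.clip(10.0**logs - 1.0, 0.0, None)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    matrix = pd.DataFrame(values, index=genes, columns=list(conditions))
    return matrix, pd.Series(labels, index=genes, name="group")


# ---------------------------------------------------------------------------
# Promoter generator
# ---------------------------------------------------------------------------


def generate_promoters(
    n: int,
    length: int,
    motif_plan: Mapping[int, Sequence[tuple[str, str]]],
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, int, str]]]:
    """Random promoters with motifs planted at recorded positions.

    ``motif_plan`` maps promoter index (0-based) to a list of
    (element_name, iupac_pattern) to plant on the forward strand at
    non-overlapping random offsets. Returns (FASTA records, planted) with
    planted rows (promoter_id, element_name, offset, matched_sequence).
    Raises if a promoter cannot fit its motifs without overlap.
    """
    from .expression_cis import IUPAC  # degeneracy alphabet

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    planted: list[tuple[str, str, int, str]] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        seq = list("".join(rng.choice(list(_BASES), size=length)))
        occupied: list[tuple[int, int]] = []
        for name, pattern in motif_plan.get(i, []):
            width = len(pattern)
            if width > length:
                raise ValueError(f"motif {name} longer than promoter")
            concrete = "".join(
                ch if ch in _BASES else rng.choice(list(IUPAC[ch].strip("[]")))
                for ch in pattern.upper()
            )
            placed = False
            for _ in range(1000):
                off = int(rng.integers(0, length - width + 1))
                if all(off + width <= s or off >= e for s, e in occupied):
                    seq[off : off + width] = concrete
                    occupied.append((off, off + width))
                    planted.append((pid, name, off, concrete))
                    placed = True
                    break
            if not placed:
                raise ValueError(f"promoter {pid}: motif plan too dense to place {name}")
        records.append((pid, "".join(seq)))
    return records, planted
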