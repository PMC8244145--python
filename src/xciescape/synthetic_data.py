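"""Seeded generator of X-inactivation benchmark data with planted structure.

The generator emulates the statistical structure the calling pipeline is
built for: skewed-XCI female samples whose escape genes express the
inactive-X allele at >= 10% of the active-X level while silenced genes sit
below it; bimodal per-allele promoter methylation whose inactive-X reads
are only partially methylated because of CpG-to-CpG inconsistency (per-CpG
offsets, not cell mixtures); histone signal whose female excess over males
depends on each gene's per-sample XCI state; and autosomal genotypes, some
of which shift the escape probability of variably escaping genes.

Every draw flows through explicitly passed ``numpy.random.Generator``
objects derived from one seed; regenerating with the same seed is
bit-identical.  Each simulation stage uses its own fixed stream so stages
are reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (GeneAnnotation, SampleInfo, write_gene_models,
                        write_sample_sheet, write_vcf)
from .methylation import MethylRead
from .chromatin_signal import MARKS, MARK_REGION_KIND, MarkMatrix

# fixed per-stage stream tags so each stage is independently reproducible
_STREAM_TRUTH, _STREAM_EXPR, _STREAM_METH, _STREAM_MARKS, _STREAM_GENO = range(5)


@dataclass(frozen=True)
class MarkEffect:
    """Generative means for one mark: Xa baseline plus status-dependent Xi add-on."""

    xa_mean: float
    xi_escape: float
    xi_subject: float
    sd: float = 0.15


#: Direction structure of the study system: heterochromatic marks (H3K9me3,
#: H3K27me3, DNAme) carry a larger Xi component at silenced genes, euchromatic
#: marks (H3K4me3, H3K27ac, H3K36me3, H3K4me1) retain an Xa-like Xi component
#: only where the gene escapes.  DNAme is on the proportion scale — the female
#: promoter mean is the Xa/Xi average, so a methylated Xi adds ~0.35 — and is
#: deliberately the most separating feature between the two states.
DEFAULT_MARK_EFFECTS: dict[str, MarkEffect] = {
    "H3K4me3": MarkEffect(xa_mean=1.0, xi_escape=0.9, xi_subject=0.10),
    "H3K27ac": MarkEffect(xa_mean=1.0, xi_escape=0.9, xi_subject=0.10),
    "H3K36me3": MarkEffect(xa_mean=1.0, xi_escape=0.6, xi_subject=0.30),
    "H3K4me1": MarkEffect(xa_mean=1.0, xi_escape=0.8, xi_subject=0.55),
    "H3K9me3": MarkEffect(xa_mean=0.5, xi_escape=0.7, xi_subject=1.10),
    "H3K27me3": MarkEffect(xa_mean=0.5, xi_escape=1.5, xi_subject=2.00),
    "DNAme": MarkEffect(xa_mean=0.05, xi_escape=0.0, xi_subject=0.35, sd=0.02),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A locus shifting the escape probability of one variable gene.

    ``probs`` are escape probabilities for dosage 0/1/2.  ``gene_id`` of
    None assigns the effect to the next unclaimed variable gene at truth
    time; an explicit id must name a variable gene.
    """

    locus_id: str
    probs: tuple[float, float, float]
    gene_id: str | None = None
    allele_freq: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 200
    frac_escape: float = 0.12
    frac_subject: float = 0.80
    frac_variable: float = 0.08
    n_samples_female: int = 8
    n_samples_male: int = 4
    tissues: tuple[str, ...] = ("blood", "brain", "breast")
    skew_fraction: float = 0.5
    xi_expr_ratio_escape: tuple[float, float] = (0.15, 1.0)
    xi_expr_ratio_subject: tuple[float, float] = (0.0, 0.05)
    dname_xa_mean: float = 0.03
    dname_xi_subject_mean: float = 0.80
    dname_xi_escape_mean: float = 0.05
    per_cpg_sd: float = 0.20
    mark_effects: Mapping[str, MarkEffect] = field(
        default_factory=lambda: dict(DEFAULT_MARK_EFFECTS))
    n_loci: int = 50
    planted_effects: tuple[PlantedEffect, ...] = (
        PlantedEffect("rs_planted_1", probs=(0.7, 0.5, 0.3)),
    )
    n_cpgs_per_island: int = 10
    reads_per_island: int = 40
    read_span: int = 5
    variable_base_prob: float = 0.5

    def __post_init__(self):
        for name in ("frac_escape", "frac_subject", "frac_variable",
                     "skew_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_escape + self.frac_subject + self.frac_variable > 1 + 1e-9:
            raise ValueError("status fractions must sum to at most 1")
        if self.n_cpgs_per_island < 5:
            raise ValueError("islands need at least 5 CpGs")


@dataclass
class Truth:
    """Ground truth: genes, samples, per-gene per-sample XCI states, genotypes."""

    cfg: SimConfig
    genes: list[GeneAnnotation]
    samples: list[SampleInfo]
    states: pd.DataFrame           # gene x female-sample, "escape"/"subject"
    xi_haplotype: dict[str, str]   # female sample -> "A"/"B" (the skewed choice)
    planted: list[PlantedEffect]   # gene_id resolved
    planted_genotypes: pd.DataFrame  # all samples x planted loci, dosage

    @property
    def female_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.sex == "female"]

    @property
    def male_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.sex == "male"]

    @property
    def meta_status(self) -> dict[str, str]:
        return {g.gene_id: g.meta_status for g in self.genes}


def _stage_rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _make_genes(cfg: SimConfig, statuses: Sequence[str]) -> list[GeneAnnotation]:
    genes = []
    for i, status in enumerate(statuses):
        start = 100_000 + i * 20_000
        end = start + 8_000
        strand = "+" if i % 2 == 0 else "-"
        tss = start if strand == "+" else end - 1
        island = (tss - 250, tss + 250)
        exons = [(start, start + 2_000), (end - 3_000, end)]
        genes.append(GeneAnnotation(
            gene_id=f"G{i:04d}", transcript_id=f"G{i:04d}.T1", chrom="chrX",
            strand=strand, start=start, end=end, exons=exons,
            cpg_island=island, is_PAR=False, meta_status=status))
    return genes


def simulate_truth(cfg: SimConfig) -> Truth:
    """Assign meta-statuses, per-sample states, skew, and planted genotypes.

    Constitutive genes hold one state in every sample; variable genes draw
    a state per female sample — Bernoulli(variable_base_prob), or the
    planted per-genotype escape probability where a locus is linked.
    """
    rng = _stage_rng(cfg, _STREAM_TRUTH)
    n = cfg.n_genes
    n_escape = round(n * cfg.frac_escape)
    n_variable = round(n * cfg.frac_variable)
    n_subject = round(n * cfg.frac_subject)
    n_subject = min(n_subject, n - n_escape - n_variable)
    statuses = (["escape"] * n_escape + ["variable"] * n_variable
                + ["subject"] * n_subject)
    statuses += ["unknown"] * (n - len(statuses))
    rng.shuffle(statuses)
    genes = _make_genes(cfg, statuses)

    # skew_fraction is a proportion, so exactly that many females are skewed
    n_skewed = round(cfg.skew_fraction * cfg.n_samples_female)
    skew_idx = set(rng.choice(cfg.n_samples_female, size=n_skewed, replace=False)) \
        if cfg.n_samples_female else set()
    samples = []
    for i in range(cfg.n_samples_female):
        tissue = cfg.tissues[i % len(cfg.tissues)]
        samples.append(SampleInfo(f"F{i:03d}", "female", tissue, "sim",
                                  i in skew_idx))
    for i in range(cfg.n_samples_male):
        tissue = cfg.tissues[i % len(cfg.tissues)]
        samples.append(SampleInfo(f"M{i:03d}", "male", tissue, "sim", None))

    female_ids = [s.sample_id for s in samples if s.sex == "female"]
    xi_hap = {sid: ("A" if rng.random() < 0.5 else "B") for sid in female_ids}

    variable_ids = [g.gene_id for g in genes if g.meta_status == "variable"]
    gene_ids = {g.gene_id for g in genes}
    planted: list[PlantedEffect] = []
    claimed: set[str] = set()
    for eff in cfg.planted_effects:
        if eff.gene_id is None:
            free = [g for g in variable_ids if g not in claimed]
            if not free:
                continue  # nothing left to plant on
            eff = replace(eff, gene_id=free[0])
        elif eff.gene_id not in gene_ids:
            raise ValueError(f"planted locus {eff.locus_id} references unknown "
                             f"gene {eff.gene_id}")
        claimed.add(eff.gene_id)
        planted.append(eff)

    all_ids = [s.sample_id for s in samples]
    geno = pd.DataFrame(index=pd.Index(all_ids, name="sample_id"),
                        columns=[e.locus_id for e in planted], dtype=float)
    for eff in planted:
        geno[eff.locus_id] = rng.binomial(2, eff.allele_freq, size=len(all_ids))

    effect_by_gene = {e.gene_id: e for e in planted}
    states = pd.DataFrame(index=pd.Index([g.gene_id for g in genes], name="gene_id"),
                          columns=female_ids, dtype=object)
    # true hidden state for unknown-meta genes: mostly silenced, like the X
    hidden = {g.gene_id: ("escape" if rng.random() < 0.15 else "subject")
              for g in genes if g.meta_status == "unknown"}
    for g in genes:
        if g.meta_status == "variable":
            eff = effect_by_gene.get(g.gene_id)
            for sid in female_ids:
                if eff is not None:
                    p = eff.probs[int(geno.loc[sid, eff.locus_id])]
                else:
                    p = cfg.variable_base_prob
                states.loc[g.gene_id, sid] = "escape" if rng.random() < p else "subject"
        else:
            state = g.meta_status if g.meta_status in ("escape", "subject") \
                else hidden[g.gene_id]
            states.loc[g.gene_id, :] = state
    return Truth(cfg, genes, samples, states, xi_hap, planted, geno)


def simulate_allelic_counts(truth: Truth, depth: float = 200.0) -> pd.DataFrame:
    """Allelic RNA-seq read counts per gene per female sample.

    Total reads ~ Poisson(depth); Xi reads ~ Binomial(total, r/(1+r)) with
    the Xi/Xa ratio r drawn from the status-appropriate range.  In samples
    without skewed XCI each cell picks its Xi at random, so the two
    haplotypes mix 50:50 and allelic imbalance vanishes in expectation.
    Columns: gene_id, sample_id, allele_a, allele_b.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = truth.cfg
    rng = _stage_rng(cfg, _STREAM_EXPR)
    skew = {s.sample_id: s.skewed_xi for s in truth.samples}
    rows = []
    for gene in truth.genes:
        for sid in truth.female_ids:
            state = truth.states.loc[gene.gene_id, sid]
            lo, hi = (cfg.xi_expr_ratio_escape if state == "escape"
                      else cfg.xi_expr_ratio_subject)
            r = rng.uniform(lo, hi)
            total = rng.poisson(depth)
            if total == 0:
                rows.append((gene.gene_id, sid, 0, 0))
                continue
            p_xi = r / (1.0 + r)
            if skew[sid]:
                xi = rng.binomial(total, p_xi)
                xa = total - xi
                a, b = (xi, xa) if truth.xi_haplotype[sid] == "A" else (xa, xi)
            else:
                # 50:50 mixture of the two Xi choices
                a = rng.binomial(total, 0.5)
                b = total - a
            rows.append((gene.gene_id, sid, int(a), int(b)))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "allele_a", "allele_b"])


_INFORMATIVE_PAIRS = (("C", "G"), ("C", "A"), ("T", "G"))


@dataclass
class BisulfiteSim:
    reads: list[MethylRead]
    snps: pd.DataFrame            # snp_id, gene_id, ref, alt, pos
    read_table: pd.DataFrame      # same content as reads, tabular, + sample/gene
    cpg_xi_probs: dict[tuple[str, str], np.ndarray]  # (gene, sample) -> per-CpG Xi p


def simulate_bisulfite_reads(truth: Truth, snp_prob: float = 0.7,
                             excluded_pair_prob: float = 0.25) -> BisulfiteSim:
    """Per-read bisulfite records over each gene's CpG island, per female sample.

    WGBS is DNA, so reads come from the two chromosomes equally regardless
    of expression skew.  A read's chromosome is the sample's Xi haplotype
    or not; in unskewed samples the cell of origin re-draws the Xi per
    read.  Per-CpG methylation probability is the allele/state mean plus a
    per-CpG offset ~ Normal(0, per_cpg_sd) clipped to [0, 1] — the offsets,
    shared by all reads of that island in that sample, create the
    CpG-to-CpG inconsistency that yields intermediately methylated reads.
    Some SNPs are generated with C/T- or G/A-style allele pairs to exercise
    the caller's exclusion rule.
    """
    cfg = truth.cfg
    rng = _stage_rng(cfg, _STREAM_METH)
    skew = {s.sample_id: s.skewed_xi for s in truth.samples}
    n_cpg = cfg.n_cpgs_per_island
    span = min(cfg.read_span, n_cpg)

    snp_rows = []
    snp_by_gene: dict[str, tuple[str, str, str]] = {}
    for gene in truth.genes:
        if rng.random() >= snp_prob:
            continue
        if rng.random() < excluded_pair_prob:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        else:
            ref, alt = _INFORMATIVE_PAIRS[rng.integers(len(_INFORMATIVE_PAIRS))]
        snp_id = f"snp_{gene.gene_id}"
        snp_rows.append((snp_id, gene.gene_id, ref, alt, gene.tss + 100))
        snp_by_gene[gene.gene_id] = (snp_id, ref, alt)

    reads: list[MethylRead] = []
    tab_rows = []
    cpg_probs: dict[tuple[str, str], np.ndarray] = {}
    for gene in truth.genes:
        snp = snp_by_gene.get(gene.gene_id)
        for sid in truth.female_ids:
            state = truth.states.loc[gene.gene_id, sid]
            xi_mean = (cfg.dname_xi_escape_mean if state == "escape"
                       else cfg.dname_xi_subject_mean)
            offsets = rng.normal(0.0, cfg.per_cpg_sd, size=n_cpg)
            p_xi = np.clip(xi_mean + offsets, 0.0, 1.0)
            p_xa = np.clip(cfg.dname_xa_mean + offsets * 0.25, 0.0, 1.0)
            cpg_probs[(gene.gene_id, sid)] = p_xi
            island_id = f"{gene.gene_id}.island"
            for k in range(cfg.reads_per_island):
                chrom_a = rng.random() < 0.5  # sequenced chromosome: hap A?
                if skew[sid]:
                    is_xi = (truth.xi_haplotype[sid] == "A") == chrom_a
                else:
                    is_xi = rng.random() < 0.5  # random Xi choice per cell
                probs = p_xi if is_xi else p_xa
                start = int(rng.integers(0, n_cpg - span + 1))
                covered = probs[start:start + span]
                n_meth = int(rng.binomial(1, covered).sum())
                allele = None
                snp_id = None
                if snp is not None and rng.random() < 0.8:
                    snp_id, ref, alt = snp
                    allele = ref if chrom_a else alt
                read = MethylRead(f"{island_id}.{sid}.r{k}", island_id,
                                  n_meth, span, allele, snp_id)
                reads.append(read)
                tab_rows.append((read.read_id, island_id, gene.gene_id, sid,
                                 n_meth, span, snp_id or "", allele or ""))

    snps = pd.DataFrame(snp_rows, columns=["snp_id", "gene_id", "ref", "alt", "pos"])
    table = pd.DataFrame(tab_rows, columns=[
        "read_id", "island_id", "gene_id", "sample_id", "n_meth", "n_total",
        "snp_id", "snp_allele"])
    return BisulfiteSim(reads, snps, table, cpg_probs)


def simulate_mark_matrix(truth: Truth, effect_scale: float = 1.0) -> dict[str, MarkMatrix]:
    """Region x sample normalised-signal matrices for the 6 histone marks + DNAme.

    Female signal = Xa component + Xi component (the latter depends on the
    sample's state at the gene, scaled by ``effect_scale``); male signal is
    the Xa component alone.  Gaussian noise, truncated at zero.
    """
    cfg = truth.cfg
    rng = _stage_rng(cfg, _STREAM_MARKS)
    tids = [g.transcript_id for g in truth.genes]
    gene_of = {g.transcript_id: g.gene_id for g in truth.genes}
    all_ids = [s.sample_id for s in truth.samples]
    sex = {s.sample_id: s.sex for s in truth.samples}
    out = {}
    for mark in MARKS:
        eff = cfg.mark_effects[mark]
        mat = np.zeros((len(tids), len(all_ids)))
        for j, sid in enumerate(all_ids):
            for i, tid in enumerate(tids):
                base = eff.xa_mean
                if sex[sid] == "female":
                    state = truth.states.loc[gene_of[tid], sid]
                    xi = eff.xi_escape if state == "escape" else eff.xi_subject
                    base = eff.xa_mean + effect_scale * xi
                mat[i, j] = max(0.0, base + rng.normal(0.0, eff.sd))
        values = pd.DataFrame(mat, index=pd.Index(tids, name="region_id"),
                              columns=all_ids)
        out[mark] = MarkMatrix(mark, values, MARK_REGION_KIND[mark])
    return out


def simulate_autosomal_profile(truth: Truth, tissue_sep: float = 1.0,
                               noise_sd: float = 0.1) -> pd.DataFrame:
    """Per-sample autosomal mean level of each mark, structured by tissue.

    Used by the predictor's sample clustering: tissues are offset from one
    another so k-means recovers tissue groups containing both sexes.
    """
    cfg = truth.cfg
    rng = _stage_rng(cfg, _STREAM_MARKS + 100)
    tissue_idx = {t: i for i, t in enumerate(cfg.tissues)}
    rows = {}
    for s in truth.samples:
        offset = tissue_sep * tissue_idx[s.tissue]
        rows[s.sample_id] = [1.0 + offset + rng.normal(0.0, noise_sd)
                             for _ in MARKS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MARKS)) \
        .rename_axis("sample_id")


def simulate_genotypes(truth: Truth) -> pd.DataFrame:
    """Sample x locus dosage matrix: planted loci plus independent null loci.

    Null loci are Hardy–Weinberg draws at allele frequencies uniform in
    [0.1, 0.5], independent of the truth table.
    """
    cfg = truth.cfg
    rng = _stage_rng(cfg, _STREAM_GENO)
    planted = truth.planted_genotypes
    n_null = max(0, cfg.n_loci - len(truth.planted))
    cols = {}
    for k in range(n_null):
        freq = rng.uniform(0.1, 0.5)
        cols[f"rs{k:05d}"] = rng.binomial(2, freq, size=len(planted.index)).astype(float)
    null = pd.DataFrame(cols, index=planted.index)
    return pd.concat([planted, null], axis=1)


def write_all(truth: Truth, outdir, depth: float = 200.0) -> dict[str, Path]:
    """Materialise every downstream input format under ``outdir``.

    Emits the gene models (BED12 dialect), sample sheet, allelic counts
    TSV, read-level bisulfite TSV + SNP table, one mark-matrix TSV per
    mark, the autosomal clustering profile, genotypes as minimal VCF, and
    the truth table (for evaluation only, never consumed by callers).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gene_models"] = outdir / "gene_models.bed"
    write_gene_models(truth.genes, paths["gene_models"])
    paths["sample_sheet"] = outdir / "samples.tsv"
    write_sample_sheet(truth.samples, paths["sample_sheet"])

    counts = simulate_allelic_counts(truth, depth=depth)
    paths["allelic_counts"] = outdir / "allelic_counts.tsv"
    counts.to_csv(paths["allelic_counts"], sep="\t", index=False)

    bs = simulate_bisulfite_reads(truth)
    paths["methyl_reads"] = outdir / "methyl_reads.tsv"
    bs.read_table.to_csv(paths["methyl_reads"], sep="\t", index=False)
    paths["snps"] = outdir / "island_snps.tsv"
    bs.snps.to_csv(paths["snps"], sep="\t", index=False)

    marks = simulate_mark_matrix(truth)
    for mark, mm in marks.items():
        p = outdir / f"mark_{mark}.tsv"
        mm.values.to_csv(p, sep="\t", float_format="%.6g")
        paths[f"mark_{mark}"] = p
    paths["autosomal_profile"] = outdir / "autosomal_profile.tsv"
    simulate_autosomal_profile(truth).to_csv(
        paths["autosomal_profile"], sep="\t", float_format="%.6g")

    geno = simulate_genotypes(truth)
    paths["genotypes"] = outdir / "genotypes.vcf"
    write_vcf(geno, paths["genotypes"])

    paths["truth_states"] = outdir / "truth_states.tsv"
    truth.states.to_csv(paths["truth_states"], sep="\t")
    return paths
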