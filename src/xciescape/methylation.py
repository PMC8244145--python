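"""Promoter DNA-methylation XCI calls at three resolutions.

Island/promoter means: a gene escapes XCI when female promoter DNAme is
below 10%, is subject to XCI between 15% and 60%, and hypermethylated
above 60%; promoters methylated in males (>= 15%) are uninformative
because the active X is already methylated there.  Read level: bisulfite
reads carry their own fraction of methylated CG dinucleotides, and genes
are binned by mean island DNAme.  Allele level: reads tagged by a
heterozygous SNP are split into C/T and G/A base groups (C<->T and G<->A
polymorphisms are excluded outright — bisulfite conversion itself turns
unmethylated C into T, and G into A on the opposite strand) and called
escape/subject/hypermethylated from the two per-allele means with 0.25 and
0.75 thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allelic_expression import XCICall


@dataclass
class DnameCallConfig:
    escape_max: float = 0.10
    subject_min: float = 0.15
    subject_max: float = 0.60
    hyper_min: float = 0.60
    male_informative_max: float = 0.15
    allelic_low: float = 0.25
    allelic_high: float = 0.75
    min_reads_per_allele: int = 5

    def __post_init__(self):
        if not (0 < self.escape_max < self.subject_min < self.subject_max <= self.hyper_min < 1):
            raise ValueError("thresholds must satisfy 0 < escape_max < subject_min"
                             " < subject_max <= hyper_min < 1")
        if not self.allelic_low < self.allelic_high:
            raise ValueError("allelic_low must be below allelic_high")


@dataclass
class MethylRead:
    """One bisulfite read: methylated/total CG dinucleotides, optional SNP tag."""

    read_id: str
    island_id: str
    n_meth: int
    n_total: int
    snp_allele: str | None = None
    snp_id: str | None = None

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("read must cover at least one CG")
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError("n_meth outside [0, n_total]")

    @property
    def dname(self) -> float:
        return self.n_meth / self.n_total


@dataclass
class IslandMethSummary:
    island_id: str
    sample_id: str
    mean_dname: float
    bin: int                       # decile of mean_dname, top bin closed
    read_fractions: tuple[float, float, float]  # <25%, 33-66%, >75%
    n_reads: int


def dname_bin(mean_dname: float) -> int:
    """Decile bin of a methylation mean: floor(10m), with [0.9, 1.0] -> 9."""
    return min(int(math.floor(mean_dname * 10)), 9)


def call_from_dname(female_mean: float, male_mean: float | None,
                    cfg: DnameCallConfig | None = None,
                    gene_id: str = "", sample_id: str = "") -> XCICall:
    """Threshold call from female and male promoter DNAme means.

    Values in the deliberate buffer zones (the 10-15% gap and exactly 60%)
    are "intermediate" rather than snapped to the nearest band.
    """
    cfg = cfg or DnameCallConfig()
    detail = {"female_mean": female_mean, "male_mean": male_mean}
    if male_mean is None or math.isnan(male_mean):
        return XCICall(gene_id, sample_id, "uninformative", "dname",
                       {**detail, "reason": "no male data"})
    if math.isnan(female_mean):
        return XCICall(gene_id, sample_id, "uninformative", "dname",
                       {**detail, "reason": "no female data"})
    if male_mean >= cfg.male_informative_max:
        return XCICall(gene_id, sample_id, "uninformative", "dname",
                       {**detail, "reason": "male methylated"})
    if female_mean < cfg.escape_max:
        status = "escape"
    elif cfg.subject_min < female_mean < cfg.subject_max:
        status = "subject"
    elif female_mean > cfg.hyper_min:
        status = "hypermethylated"
    else:
        status = "intermediate"
    return XCICall(gene_id, sample_id, status, "dname", detail)


def per_read_profile(reads: Sequence[MethylRead], sample_id: str = "") -> IslandMethSummary:
    """Per-read methylation summary for one island in one sample.

    Per-read DNAme is methylated/total CGs on that read; the island mean is
    the unweighted mean over reads.  Category fractions use the bands
    < 25%, 33-66% inclusive, and > 75% (deliberately non-exhaustive, so
    they are disjoint but need not sum to 1).
    """
    if not reads:
        raise ValueError("need at least one read")
    island_id = reads[0].island_id
    vals = np.array([r.dname for r in reads])
    mean = float(vals.mean())
    frac_low = float((vals < 0.25).mean())
    frac_mid = float(((vals >= 0.33) & (vals <= 0.66)).mean())
    frac_high = float((vals > 0.75).mean())
    return IslandMethSummary(island_id, sample_id, mean, dname_bin(mean),
                             (frac_low, frac_mid, frac_high), len(reads))


_CT = {"C", "T"}
_GA = {"G", "A"}


def snp_excluded(ref: str, alt: str) -> bool:
    """True for C<->T and G<->A polymorphisms, unresolvable after conversion."""
    alleles = {ref.upper(), alt.upper()}
    return alleles <= _CT or alleles <= _GA


def allelic_dname_call(reads: Sequence[MethylRead], ref: str, alt: str,
                       cfg: DnameCallConfig | None = None,
                       gene_id: str = "", sample_id: str = "") -> XCICall:
    """Allele-resolved XCI call at one SNP from its tagged bisulfite reads.

    Reads are pooled into a C/T group and a G/A group by their tagged base;
    each group needs ``min_reads_per_allele`` reads.  Both group means
    below 0.25 -> escape; one below 0.25 and one above 0.75 -> subject;
    both above 0.75 -> hypermethylated; anything else uninformative.
    """
    cfg = cfg or DnameCallConfig()
    if snp_excluded(ref, alt):
        return XCICall(gene_id, sample_id, "uninformative", "allelic_dname",
                       {"reason": "CT/GA polymorphism", "alleles": (ref, alt)})
    ct = [r.dname for r in reads if r.snp_allele in _CT]
    ga = [r.dname for r in reads if r.snp_allele in _GA]
    if len(ct) < cfg.min_reads_per_allele or len(ga) < cfg.min_reads_per_allele:
        return XCICall(gene_id, sample_id, "uninformative", "allelic_dname",
                       {"reason": "too few reads per allele",
                        "n_ct": len(ct), "n_ga": len(ga)})
    m_ct, m_ga = float(np.mean(ct)), float(np.mean(ga))
    lo, hi = min(m_ct, m_ga), max(m_ct, m_ga)
    if hi < cfg.allelic_low:
        status = "escape"
    elif lo < cfg.allelic_low and hi > cfg.allelic_high:
        status = "subject"
    elif lo > cfg.allelic_high:
        status = "hypermethylated"
    else:
        status = "uninformative"
    return XCICall(gene_id, sample_id, status, "allelic_dname",
                   {"mean_ct": m_ct, "mean_ga": m_ga})


def allelic_bin_profile(reads: Sequence[MethylRead]) -> dict:
    """Binned per-allele read summary for one SNP.

    The gene bin uses the mean of the two per-allele means — so the bin
    sits between Xi and Xa even when read depth is lopsided.  The allele
    with the lower mean is reported as the low allele; exact ties break to
    the C/T group (display only, never a call).
    """
    ct = [r.dname for r in reads if r.snp_allele in _CT]
    ga = [r.dname for r in reads if r.snp_allele in _GA]
    if not ct or not ga:
        raise ValueError("need reads for both allele groups")
    m_ct, m_ga = float(np.mean(ct)), float(np.mean(ga))
    bin_idx = dname_bin((m_ct + m_ga) / 2.0)
    if m_ct <= m_ga:  # tie -> CT group is the low allele
        low_label, low, high_label, high = "CT", m_ct, "GA", m_ga
        low_reads, high_reads = ct, ga
    else:
        low_label, low, high_label, high = "GA", m_ga, "CT", m_ct
        low_reads, high_reads = ga, ct
    return {"bin": bin_idx, "low_allele": low_label, "low_mean": low,
            "high_allele": high_label, "high_mean": high,
            "low_reads": low_reads, "high_reads": high_reads}


def adjacent_cpg_difference(values: Sequence[float]) -> float:
    """Mean |difference| between consecutive CpG methylation values.

    Pairs with a missing (NaN) member are skipped.  Needs at least two
    non-missing-capable positions and one usable pair.
    """
    if len(values) < 2:
        raise ValueError("need at least two CpG values")
    diffs = []
    for a, b in zip(values, values[1:]):
        if math.isnan(a) or math.isnan(b):
            continue
        diffs.append(abs(b - a))
    if not diffs:
        return math.nan
    return float(np.mean(diffs))


def filter_450k_style(probe_means: pd.DataFrame, sex: Mapping[str, str],
                      cfg: DnameCallConfig | None = None) -> tuple[list[str], list[str]]:
    """Array-style probe and sample filters.

    ``probe_means`` is probe x sample.  Probes whose male average exceeds
    15% are dropped (methylated Xa).  Female samples whose across-probe
    mean falls strictly below the female average minus two standard
    deviations are dropped — presumed mislabelled males or Xi loss.
    Returns (retained probes, retained female samples).
    """
    cfg = cfg or DnameCallConfig()
    males = [s for s in probe_means.columns if sex.get(s) == "male"]
    females = [s for s in probe_means.columns if sex.get(s) == "female"]
    if males:
        male_avg = probe_means[males].mean(axis=1)
        probes = probe_means.index[male_avg <= cfg.male_informative_max].tolist()
    else:
        probes = probe_means.index.tolist()
    if not females:
        return probes, []
    fem_sample_means = probe_means.loc[probes, females].mean(axis=0)
    cutoff = fem_sample_means.mean() - 2 * fem_sample_means.std(ddof=1) \
        if len(females) > 1 else -math.inf
    kept_females = [s for s in females if not fem_sample_means[s] < cutoff]
    return probes, kept_females


def dname_variable_escape(per_sample_statuses: Sequence[str], transcript_id: str = "",
                          frac_each: float = 1.0 / 3.0,
                          constitutive_frac: float = 0.66) -> XCICall:
    """Overall DNAme call for one transcript across samples.

    Denominators count informative samples only (escape/subject/
    hypermethylated/intermediate statuses contribute to the denominator;
    "uninformative" does not).  A transcript is variable when escape and
    subject each reach ``frac_each`` of informative samples; constitutive
    when one status reaches ``constitutive_frac``.
    """
    informative = [s for s in per_sample_statuses if s != "uninformative"]
    n = len(informative)
    if n == 0:
        return XCICall(transcript_id, "overall", "uninformative", "dname",
                       {"reason": "no informative samples"})
    frac_e = informative.count("escape") / n
    frac_s = informative.count("subject") / n
    detail = {"n_informative": n, "frac_escape": frac_e, "frac_subject": frac_s}
    if frac_e >= frac_each and frac_s >= frac_each:
        status = "variable"
    elif frac_e >= constitutive_frac:
        status = "escape"
    elif frac_s >= constitutive_frac:
        status = "subject"
    elif informative.count("hypermethylated") / n >= constitutive_frac:
        status = "hypermethylated"
    else:
        status = "uninformative"
    return XCICall(transcript_id, "overall", status, "dname", detail)


def gene_level_dname_calls(transcript_calls: pd.DataFrame) -> pd.DataFrame:
    """Lift transcript-level overall calls to genes.

    Transcripts of one gene with opposing constitutive statuses flag the
    gene as variable (between TSSs); otherwise the gene takes its
    transcripts' shared (or only) informative status.
    """
    rows = []
    for gene_id, sub in transcript_calls.groupby("gene_id"):
        statuses = set(sub["status"]) - {"uninformative"}
        if {"escape", "subject"} <= statuses:
            status, between = "variable", True
        elif "variable" in statuses:
            status, between = "variable", False
        elif len(statuses) == 1:
            status, between = statuses.pop(), False
        elif not statuses:
            status, between = "uninformative", False
        else:
            status, between = "intermediate", False
        rows.append((gene_id, status, between))
    return pd.DataFrame(rows, columns=["gene_id", "status", "variable_between_tss"])


def read_methyl_reads(path) -> list[MethylRead]:
    """Read the read-level TSV (read_id, island_id, n_meth, n_total, snp_id, snp_allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "snp_allele": str},
                     na_values=[""], keep_default_na=True)
    out = []
    for row in df.itertuples(index=False):
        out.append(MethylRead(
            read_id=str(row.read_id), island_id=str(row.island_id),
            n_meth=int(row.n_meth), n_total=int(row.n_total),
            snp_allele=None if pd.isna(row.snp_allele) else str(row.snp_allele),
            snp_id=None if pd.isna(row.snp_id) else str(row.snp_id)))
    return out


def write_methyl_reads(reads: Iterable[MethylRead], path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tisland_id\tn_meth\tn_total\tsnp_id\tsnp_allele\n")
        for r in reads:
            handle.write(f"{r.read_id}\t{r.island_id}\t{r.n_meth}\t{r.n_total}\t"
                         f"{r.snp_id or ''}\t{r.snp_allele or ''}\n")
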