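"""Genotype <-> XCI-status association and methylation QTLs.

Variable-escape genes are tested against genotypes with a 2x2 Pearson
chi-square over the two homozygote classes — heterozygotes are excluded
because the analysis targets a cis effect and a heterozygote's Xi allele
is unknown.  Significant loci get a population attributable risk for the
escape outcome.  DNAme-QTLs are ordinary least-squares fits of island
methylation on genotype dosage, run separately per sex (an Xi-mediated
effect should appear only in females), with a flag for loci whose two
homozygote methylation medians span the escape/subject call bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import DnameCallConfig


@dataclass
class AssociationResult:
    gene_id: str
    locus_id: str
    contingency: np.ndarray       # 2x2: genotype (hom-ref, hom-alt) x (escape, subject)
    chi2: float
    p_raw: float
    p_adj: float = math.nan
    enrichment_ratio: float = math.nan
    attributable_risk: float = math.nan


@dataclass
class QtlResult:
    locus_id: str
    island_id: str
    sex: str
    slope: float
    intercept: float
    p_raw: float
    p_adj: float = math.nan
    allele_medians: tuple[float, float] = (math.nan, math.nan)  # hom-ref, hom-alt
    spans_status_change: bool = False


def relaxed_variable_set(per_sample_calls: pd.DataFrame,
                         min_each: int = 100) -> list[str]:
    """Genes with strictly more than ``min_each`` samples of each status.

    The relaxed rule used when the cohort is large enough that absolute
    counts beat the usual 33%-of-samples fractions.  Expects columns
    gene_id, sample_id, status.
    """
    genes = []
    for gene_id, sub in per_sample_calls.groupby("gene_id"):
        n_e = int((sub["status"] == "escape").sum())
        n_s = int((sub["status"] == "subject").sum())
        if n_e > min_each and n_s > min_each:
            genes.append(gene_id)
    return genes


def xci_genotype_test(status_by_gene: pd.DataFrame, genotypes: pd.DataFrame,
                      alpha: float = 0.01, min_per_class: int = 5,
                      loci: Sequence[str] | None = None,
                      ) -> list[AssociationResult]:
    """Chi-square association of every gene x locus pair, BH over the run.

    ``status_by_gene``: columns gene_id, sample_id, status;
    ``genotypes``: sample x locus dosage.  Pairs where either homozygote
    class has fewer than ``min_per_class`` samples, or a contingency
    margin is empty, are skipped (no exact-test fallback, no continuity
    correction).  Restrict ``loci`` (e.g. X-only) for a second family.
    """
    loci = list(loci) if loci is not None else list(genotypes.columns)
    results: list[AssociationResult] = []
    geno_mat = genotypes[loci]
    for gene_id, sub in status_by_gene.groupby("gene_id"):
        status = sub.set_index("sample_id")["status"]
        shared = status.index.intersection(geno_mat.index)
        status = status.loc[shared]
        g = geno_mat.loc[shared].to_numpy(dtype=float)      # samples x loci
        is_e = (status == "escape").to_numpy()[:, None]
        is_s = (status == "subject").to_numpy()[:, None]
        ref, alt = g == 0.0, g == 2.0                        # hets drop out
        a = (ref & is_e).sum(axis=0).astype(float)           # ref x escape
        b = (ref & is_s).sum(axis=0).astype(float)
        c = (alt & is_e).sum(axis=0).astype(float)
        d = (alt & is_s).sum(axis=0).astype(float)
        n = a + b + c + d
        row1, row2, col1, col2 = a + b, c + d, a + c, b + d
        valid = (np.minimum(row1, row2) >= min_per_class) \
            & (col1 > 0) & (col2 > 0) & (row1 > 0) & (row2 > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
        p = stats.chi2.sf(chi2, df=1)
        for j in np.flatnonzero(valid):
            table = np.array([[a[j], b[j]], [c[j], d[j]]])
            results.append(AssociationResult(gene_id, loci[j], table,
                                             float(chi2[j]), float(p[j])))
    if results:
        adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, p_adj in zip(results, adj):
            r.p_adj = float(p_adj)
            r.enrichment_ratio = _enrichment_ratio(r.contingency)
            r.attributable_risk = attributable_risk(r.contingency)
    return results


def _enrichment_ratio(table: np.ndarray) -> float:
    """Ratio of ref:alt allele ratios between escape and subject samples."""
    e_ref, s_ref = table[0, 0], table[0, 1]
    e_alt, s_alt = table[1, 0], table[1, 1]
    if min(e_alt, s_ref) == 0 or s_alt == 0 or e_ref == 0:
        return math.nan
    ratio = (e_ref / e_alt) / (s_ref / s_alt)
    return float(ratio if ratio >= 1 else 1.0 / ratio)


def attributable_risk(table: np.ndarray) -> float:
    """Population attributable risk of escape for the higher-escape genotype.

    AR = (P(escape) - P(escape | non-carrier)) / P(escape), computed over
    the two homozygote classes with "carrier" the genotype showing the
    higher escape rate; clipped to [0, 1].  Reads as: how much of the
    escaping population is attributable to carrying the permissive allele.
    """
    table = np.asarray(table, dtype=float)
    n_geno = table.sum(axis=1)
    if (n_geno == 0).any():
        return math.nan
    escape_rate = table[:, 0] / n_geno
    carrier = int(np.argmax(escape_rate))
    non_carrier = 1 - carrier
    p_escape = table[:, 0].sum() / table.sum()
    if p_escape == 0:
        return 0.0
    ar = (p_escape - escape_rate[non_carrier]) / p_escape
    return float(min(max(ar, 0.0), 1.0))


def dname_qtl(dname: pd.Series, genotype: pd.Series, sex: Mapping[str, str],
              locus_id: str = "", island_id: str = "",
              cfg: DnameCallConfig | None = None,
              min_per_sex: int = 10) -> list[QtlResult]:
    """Per-sex OLS of island DNAme on genotype dosage for one SNP-island pair.

    ``dname`` and ``genotype`` are indexed by sample.  Each sex needs
    ``min_per_sex`` samples with both values.  Returns one QtlResult per
    sex fitted (p_adj left for the caller's family-wise correction).
    """
    cfg = cfg or DnameCallConfig()
    df = pd.DataFrame({"dname": dname, "geno": genotype}).dropna()
    df["sex"] = [sex.get(s) for s in df.index]
    out = []
    for which in ("female", "male"):
        sub = df[df["sex"] == which]
        if len(sub) < min_per_sex:
            continue
        x = sub["geno"].to_numpy(dtype=float)
        y = sub["dname"].to_numpy(dtype=float)
        if np.var(x) == 0:
            continue
        if np.var(y) == 0:
            slope, intercept, p = 0.0, float(y.mean()), 1.0
        else:
            res = stats.linregress(x, y)
            slope, intercept, p = float(res.slope), float(res.intercept), float(res.pvalue)
        med_ref = float(sub.loc[sub["geno"] == 0.0, "dname"].median()) \
            if (sub["geno"] == 0.0).any() else math.nan
        med_alt = float(sub.loc[sub["geno"] == 2.0, "dname"].median()) \
            if (sub["geno"] == 2.0).any() else math.nan
        result = QtlResult(locus_id, island_id, which, slope, intercept, p,
                           allele_medians=(med_ref, med_alt))
        result.spans_status_change = status_span(result, cfg)
        out.append(result)
    return out


def adjust_qtl(results: Sequence[QtlResult], alpha: float = 0.01) -> list[QtlResult]:
    """BH adjustment within each sex across all tested pairs."""
    for which in ("female", "male"):
        group = [r for r in results if r.sex == which]
        if not group:
            continue
        adj = multipletests([r.p_raw for r in group], method="fdr_bh")[1]
        for r, p in zip(group, adj):
            r.p_adj = float(p)
    return list(results)


def status_span(result: QtlResult, cfg: DnameCallConfig | None = None) -> bool:
    """True iff the two homozygote medians fall in opposite call bands.

    One median must sit in the escape band [0, escape_max) and the other
    inside the subject band (subject_min, subject_max).
    """
    cfg = cfg or DnameCallConfig()
    a, b = result.allele_medians
    if math.isnan(a) or math.isnan(b):
        return False
    in_escape = lambda v: 0 <= v < cfg.escape_max
    in_subject = lambda v: cfg.subject_min < v < cfg.subject_max
    return (in_escape(a) and in_subject(b)) or (in_escape(b) and in_subject(a))


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.contingency
        rows.append({
            "gene_id": r.gene_id, "locus_id": r.locus_id,
            "n_ref_escape": int(t[0, 0]), "n_ref_subject": int(t[0, 1]),
            "n_alt_escape": int(t[1, 0]), "n_alt_subject": int(t[1, 1]),
            "chi2": r.chi2, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "enrichment_ratio": r.enrichment_ratio,
            "attributable_risk": r.attributable_risk})
    return pd.DataFrame(rows)


def qtl_frame(results: Sequence[QtlResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": r.locus_id, "island_id": r.island_id, "sex": r.sex,
        "slope": r.slope, "intercept": r.intercept, "p_raw": r.p_raw,
        "p_adj": r.p_adj, "median_ref": r.allele_medians[0],
        "median_alt": r.allele_medians[1],
        "spans_status_change": r.spans_status_change} for r in results])
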