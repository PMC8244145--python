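"""XCI-status calls from inactive/active-X (Xi/Xa) allelic read counts.

A gene escapes XCI when its expression from the inactive X is at least 10%
of the active-X level.  The caller puts a Wald 95% confidence interval on
the binomial proportion p = Xi/(Xi + Xa) and compares the whole interval
against the proportion equivalent of the 10% ratio threshold,
p* = 0.1/1.1 = 1/11: a call is made only when the interval resolves the
threshold.  Downstream utilities orient alleles into Xi/Xa, drop samples
whose X-inactivation is not skewed enough for allelic analysis, and
classify variable escape across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATUSES = ("escape", "subject", "variable", "hypermethylated", "intermediate",
            "leaning_escape", "leaning_subject", "uninformative")
METHODS = ("allelic_expression", "dname", "allelic_dname", "predictor",
           "simple_threshold")


@dataclass
class AllelicCount:
    """Xi and Xa read counts for one gene in one sample."""

    gene_id: str
    sample_id: str
    xi_reads: int
    xa_reads: int

    def __post_init__(self):
        if self.xi_reads < 0 or self.xa_reads < 0:
            raise ValueError("negative read counts")

    @property
    def total(self) -> int:
        return self.xi_reads + self.xa_reads


@dataclass
class AllelicCallConfig:
    """z=1.96 gives the 95% interval; ratio_threshold is the Xi/Xa ratio cutoff."""

    z: float = 1.96
    ratio_threshold: float = 0.10
    min_total_reads: int = 10

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 0 < self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be in (0, 1)")

    @property
    def proportion_threshold(self) -> float:
        """Ratio threshold r translated to the proportion scale: r / (1 + r)."""
        return self.ratio_threshold / (1.0 + self.ratio_threshold)


@dataclass
class XCICall:
    """A status assignment with its method and free-form provenance detail."""

    gene_id: str
    sample_id: str
    status: str
    method: str
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def wald_interval(xi: int, xa: int, z: float = 1.96) -> tuple[float, float, float]:
    """Wald interval on p = xi/(xi + xa).

    Returns ``(p_hat, lower, upper)`` with bounds clipped to [0, 1].  The
    half-width is z * sqrt(p_hat (1 - p_hat) / n); at p_hat of exactly 0 or
    1 the interval has zero width (no continuity correction is applied).
    """
    n = xi + xa
    if n < 1:
        raise ValueError("need at least one read")
    p_hat = xi / n
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return p_hat, max(0.0, p_hat - half), min(1.0, p_hat + half)


def call_from_allelic(counts: AllelicCount, cfg: AllelicCallConfig | None = None) -> XCICall:
    """Escape/subject call from one gene-sample Xi/Xa count pair.

    Escape when the whole CI sits above the proportion threshold, subject
    when it sits below; an interval straddling the threshold is
    uninformative rather than forced to a side.
    """
    cfg = cfg or AllelicCallConfig()
    if counts.total < cfg.min_total_reads:
        return XCICall(counts.gene_id, counts.sample_id, "uninformative",
                       "allelic_expression", {"reason": "depth", "total": counts.total})
    p_hat, lower, upper = wald_interval(counts.xi_reads, counts.xa_reads, cfg.z)
    p_star = cfg.proportion_threshold
    if lower > p_star:
        status = "escape"
    elif upper < p_star:
        status = "subject"
    else:
        status = "uninformative"
    return XCICall(counts.gene_id, counts.sample_id, status, "allelic_expression",
                   {"p_hat": p_hat, "ci": (lower, upper)})


def call_table(counts: pd.DataFrame, cfg: AllelicCallConfig | None = None) -> pd.DataFrame:
    """Vectorised ``call_from_allelic`` over a (gene_id, sample_id, xi, xa) table."""
    cfg = cfg or AllelicCallConfig()
    xi = counts["xi"].to_numpy(dtype=float)
    xa = counts["xa"].to_numpy(dtype=float)
    n = xi + xa
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(n > 0, xi / n, np.nan)
        half = cfg.z * np.sqrt(p_hat * (1 - p_hat) / n)
    lower = np.clip(p_hat - half, 0, 1)
    upper = np.clip(p_hat + half, 0, 1)
    p_star = cfg.proportion_threshold
    status = np.where(lower > p_star, "escape",
                      np.where(upper < p_star, "subject", "uninformative"))
    status = np.where(n < cfg.min_total_reads, "uninformative", status)
    out = counts[["gene_id", "sample_id"]].copy()
    out["status"] = status
    out["p_hat"] = p_hat
    out["ci_lower"] = lower
    out["ci_upper"] = upper
    out["total"] = n.astype(int)
    out["method"] = "allelic_expression"
    return out


def infer_xi_haplotype(allele_counts: pd.DataFrame,
                       meta_status: Mapping[str, str]) -> dict[str, str | None]:
    """Label each sample's inactive-X haplotype from genes known to be silenced.

    For every gene with meta-status "subject" the silenced haplotype is the
    one with the minor read count; the haplotype silenced at the majority
    of such genes is labelled Xi.  Ties (or no informative genes) leave the
    sample unoriented (None).  Expects columns gene_id, sample_id,
    allele_a, allele_b.
    """
    out: dict[str, str | None] = {}
    for sample_id, sub in allele_counts.groupby("sample_id"):
        votes_a = votes_b = 0
        for _, row in sub.iterrows():
            if meta_status.get(row["gene_id"]) != "subject":
                continue
            a, b = row["allele_a"], row["allele_b"]
            if a + b == 0 or a == b:
                continue
            if a < b:
                votes_a += 1
            else:
                votes_b += 1
        if votes_a > votes_b:
            out[sample_id] = "A"
        elif votes_b > votes_a:
            out[sample_id] = "B"
        else:
            out[sample_id] = None
    return out


def orient_counts(allele_counts: pd.DataFrame,
                  xi_haplotype: Mapping[str, str | None]) -> pd.DataFrame:
    """Map allele_a/allele_b counts to xi/xa using per-sample Xi labels.

    Samples without an orientation are dropped (their Xi cannot be named).
    """
    rows = []
    for _, row in allele_counts.iterrows():
        hap = xi_haplotype.get(row["sample_id"])
        if hap is None:
            continue
        xi, xa = ((row["allele_a"], row["allele_b"]) if hap == "A"
                  else (row["allele_b"], row["allele_a"]))
        rows.append((row["gene_id"], row["sample_id"], int(xi), int(xa)))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "xi", "xa"])


def filter_unskewed(calls: pd.DataFrame, meta_status: Mapping[str, str],
                    max_escape_frac: float = 0.25) -> list[str]:
    """Retain samples whose X-inactivation looks skewed enough for allelic work.

    A sample is dropped iff strictly more than ``max_escape_frac`` of its
    informative meta-subject genes are called escaping — in an unskewed
    sample both alleles are expressed everywhere, so known-silenced genes
    spuriously look like escapees.  Expects per-sample calls with columns
    gene_id, sample_id, status.
    """
    retained = []
    for sample_id, sub in calls.groupby("sample_id"):
        meta_subject = sub[sub["gene_id"].map(lambda g: meta_status.get(g) == "subject")]
        informative = meta_subject[meta_subject["status"] != "uninformative"]
        if len(informative) == 0:
            retained.append(sample_id)
            continue
        frac = (informative["status"] == "escape").mean()
        if frac <= max_escape_frac:  # "more than 25%" is strict
            retained.append(sample_id)
    return retained


def variable_by_expression(per_sample_statuses: Sequence[str], gene_id: str = "",
                           min_each: int = 2) -> XCICall:
    """Overall expression-based call across samples for one gene.

    At least ``min_each`` samples escaping and ``min_each`` subject makes
    the gene variably escaping; otherwise the majority constitutive
    status.  Fewer than ``min_each`` informative samples in total is
    uninformative.
    """
    statuses = [s for s in per_sample_statuses if s in ("escape", "subject")]
    n_escape = statuses.count("escape")
    n_subject = statuses.count("subject")
    if n_escape >= min_each and n_subject >= min_each:
        status = "variable"
    elif len(statuses) < min_each:
        status = "uninformative"
    elif n_escape > n_subject:
        status = "escape"
    elif n_subject > n_escape:
        status = "subject"
    else:
        status = "uninformative"
    return XCICall(gene_id, "overall", status, "allelic_expression",
                   {"n_escape": n_escape, "n_subject": n_subject})


def overall_expression_calls(calls: pd.DataFrame, min_each: int = 2) -> pd.DataFrame:
    rows = []
    for gene_id, sub in calls.groupby("gene_id"):
        c = variable_by_expression(sub["status"].tolist(), gene_id, min_each)
        rows.append((gene_id, c.status, c.detail["n_escape"], c.detail["n_subject"]))
    return pd.DataFrame(rows, columns=["gene_id", "status", "n_escape", "n_subject"])
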