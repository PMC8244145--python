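"""Normalised histone/DNAme quantification and the Xi:Xa fold-change machinery.

Each mark is quantified over its biologically appropriate region kind:
promoter windows for H3K4me3/H3K9me3/H3K27ac/H3K27me3/DNAme, exon bodies
for H3K36me3, annotated enhancers for H3K4me1.  Samples are
depth-normalised by scaling every sample to the same genome-wide total.
The Xi:Xa fold change for a female sample is (female - male)/male against
a paired male reference: the male value proxies the Xa contribution and
the female excess the Xi contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneAnnotation, Region, RegionSet, SignalTrack

MARKS = ("H3K4me1", "H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "H3K36me3", "DNAme")
MARK_REGION_KIND = {
    "H3K4me1": "enhancer",
    "H3K36me3": "exon_body",
    **{m: "promoter" for m in ("H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "DNAme")},
}


@dataclass
class MarkMatrix:
    """Normalised mean signal, region x sample, for one mark."""

    mark: str
    values: pd.DataFrame       # index: region/transcript id, columns: sample ids
    region_kind: str

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")
        expected = MARK_REGION_KIND[self.mark]
        if self.region_kind != expected:
            raise ValueError(f"{self.mark} must be quantified over {expected}, "
                             f"not {self.region_kind}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative signal values")


@dataclass
class FoldChangeRecord:
    region_id: str
    mark: str
    female_value: float
    male_value: float
    xi_xa: float                     # (female - male) / male
    log2_xi_xa: float                # NaN when female <= male
    negative_difference: bool        # sign flag for the undefined-log2 case


def normalize_depth(totals: Mapping[str, float]) -> dict[str, float]:
    """Scale factors bringing every sample to the maximum total depth."""
    if not totals:
        raise ValueError("no sample totals")
    for sample, total in totals.items():
        if total <= 0:
            raise ValueError(f"sample {sample!r} has non-positive total depth")
    target = max(totals.values())
    return {s: target / t for s, t in totals.items()}


def quantify(tracks: Mapping[str, SignalTrack], regions: RegionSet,
             normalize: bool = True) -> pd.DataFrame:
    """Length-weighted mean signal per region per sample (region x sample).

    ``tracks`` maps sample id -> signal track.  With ``normalize`` the
    tracks are first depth-scaled to a common genome-wide total.  Regions
    sharing a ``linked_id`` (a transcript's exons) are aggregated
    length-weighted into one row.
    """
    if normalize:
        factors = normalize_depth({s: t.total_signal() for s, t in tracks.items()})
        tracks = {s: t.scale(factors[s]) for s, t in tracks.items()}
    grouped: dict[str, list[Region]] = {}
    order: list[str] = []
    for region in regions:
        key = region.linked_id or f"{region.chrom}:{region.start}-{region.end}"
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(region)
    data = {
        sample: [track.mean_over_regions(grouped[key]) for key in order]
        for sample, track in tracks.items()
    }
    return pd.DataFrame(data, index=pd.Index(order, name="region_id"))


def xi_xa_fold_change(female: pd.Series | pd.DataFrame, male_reference: pd.Series,
                      mark: str = "H3K4me3") -> list[FoldChangeRecord]:
    """(female - male)/male per region, with log2 defined only for female > male.

    ``male_reference`` is the mean over the paired male group (see
    ``epigenetic_predictor.pair_female_male`` for the pairing).  A negative
    difference keeps its linear value but records the log2 as missing with
    a sign flag — no pseudocount is applied.
    """
    if isinstance(female, pd.DataFrame):
        female = female.mean(axis=1)
    records = []
    for region_id in female.index:
        f = float(female[region_id])
        m = float(male_reference.get(region_id, math.nan))
        if math.isnan(f) or math.isnan(m) or m <= 0:
            continue
        ratio = (f - m) / m
        negative = f < m
        log2 = math.log2(ratio) if f > m else math.nan
        records.append(FoldChangeRecord(str(region_id), mark, f, m, ratio, log2, negative))
    return records


def fold_change_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region_id": r.region_id, "mark": r.mark, "female_value": r.female_value,
        "male_value": r.male_value, "xi_xa": r.xi_xa, "log2_xi_xa": r.log2_xi_xa,
        "negative_difference": r.negative_difference} for r in records])


def group_compare(values: pd.DataFrame, groups: Mapping[str, str],
                  group_a: str, group_b: str, alpha: float = 0.01,
                  correct: bool = True) -> pd.DataFrame:
    """Welch t-test per feature (row) between two sample groups, BH-adjusted.

    One call is one multiple-testing family (one per mark x comparison).
    ``correct=False`` with ``alpha=0.05`` is the mode used for the small
    expression-based variable-gene tests, where sample sizes of 2-3 per
    status make correction overly conservative.  Features with fewer than
    two values in either group are skipped.
    """
    cols_a = [s for s in values.columns if groups.get(s) == group_a]
    cols_b = [s for s in values.columns if groups.get(s) == group_b]
    rows = []
    for feature in values.index:
        a = values.loc[feature, cols_a].dropna().to_numpy(dtype=float)
        b = values.loc[feature, cols_b].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            t = 0.0 if p == 1.0 else math.inf
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((feature, float(t), float(p), float(np.mean(a) - np.mean(b)),
                     len(a), len(b)))
    out = pd.DataFrame(rows, columns=["feature", "t_stat", "p_raw", "direction",
                                      "n_a", "n_b"])
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    if correct:
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p_raw"]
    out["significant"] = out["p_adj"] < alpha
    return out


def sex_significance_fraction(tests: pd.DataFrame,
                              meta_status: Mapping[str, str]) -> pd.Series:
    """Fraction of informative transcripts significant, per XCI meta-status."""
    tests = tests.copy()
    tests["meta"] = tests["feature"].map(lambda f: meta_status.get(f, "unknown"))
    return tests.groupby("meta")["significant"].mean()


def metagene_profile(tracks: Mapping[str, SignalTrack] | SignalTrack,
                     genes: Sequence[GeneAnnotation], flank: int = 50_000,
                     body_bins: int = 100, flank_bins: int = 50,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD signal profile across genes, 5'->3' left to right.

    Gene bodies are length-scaled into ``body_bins`` bins; each flank is
    split into ``flank_bins`` fixed-width bins of ``flank/flank_bins``
    bases.  Minus-strand genes are flipped so upstream is always on the
    left.  Returns ``(mean, sd)`` arrays of length
    ``2 * flank_bins + body_bins``; bins with no data anywhere are NaN.
    """
    if isinstance(tracks, SignalTrack):
        tracks = {"": tracks}
    n_bins = 2 * flank_bins + body_bins
    flank_width = flank / flank_bins
    per_gene = []
    for g in genes:
        profile = np.full(n_bins, np.nan)
        body_width = (g.end - g.start) / body_bins
        edges = []
        for i in range(flank_bins):  # upstream-in-genome-coordinates flank
            edges.append((g.start - flank + i * flank_width,
                          g.start - flank + (i + 1) * flank_width))
        for i in range(body_bins):
            edges.append((g.start + i * body_width, g.start + (i + 1) * body_width))
        for i in range(flank_bins):
            edges.append((g.end + i * flank_width, g.end + (i + 1) * flank_width))
        gene_vals = []
        for track in tracks.values():
            vals = np.full(n_bins, np.nan)
            for i, (s, e) in enumerate(edges):
                s_i, e_i = int(round(s)), int(round(e))
                if e_i > s_i and s_i >= 0:
                    vals[i] = track.mean_over(g.chrom, s_i, e_i)
            gene_vals.append(vals)
        profile = np.nanmean(np.vstack(gene_vals), axis=0) if gene_vals else profile
        if g.strand == "-":
            profile = profile[::-1]
        per_gene.append(profile)
    stack = np.vstack(per_gene)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0)
    return mean, sd


def enrichment_chi2(tables: Mapping[str, np.ndarray], alpha: float = 0.01) -> pd.DataFrame:
    """Pearson chi-square (no continuity correction) per 2x2 table, BH across marks."""
    rows = []
    for mark, table in tables.items():
        table = np.asarray(table, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("expected 2x2 contingency tables")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append((mark, float(chi2), float(p)))
    out = pd.DataFrame(rows, columns=["mark", "chi2", "p_raw"])
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
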