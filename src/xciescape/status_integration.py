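"""Cross-method reconciliation and variable-escape typing.

Calls from different methods (allelic expression, promoter DNAme, the
ensemble predictor) are cross-tabulated, variable escape is classified by
where the variation lives (across the dataset, between tissues, between
TSSs of one gene, or within one tissue), and epigenetic marks are tested
for differences between the samples in which a variable gene escapes and
those in which it is silenced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chromatin_signal import group_compare
from .epigenetic_predictor import PredictorConfig, aggregate_samples

CONSTITUTIVE = {"escape", "subject"}


@dataclass
class CallSet:
    """One method's per-sample call table plus its overall per-transcript calls.

    ``per_sample``: columns transcript_id (or gene_id), sample_id, status.
    ``overall``: columns transcript_id, status — one row per transcript.
    """

    method: str
    per_sample: pd.DataFrame
    overall: pd.DataFrame

    def __post_init__(self):
        if self.overall["transcript_id"].duplicated().any():
            raise ValueError("one overall call per transcript required")


def _collapse(status: str) -> str | None:
    """Collapse to {escape, subject, variable}; leaning/uninformative -> None."""
    if status in CONSTITUTIVE or status == "variable":
        return status
    return None


def concordance(a: CallSet, b: CallSet) -> dict:
    """Cross-tabulation and agreement fraction between two call sets.

    Statuses are collapsed to escape/subject/variable; transcripts where
    either method gives a leaning or uninformative call leave the
    denominator.  An empty denominator reports agreement as NaN.
    """
    left = a.overall.set_index("transcript_id")["status"].map(_collapse).dropna()
    right = b.overall.set_index("transcript_id")["status"].map(_collapse).dropna()
    shared = left.index.intersection(right.index)
    table = pd.crosstab(left.loc[shared].rename(a.method),
                        right.loc[shared].rename(b.method))
    agreement = float((left.loc[shared] == right.loc[shared]).mean()) \
        if len(shared) else math.nan
    return {"table": table, "agreement": agreement, "n_shared": len(shared)}


def classify_variable_type(per_sample: pd.DataFrame,
                           tissue_of: Mapping[str, str],
                           transcript_to_gene: Mapping[str, str],
                           frac_each: float = 1.0 / 3.0,
                           cfg: PredictorConfig | None = None) -> pd.DataFrame:
    """Tag each gene with the scope(s) at which its escape varies.

    - ``across_dataset``: the 33%-each rule over all samples.
    - ``across_tissues``: constitutive per-tissue consensus statuses that
      differ between at least two tissues (a tissue needs >= 2 informative
      samples to yield a consensus).
    - ``between_TSSs``: two transcripts of one gene with opposite
      constitutive consensus.
    - ``within_tissue:<t>``: the 33% rule restricted to one tissue.

    A gene may carry several tags.  ``per_sample`` needs columns
    transcript_id, sample_id, status.
    """
    cfg = cfg or PredictorConfig(agg_variable_frac=frac_each)
    df = per_sample.copy()
    df["gene_id"] = df["transcript_id"].map(transcript_to_gene)
    df["tissue"] = df["sample_id"].map(tissue_of)
    rows = []
    for gene_id, gsub in df.groupby("gene_id"):
        tags = []
        statuses = gsub["status"].tolist()
        if _variable_rule(statuses, frac_each):
            tags.append("across_dataset")
        # per-tissue consensus (constitutive only)
        consensus = {}
        for tissue, tsub in gsub.groupby("tissue"):
            informative = [s for s in tsub["status"] if s != "uninformative"]
            if len(informative) < 2:
                continue
            agg = aggregate_samples(tsub["status"].tolist(), cfg)
            if agg in CONSTITUTIVE:
                consensus[tissue] = agg
            if _variable_rule(tsub["status"].tolist(), frac_each):
                tags.append(f"within_tissue:{tissue}")
        if len(set(consensus.values())) > 1:
            tags.append("across_tissues")
        # between-TSS: opposite constitutive consensus for two transcripts
        tss_consensus = set()
        for _tid, tsub in gsub.groupby("transcript_id"):
            agg = aggregate_samples(tsub["status"].tolist(), cfg)
            if agg in CONSTITUTIVE:
                tss_consensus.add(agg)
        if len(tss_consensus) > 1:
            tags.append("between_TSSs")
        rows.append((gene_id, tags))
    return pd.DataFrame(rows, columns=["gene_id", "tags"])


def _variable_rule(statuses: Sequence[str], frac_each: float) -> bool:
    n = len([s for s in statuses if s != "uninformative"])
    if n == 0:
        return False
    e = list(statuses).count("escape") / n
    s = list(statuses).count("subject") / n
    return e >= frac_each and s >= frac_each


def variable_gene_mark_test(mark_values: Mapping[str, pd.DataFrame],
                            per_sample_status: pd.DataFrame,
                            mode: str = "corrected_0.01") -> pd.DataFrame:
    """Welch t-test per gene per mark: escaping samples vs subject samples.

    ``mark_values`` maps mark -> (transcript x sample) matrix;
    ``per_sample_status`` has columns transcript_id, sample_id, status.
    ``mode`` "corrected_0.01" applies BH within each mark's family at
    alpha 0.01 (the DNAme/predictor-based analyses); "uncorrected_0.05" is
    the small-n expression-based mode.  Direction is escape mean minus
    subject mean.
    """
    if mode == "corrected_0.01":
        alpha, correct = 0.01, True
    elif mode == "uncorrected_0.05":
        alpha, correct = 0.05, False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    status_of = per_sample_status.set_index(["transcript_id", "sample_id"])["status"]
    frames = []
    for mark, values in mark_values.items():
        rows = []
        for tid in values.index:
            groups = {}
            for sid in values.columns:
                st = status_of.get((tid, sid))
                if st in CONSTITUTIVE:
                    groups[sid] = st
            row = values.loc[[tid]]
            res = group_compare(row, groups, "escape", "subject",
                                alpha=alpha, correct=False)
            if not res.empty:
                rows.append((tid, mark, res["p_raw"].iloc[0],
                             res["direction"].iloc[0]))
        frame = pd.DataFrame(rows, columns=["transcript_id", "mark", "p_raw",
                                            "direction"])
        if correct and not frame.empty:
            from statsmodels.stats.multitest import multipletests
            frame["p_adj"] = multipletests(frame["p_raw"], method="fdr_bh")[1]
        else:
            frame["p_adj"] = frame["p_raw"]
        frame["significant"] = frame["p_adj"] < alpha
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "mark", "p_raw",
                                     "direction", "p_adj", "significant"])
    return pd.concat(frames, ignore_index=True)


def summary_tables(variable_tags: pd.DataFrame, tests: pd.DataFrame,
                   transcript_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Percent of variable genes per category with a significant mark difference.

    Rows are variable-escape categories, columns are marks; a cell is
    significant genes / genes tested for that mark (genes lacking the
    mark's data leave the denominator).
    """
    tests = tests.copy()
    tests["gene_id"] = tests["transcript_id"].map(transcript_to_gene)
    categories = sorted({t for tags in variable_tags["tags"] for t in tags})
    marks = sorted(tests["mark"].unique())
    out = pd.DataFrame(index=categories, columns=marks, dtype=float)
    counts = pd.Series(index=categories, dtype=int)
    for cat in categories:
        genes = set(variable_tags.loc[variable_tags["tags"].map(lambda t: cat in t),
                                      "gene_id"])
        counts[cat] = len(genes)
        sub = tests[tests["gene_id"].isin(genes)]
        for mark in marks:
            msub = sub[sub["mark"] == mark]
            tested = msub["gene_id"].nunique()
            if tested == 0:
                out.loc[cat, mark] = math.nan
                continue
            sig = msub.loc[msub["significant"], "gene_id"].nunique()
            out.loc[cat, mark] = 100.0 * sig / tested
    out.insert(0, "n_genes", counts)
    out.index.name = "category"
    return out
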