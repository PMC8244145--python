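"""Ensemble XCI-status predictor from combined epigenetic marks.

For each female sample, a feature vector per transcript holds the seven
marks (six histone marks + DNAme) in that sample plus the mean of the same
seven marks across similar male samples — 14 features.  "Similar males"
come from k-means clustering of all samples on autosomal mark levels.
Twenty bagged-tree classifiers are trained per sample on known
escape/subject labels, each on a fresh draw of 75% of the escape genes and
twice as many subject genes; calls need 15+ of 20 model votes, with 12-14
votes annotated as a tentative "leaning" status.  Overall calls aggregate
per-sample statuses across samples (66% constitutive / 33%-each variable).
A mean-plus/minus-2SD simple threshold classifier is kept as the baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .chromatin_signal import MARKS, MarkMatrix

logger = logging.getLogger(__name__)


@dataclass
class PredictorConfig:
    n_models: int = 20
    n_trees: int = 1500
    escape_train_frac: float = 0.75
    subject_multiplier: int = 2
    holdout_per_class: int = 3
    vote_call_min: int = 15
    vote_lean_min: int = 12
    agg_constitutive_frac: float = 0.66
    agg_variable_frac: float = 1.0 / 3.0
    k_clusters: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.vote_lean_min < self.vote_call_min <= self.n_models:
            raise ValueError("need vote_lean_min < vote_call_min <= n_models")
        for name in ("escape_train_frac", "agg_constitutive_frac", "agg_variable_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class VoteResult:
    transcript_id: str
    sample_id: str
    votes_escape: int
    status: str
    model_accuracies: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Ensemble:
    """Twenty fitted classifiers for one sample plus their bookkeeping."""

    models: list[RandomForestClassifier]
    feature_names: list[str]
    holdout_escape: list[str]
    holdout_subject: list[str]
    train_ids: list[set[str]]            # per-model drawn transcript ids
    model_accuracies: list[tuple[float, float]]  # (escape, subject) held-out acc
    max_features: int
    cfg: PredictorConfig


# ---------------------------------------------------------------------------
# Sample pairing
# ---------------------------------------------------------------------------

def pair_female_male(autosomal: pd.DataFrame, sex: Mapping[str, str],
                     k: int = 3, seed: int = 0) -> dict[str, list[str]]:
    """Pair each female with the males in her autosomal k-means cluster.

    ``autosomal`` is sample x mark mean levels; columns are standardised
    before clustering.  A cluster without males falls back to the global
    male set (logged).  No males at all is an error.
    """
    males = [s for s in autosomal.index if sex.get(s) == "male"]
    females = [s for s in autosomal.index if sex.get(s) == "female"]
    if not males:
        raise ValueError("no male samples available for pairing")
    values = autosomal.to_numpy(dtype=float)
    std = values.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    z = (values - values.mean(axis=0)) / std
    k_eff = min(k, len(autosomal))
    labels = KMeans(n_clusters=k_eff, random_state=seed, n_init=10).fit_predict(z)
    cluster_of = dict(zip(autosomal.index, labels))
    males_by_cluster: dict[int, list[str]] = {}
    for m in males:
        males_by_cluster.setdefault(cluster_of[m], []).append(m)
    pairing = {}
    for f in females:
        cluster_males = males_by_cluster.get(cluster_of[f])
        if not cluster_males:
            logger.info("cluster of %s has no males; using global male mean", f)
            cluster_males = list(males)
        pairing[f] = cluster_males
    return pairing


def build_features(marks: Mapping[str, MarkMatrix], female_id: str,
                   male_ids: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript x 14 feature table for one female sample.

    Seven female columns (``<mark>_F``) and seven paired-male-mean columns
    (``<mark>_M``).  Missing values are imputed with the sample-wide median
    of the feature; the returned boolean frame flags what was imputed.
    """
    cols = {}
    for mark in MARKS:
        mm = marks[mark]
        cols[f"{mark}_F"] = mm.values[female_id]
        cols[f"{mark}_M"] = mm.values[list(male_ids)].mean(axis=1)
    feats = pd.DataFrame(cols)
    imputed = feats.isna()
    feats = feats.fillna(feats.median())
    return feats, imputed


# ---------------------------------------------------------------------------
# Ensemble training
# ---------------------------------------------------------------------------

def _tune_max_features(x: np.ndarray, y: np.ndarray, cfg: PredictorConfig,
                       rng: np.random.Generator) -> int:
    """Pick features-per-split from 5 evenly spaced values by out-of-bag AUC.

    The search forests are capped at 300 trees: the OOB AUC ranking is
    stable well below the production tree count.
    """
    import warnings
    n_feat = x.shape[1]
    grid = sorted({max(1, int(round(v))) for v in np.linspace(1, n_feat, 5)})
    best, best_auc = grid[0], -np.inf
    for mf in grid:
        clf = RandomForestClassifier(
            n_estimators=min(cfg.n_trees, 300), max_features=mf, oob_score=True,
            bootstrap=True, random_state=int(rng.integers(2**31 - 1)), n_jobs=1)
        with warnings.catch_warnings():
            # tiny test forests can miss OOB coverage for a few genes
            warnings.simplefilter("ignore", UserWarning)
            clf.fit(x, y)
        oob = clf.oob_decision_function_[:, list(clf.classes_).index("escape")]
        mask = ~np.isnan(oob)
        try:
            auc = roc_auc_score((y[mask] == "escape").astype(int), oob[mask])
        except ValueError:
            auc = 0.5
        if auc > best_auc:
            best, best_auc = mf, auc
    return best


def train_ensemble(features: pd.DataFrame, labels: Mapping[str, str],
                   cfg: PredictorConfig | None = None) -> Ensemble:
    """Train the 20-model ensemble for one sample.

    A fixed global holdout of ``holdout_per_class`` escape and subject
    genes is removed first and never trained on.  Each model then draws,
    without replacement and fresh per model, floor(75% of remaining escape
    genes) escape genes and twice that count of subject genes.  Per-model
    accuracy is recorded on the labelled genes that model did not draw.
    """
    cfg = cfg or PredictorConfig()
    rng = np.random.default_rng(cfg.seed)
    escape_ids = sorted(t for t in features.index if labels.get(t) == "escape")
    subject_ids = sorted(t for t in features.index if labels.get(t) == "subject")
    need_escape = cfg.holdout_per_class + 4
    if len(escape_ids) < need_escape:
        raise ValueError(f"need at least {need_escape} labelled escape genes, "
                         f"have {len(escape_ids)}")
    if len(subject_ids) < cfg.holdout_per_class + 4:
        raise ValueError(f"need at least {cfg.holdout_per_class + 4} labelled "
                         f"subject genes, have {len(subject_ids)}")

    holdout_e = list(rng.choice(escape_ids, size=cfg.holdout_per_class, replace=False))
    holdout_s = list(rng.choice(subject_ids, size=cfg.holdout_per_class, replace=False))
    pool_e = [t for t in escape_ids if t not in holdout_e]
    pool_s = [t for t in subject_ids if t not in holdout_s]
    n_draw_e = int(math.floor(cfg.escape_train_frac * len(pool_e)))
    n_draw_s = min(cfg.subject_multiplier * n_draw_e, len(pool_s))
    if n_draw_e < 2:
        raise ValueError("too few escape genes remain after the holdout")

    pool_ids = pool_e + pool_s
    pool_x = features.loc[pool_ids].to_numpy(dtype=float)
    pool_y = np.array([labels[t] for t in pool_ids])
    max_features = _tune_max_features(pool_x, pool_y, cfg, rng)

    models, train_ids, accuracies = [], [], []
    for _ in range(cfg.n_models):
        draw_e = list(rng.choice(pool_e, size=n_draw_e, replace=False))
        draw_s = list(rng.choice(pool_s, size=n_draw_s, replace=False))
        drawn = draw_e + draw_s
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1)
        clf.fit(features.loc[drawn].to_numpy(dtype=float),
                np.array([labels[t] for t in drawn]))
        rest_e = [t for t in pool_e if t not in set(draw_e)] + holdout_e
        rest_s = [t for t in pool_s if t not in set(draw_s)] + holdout_s
        acc = []
        for rest, cls in ((rest_e, "escape"), (rest_s, "subject")):
            if rest:
                pred = clf.predict(features.loc[rest].to_numpy(dtype=float))
                acc.append(float(np.mean(pred == cls)))
            else:
                acc.append(math.nan)
        models.append(clf)
        train_ids.append(set(drawn))
        accuracies.append((acc[0], acc[1]))
    return Ensemble(models, list(features.columns), holdout_e, holdout_s,
                    train_ids, accuracies, max_features, cfg)


def vote_call(votes_escape: int, cfg: PredictorConfig | None = None) -> str:
    """Status from the escape-vote count out of ``n_models``.

    15+ of 20 on either side is a firm call, 12-14 a leaning call, and a
    10-11/10-9 split is inconsistent (returned as "uninformative").
    """
    cfg = cfg or PredictorConfig()
    if not 0 <= votes_escape <= cfg.n_models:
        raise ValueError("vote count out of range")
    votes_subject = cfg.n_models - votes_escape
    if votes_escape >= cfg.vote_call_min:
        return "escape"
    if votes_subject >= cfg.vote_call_min:
        return "subject"
    if votes_escape >= cfg.vote_lean_min:
        return "leaning_escape"
    if votes_subject >= cfg.vote_lean_min:
        return "leaning_subject"
    return "uninformative"


def predict_sample(ensemble: Ensemble, features: pd.DataFrame,
                   sample_id: str = "") -> pd.DataFrame:
    """Apply the 20-model vote machinery to a feature table.

    Each model votes escape when its escape class probability reaches 0.5.
    Works unchanged for cross-sample application — pass another sample's
    features.
    """
    x = features[ensemble.feature_names].to_numpy(dtype=float)
    votes = np.zeros(len(features), dtype=int)
    for clf in ensemble.models:
        idx = list(clf.classes_).index("escape")
        votes += (clf.predict_proba(x)[:, idx] >= 0.5).astype(int)
    cfg = ensemble.cfg
    out = pd.DataFrame({
        "transcript_id": features.index,
        "sample_id": sample_id,
        "votes_escape": votes,
        "status": [vote_call(int(v), cfg) for v in votes]})
    return out


cross_sample_apply = predict_sample  # identical machinery on foreign features


def aggregate_samples(statuses: Sequence[str],
                      cfg: PredictorConfig | None = None) -> str:
    """Overall call across samples for one transcript.

    Denominator: every sample with a vote result, inconsistent included.
    Firm fractions are tested first (constitutive at >= 66%, variable at
    >= 33% each); only if neither rule fires are leaning votes folded into
    their side and the 66% rule retried, yielding a leaning status.
    """
    cfg = cfg or PredictorConfig()
    n = len(statuses)
    if n == 0:
        return "uninformative"
    frac = lambda *names: sum(statuses.count(s) for s in names) / n
    firm_e, firm_s = frac("escape"), frac("subject")
    if firm_e >= cfg.agg_constitutive_frac:
        return "escape"
    if firm_s >= cfg.agg_constitutive_frac:
        return "subject"
    if firm_e >= cfg.agg_variable_frac and firm_s >= cfg.agg_variable_frac:
        return "variable"
    if frac("escape", "leaning_escape") >= cfg.agg_constitutive_frac:
        return "leaning_escape"
    if frac("subject", "leaning_subject") >= cfg.agg_constitutive_frac:
        return "leaning_subject"
    return "uninformative"


def variable_threshold_sweep(per_sample: Mapping[str, Sequence[str]],
                             fractions: Sequence[float]) -> dict[float, int]:
    """Variable-gene counts as the each-status fraction threshold is varied.

    Re-runs only the variable rule (both firm statuses reaching the
    fraction); counts are monotone non-increasing in the threshold.
    """
    counts = {}
    for f in fractions:
        c = 0
        for statuses in per_sample.values():
            n = len(statuses)
            if n == 0:
                continue
            if (list(statuses).count("escape") / n >= f
                    and list(statuses).count("subject") / n >= f):
                c += 1
        counts[f] = c
    return counts


def feature_importance_ranks(ensemble: Ensemble) -> pd.Series:
    """Mean importance rank per feature across models (14 = most important).

    Within each model the features are ranked by impurity importance, ties
    broken by feature order (earlier feature gets the lower rank).
    """
    n_feat = len(ensemble.feature_names)
    total = np.zeros(n_feat)
    for clf in ensemble.models:
        order = np.argsort(clf.feature_importances_, kind="stable")
        ranks = np.empty(n_feat)
        ranks[order] = np.arange(1, n_feat + 1)
        total += ranks
    return pd.Series(total / len(ensemble.models), index=ensemble.feature_names,
                     name="mean_rank").sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Simple 2-SD baseline
# ---------------------------------------------------------------------------

@dataclass
class SimpleThresholdRule:
    """Mean +/- 2SD class bands, or a midpoint threshold when the bands overlap."""

    mean_escape: float
    sd_escape: float
    mean_subject: float
    sd_subject: float

    @property
    def bands_overlap(self) -> bool:
        lo_e, hi_e = self.mean_escape - 2 * self.sd_escape, self.mean_escape + 2 * self.sd_escape
        lo_s, hi_s = self.mean_subject - 2 * self.sd_subject, self.mean_subject + 2 * self.sd_subject
        return lo_e <= hi_s and lo_s <= hi_e

    @property
    def midpoint(self) -> float:
        return (self.mean_escape + self.mean_subject) / 2.0

    def classify(self, value: float) -> str | None:
        if self.bands_overlap:
            # sides by class-mean order; the exact midpoint goes to the
            # lower-mean class (documented tie-break)
            low_class = ("escape" if self.mean_escape <= self.mean_subject
                         else "subject")
            high_class = "subject" if low_class == "escape" else "escape"
            return low_class if value <= self.midpoint else high_class
        in_e = abs(value - self.mean_escape) <= 2 * self.sd_escape
        in_s = abs(value - self.mean_subject) <= 2 * self.sd_subject
        if in_e and not in_s:
            return "escape"
        if in_s and not in_e:
            return "subject"
        return None


def simple_threshold_classifier(escape_values: Sequence[float],
                                subject_values: Sequence[float]) -> SimpleThresholdRule:
    e = np.asarray(escape_values, dtype=float)
    s = np.asarray(subject_values, dtype=float)
    if len(e) < 2 or len(s) < 2:
        raise ValueError("need at least two training values per class")
    return SimpleThresholdRule(float(e.mean()), float(e.std(ddof=1)),
                               float(s.mean()), float(s.std(ddof=1)))
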