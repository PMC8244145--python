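"""Vote rules, aggregation, ensemble training, pairing and the 2-SD baseline."""

import numpy as np
import pandas as pd
import pytest

from xciescape import epigenetic_predictor as ep

FAST = ep.PredictorConfig(n_trees=25, seed=3)


def vote_oracle(v, n=20, call_min=15, lean_min=12):
    """Independently coded enumeration of the vote rule."""
    s = n - v
    if v >= call_min:
        return "escape"
    if s >= call_min:
        return "subject"
    if v >= lean_min:
        return "leaning_escape"
    if s >= lean_min:
        return "leaning_subject"
    return "uninformative"


def aggregate_oracle(statuses, const=0.66, var=1 / 3):
    n = len(statuses)
    if n == 0:
        return "uninformative"
    c = statuses.count
    if c("escape") / n >= const:
        return "escape"
    if c("subject") / n >= const:
        return "subject"
    if c("escape") / n >= var and c("subject") / n >= var:
        return "variable"
    if (c("escape") + c("leaning_escape")) / n >= const:
        return "leaning_escape"
    if (c("subject") + c("leaning_subject")) / n >= const:
        return "leaning_subject"
    return "uninformative"


class TestVoteCall:
    def test_all_vote_counts_match_oracle(self):
        for v in range(21):
            assert ep.vote_call(v) == vote_oracle(v)

    @pytest.mark.parametrize("votes,status", [
        (17, "escape"), (13, "leaning_escape"), (10, "uninformative"),
        (11, "uninformative"), (7, "leaning_subject"), (3, "subject"),
    ])
    def test_examples(self, votes, status):
        assert ep.vote_call(votes) == status


class TestAggregateSamples:
    @pytest.mark.parametrize("statuses,expected", [
        (["escape"] * 8 + ["subject"] * 2, "escape"),
        (["escape"] * 4 + ["subject"] * 4 + ["uninformative"] * 2, "variable"),
        (["escape"] * 6 + ["leaning_escape"] + ["uninformative"] * 3,
         "leaning_escape"),  # firm 60% < 66%, with leaning 70% >= 66%
    ])
    def test_spec_examples(self, statuses, expected):
        assert ep.aggregate_samples(statuses) == expected

    def test_enumeration_against_oracle(self):
        """All status compositions over up to 8 samples."""
        from itertools import combinations_with_replacement
        opts = ["escape", "subject", "leaning_escape", "leaning_subject",
                "uninformative"]
        for n in range(1, 9):
            for combo in combinations_with_replacement(opts, n):
                assert ep.aggregate_samples(list(combo)) == \
                    aggregate_oracle(list(combo)), combo


class TestSweep:
    def test_monotone_and_pigeonhole(self):
        per_sample = {
            "g1": ["escape"] * 5 + ["subject"] * 5,
            "g2": ["escape"] * 2 + ["subject"] * 8,
            "g3": ["escape"] * 1 + ["subject"] * 9,
        }
        fractions = [0.05, 0.1, 0.25, 1 / 3, 0.5, 0.51]
        counts = ep.variable_threshold_sweep(per_sample, fractions)
        vals = [counts[f] for f in fractions]
        assert vals == sorted(vals, reverse=True)
        assert counts[0.5] == 1      # only the 50:50 gene
        assert counts[0.51] == 0     # no gene can have both sides > half
        assert counts[0.1] == 3


class TestPairing:
    def _autosomal(self):
        rows = {}
        for i in range(4):   # blob at 0
            rows[f"F{i}"] = np.zeros(7)
            rows[f"M{i}"] = np.zeros(7) + 0.01
        for i in range(4, 8):  # blob at 5
            rows[f"F{i}"] = np.full(7, 5.0)
            rows[f"M{i}"] = np.full(7, 5.01)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"mk{j}" for j in range(7)])

    def test_females_pair_within_their_blob(self):
        auto = self._autosomal()
        sex = {s: ("female" if s.startswith("F") else "male") for s in auto.index}
        pairing = ep.pair_female_male(auto, sex, k=2, seed=0)
        for f, males in pairing.items():
            i = int(f[1:])
            expected = {f"M{j}" for j in (range(4) if i < 4 else range(4, 8))}
            assert set(males) == expected

    def test_same_seed_identical(self):
        auto = self._autosomal()
        sex = {s: ("female" if s.startswith("F") else "male") for s in auto.index}
        assert ep.pair_female_male(auto, sex, seed=5) == \
            ep.pair_female_male(auto, sex, seed=5)

    def test_no_males_is_an_error(self):
        auto = self._autosomal()
        with pytest.raises(ValueError, match="male"):
            ep.pair_female_male(auto, {s: "female" for s in auto.index})


def separable_features(n_escape=46, n_subject=120, noise=0.05, seed=9,
                       shuffle_labels=False):
    rng = np.random.default_rng(seed)
    ids = [f"e{i}" for i in range(n_escape)] + [f"s{i}" for i in range(n_subject)]
    labels = {t: ("escape" if t.startswith("e") else "subject") for t in ids}
    centre = np.array([0.0 if t.startswith("e") else 1.0 for t in ids])
    x = rng.normal(0, noise, size=(len(ids), 14)) + centre[:, None]
    if shuffle_labels:
        vals = list(labels.values())
        rng.shuffle(vals)
        labels = dict(zip(ids, vals))
    cols = [f"f{j}" for j in range(14)]
    return pd.DataFrame(x, index=ids, columns=cols), labels


class TestTrainEnsemble:
    def test_draw_sizes_follow_75_percent_and_double_rule(self):
        feats, labels = separable_features(n_escape=46, n_subject=120)
        ens = ep.train_ensemble(feats, labels, FAST)
        # 46 escape - 3 holdout = 43; floor(0.75 * 43) = 32 escape + 64 subject
        for drawn in ens.train_ids:
            es = [t for t in drawn if labels[t] == "escape"]
            su = [t for t in drawn if labels[t] == "subject"]
            assert (len(es), len(su)) == (32, 64)
        assert len(ens.models) == 20

    def test_separable_features_perfect_heldout_accuracy(self):
        feats, labels = separable_features()
        ens = ep.train_ensemble(feats, labels, FAST)
        for acc_e, acc_s in ens.model_accuracies:
            assert acc_e == 1.0 and acc_s == 1.0

    def test_label_shuffle_gives_chance_level_accuracy(self):
        """Shuffled labels: held-out accuracy inside a wide binomial null band."""
        feats, labels = separable_features(shuffle_labels=True)
        ens = ep.train_ensemble(feats, labels, FAST)
        mean_acc = np.mean([a for pair in ens.model_accuracies for a in pair])
        assert 0.05 < mean_acc < 0.95

    def test_too_few_escape_genes_error_names_deficit(self):
        feats, labels = separable_features(n_escape=5)
        with pytest.raises(ValueError, match="escape"):
            ep.train_ensemble(feats, labels, FAST)

    def test_deterministic_under_seed(self):
        feats, labels = separable_features()
        e1 = ep.train_ensemble(feats, labels, FAST)
        e2 = ep.train_ensemble(feats, labels, FAST)
        v1 = ep.predict_sample(e1, feats)["votes_escape"]
        v2 = ep.predict_sample(e2, feats)["votes_escape"]
        assert (v1 == v2).all()
        assert e1.train_ids == e2.train_ids


class TestPrediction:
    def test_identity_cross_sample_application(self):
        feats, labels = separable_features()
        ens = ep.train_ensemble(feats, labels, FAST)
        own = ep.predict_sample(ens, feats, "A")
        foreign = ep.cross_sample_apply(ens, feats, "B")
        assert (own["votes_escape"] == foreign["votes_escape"]).all()

    def test_inverted_features_degrade_accuracy(self):
        feats, labels = separable_features()
        ens = ep.train_ensemble(feats, labels, FAST)
        own = ep.predict_sample(ens, feats)
        inverted = ep.predict_sample(ens, 1.0 - feats)
        y = np.array([labels[t] == "escape" for t in feats.index])
        acc_own = np.mean((own["votes_escape"] >= 15) == y)
        acc_inv = np.mean((inverted["votes_escape"] >= 15) == y)
        assert acc_inv < acc_own


class TestImportanceRanks:
    def test_single_informative_feature_ranks_top(self):
        rng = np.random.default_rng(4)
        ids = [f"t{i}" for i in range(120)]
        labels = {t: ("escape" if i < 40 else "subject") for i, t in enumerate(ids)}
        x = rng.normal(size=(120, 14))
        x[:, 5] = [0.0 if labels[t] == "escape" else 1.0 for t in ids]
        feats = pd.DataFrame(x, index=ids, columns=[f"f{j}" for j in range(14)])
        ens = ep.train_ensemble(feats, labels, FAST)
        ranks = ep.feature_importance_ranks(ens)
        assert ranks.idxmax() == "f5"
        assert ranks["f5"] == pytest.approx(14.0, abs=0.2)

    def test_all_noise_features_average_mid_rank(self):
        feats, labels = separable_features(noise=1000.0)  # signal drowned
        ens = ep.train_ensemble(feats, labels, FAST)
        ranks = ep.feature_importance_ranks(ens)
        assert ranks.mean() == pytest.approx(7.5)  # ranks always sum to 105


class TestSimpleThreshold:
    def test_disjoint_bands(self):
        rule = ep.simple_threshold_classifier([0, 0.5, -0.5, 0.2, -0.2],
                                              [10, 10.5, 9.5, 10.2, 9.8])
        assert not rule.bands_overlap
        assert rule.classify(9.6) == "subject"
        assert rule.classify(0.1) == "escape"
        assert rule.classify(5.0) is None

    def test_overlapping_bands_use_midpoint(self):
        rule = ep.simple_threshold_classifier([0.5, 1.0, 1.5], [1.5, 2.0, 2.5])
        assert rule.bands_overlap
        assert rule.midpoint == pytest.approx(1.5)
        assert rule.classify(1.4) == "escape"
        assert rule.classify(1.6) == "subject"
        assert rule.classify(1.5) == "escape"  # midpoint goes to lower-mean class
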