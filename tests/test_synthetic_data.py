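"""Generator determinism and fidelity to its configured conditions."""

import numpy as np
import pandas as pd
import pytest

from xciescape import synthetic_data as sd

SEED = 424242


def small_cfg(**kw):
    base = dict(seed=SEED, n_genes=40, n_samples_female=6, n_samples_male=3)
    base.update(kw)
    return sd.SimConfig(**base)


class TestTruth:
    def test_same_seed_bit_identical(self):
        t1 = sd.simulate_truth(small_cfg())
        t2 = sd.simulate_truth(small_cfg())
        pd.testing.assert_frame_equal(t1.states, t2.states)
        pd.testing.assert_frame_equal(t1.planted_genotypes, t2.planted_genotypes)
        assert t1.xi_haplotype == t2.xi_haplotype
        c1 = sd.simulate_allelic_counts(t1)
        c2 = sd.simulate_allelic_counts(t2)
        pd.testing.assert_frame_equal(c1, c2)
        m1 = sd.simulate_mark_matrix(t1)
        m2 = sd.simulate_mark_matrix(t2)
        for mark in m1:
            pd.testing.assert_frame_equal(m1[mark].values, m2[mark].values)
        pd.testing.assert_frame_equal(sd.simulate_genotypes(t1),
                                      sd.simulate_genotypes(t2))

    def test_no_variable_genes_means_constant_states(self):
        t = sd.simulate_truth(small_cfg(frac_variable=0.0, frac_subject=0.88,
                                        planted_effects=()))
        assert (t.states.nunique(axis=1) == 1).all()

    def test_degenerate_planted_probability(self):
        eff = sd.PlantedEffect("L", probs=(0.0, 0.0, 1.0))
        t = sd.simulate_truth(small_cfg(n_samples_female=40,
                                        planted_effects=(eff,)))
        (resolved,) = t.planted
        geno = t.planted_genotypes["L"]
        for sid in t.female_ids:
            expected = "escape" if geno[sid] == 2 else "subject"
            assert t.states.loc[resolved.gene_id, sid] == expected

    def test_unknown_planted_gene_rejected(self):
        eff = sd.PlantedEffect("L", probs=(0.5, 0.5, 0.5), gene_id="NOPE")
        with pytest.raises(ValueError, match="unknown gene"):
            sd.simulate_truth(small_cfg(planted_effects=(eff,)))

    def test_skew_fraction_is_a_proportion(self):
        t = sd.simulate_truth(small_cfg(n_samples_female=10, skew_fraction=0.3))
        skewed = [s for s in t.samples if s.sex == "female" and s.skewed_xi]
        assert len(skewed) == 3


class TestAllelicCounts:
    def test_zero_ratio_gives_zero_xi(self):
        cfg = small_cfg(xi_expr_ratio_subject=(0.0, 0.0), frac_escape=0.0,
                        frac_variable=0.0, frac_subject=1.0, skew_fraction=1.0,
                        planted_effects=())
        t = sd.simulate_truth(cfg)
        counts = sd.simulate_allelic_counts(t, depth=100)
        xi = counts.apply(lambda r: r["allele_a"]
                          if t.xi_haplotype[r["sample_id"]] == "A"
                          else r["allele_b"], axis=1)
        assert (xi == 0).all()

    def test_balanced_escape_ratio_approaches_half(self):
        cfg = small_cfg(n_genes=5, xi_expr_ratio_escape=(1.0, 1.0),
                        frac_escape=1.0, frac_subject=0.0, frac_variable=0.0,
                        skew_fraction=1.0, planted_effects=())
        t = sd.simulate_truth(cfg)
        counts = sd.simulate_allelic_counts(t, depth=1e5)
        frac = counts["allele_a"] / (counts["allele_a"] + counts["allele_b"])
        assert np.allclose(frac, 0.5, atol=0.01)

    def test_unskewed_sample_has_no_allelic_imbalance(self):
        cfg = small_cfg(n_genes=5, frac_escape=0.0, frac_variable=0.0,
                        frac_subject=1.0, skew_fraction=0.0, planted_effects=())
        t = sd.simulate_truth(cfg)
        counts = sd.simulate_allelic_counts(t, depth=1e5)
        frac = counts["allele_a"] / (counts["allele_a"] + counts["allele_b"])
        assert np.allclose(frac, 0.5, atol=0.01)

    def test_status_separation_at_depth(self):
        """Escape genes above and subject genes below the proportion threshold."""
        t = sd.simulate_truth(small_cfg(n_genes=200, skew_fraction=1.0))
        counts = sd.simulate_allelic_counts(t, depth=500)
        p_star = 0.1 / 1.1
        for row in counts.itertuples(index=False):
            state = t.states.loc[row.gene_id, row.sample_id]
            hap = t.xi_haplotype[row.sample_id]
            xi = row.allele_a if hap == "A" else row.allele_b
            frac = xi / (row.allele_a + row.allele_b)
            if state == "escape":
                assert frac > p_star * 0.7   # well above silenced levels
            else:
                assert frac < p_star + 0.05


class TestBisulfite:
    def test_extreme_means_give_pure_reads(self):
        cfg = small_cfg(n_genes=6, dname_xi_subject_mean=1.0, dname_xa_mean=0.0,
                        per_cpg_sd=0.0, frac_escape=0.0, frac_variable=0.0,
                        frac_subject=1.0, skew_fraction=1.0, planted_effects=())
        t = sd.simulate_truth(cfg)
        bs = sd.simulate_bisulfite_reads(t)
        fracs = bs.read_table["n_meth"] / bs.read_table["n_total"]
        assert set(np.round(fracs, 6)) <= {0.0, 1.0}

    def test_per_cpg_offsets_create_adjacent_differences(self):
        """Monte-Carlo check: clipped-normal per-CpG offsets yield |delta| > 0."""
        t = sd.simulate_truth(small_cfg(n_genes=20, per_cpg_sd=0.2))
        bs = sd.simulate_bisulfite_reads(t)
        diffs = [np.abs(np.diff(p)).mean() for p in bs.cpg_xi_probs.values()]
        # oracle: E|X-Y| for X,Y ~ clip(N(mu, 0.2)) is comfortably positive
        rng = np.random.default_rng(0)
        x = np.clip(0.8 + rng.normal(0, 0.2, 20000), 0, 1)
        y = np.clip(0.8 + rng.normal(0, 0.2, 20000), 0, 1)
        oracle = np.abs(x - y).mean()
        assert np.mean(diffs) == pytest.approx(oracle, rel=0.25)
        assert np.mean(diffs) > 0.05

    def test_excluded_and_informative_snps_both_generated(self):
        t = sd.simulate_truth(small_cfg(n_genes=100))
        bs = sd.simulate_bisulfite_reads(t)
        pairs = {frozenset((r.ref, r.alt)) for r in bs.snps.itertuples()}
        assert frozenset(("C", "T")) in pairs or frozenset(("G", "A")) in pairs
        assert any(not (p <= {"C", "T"} or p <= {"G", "A"}) for p in pairs)


class TestMarks:
    def test_group_means_match_effect_table(self, default_truth):
        """Configured female/male means recovered within 3 standard errors."""
        marks = sd.simulate_mark_matrix(default_truth)
        states = default_truth.states
        for mark, eff in default_truth.cfg.mark_effects.items():
            values = marks[mark].values
            male = values[default_truth.male_ids].to_numpy().ravel()
            se = eff.sd / np.sqrt(male.size)
            assert abs(male.mean() - eff.xa_mean) < 3 * se + 1e-3
            fem = []
            for sid in default_truth.female_ids:
                for g in default_truth.genes:
                    if states.loc[g.gene_id, sid] == "subject":
                        fem.append(values.loc[g.transcript_id, sid])
            fem = np.asarray(fem)
            expected = eff.xa_mean + eff.xi_subject
            assert abs(fem.mean() - expected) < 3 * eff.sd / np.sqrt(fem.size) + 1e-3

    def test_zero_xi_component_equalizes_sexes(self):
        effects = {m: sd.MarkEffect(1.0, 0.0, 0.0, sd=0.05)
                   for m in sd.DEFAULT_MARK_EFFECTS}
        t = sd.simulate_truth(small_cfg(mark_effects=effects))
        marks = sd.simulate_mark_matrix(t)
        v = marks["H3K27me3"].values
        f = v[t.female_ids].to_numpy().mean()
        m = v[t.male_ids].to_numpy().mean()
        assert abs(f - m) < 0.02


class TestGenotypes:
    def test_hardy_weinberg_het_fraction(self):
        cfg = small_cfg(n_genes=10, n_samples_female=5000, n_samples_male=5000,
                        frac_variable=0.0, frac_subject=0.88, planted_effects=(
                            sd.PlantedEffect("L", (0.5, 0.5, 0.5), "G0000",
                                             allele_freq=0.5),))
        # planted on a non-variable gene id is rejected only if unknown;
        # G0000 exists, the effect simply targets a constitutive gene
        t = sd.simulate_truth(cfg)
        het = (t.planted_genotypes["L"] == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)  # 2pq at p=q=0.5

    def test_zero_allele_frequency_all_reference(self):
        eff = sd.PlantedEffect("L", (0.5, 0.5, 0.5), allele_freq=0.0)
        t = sd.simulate_truth(small_cfg(planted_effects=(eff,)))
        assert (t.planted_genotypes["L"] == 0).all()

    def test_null_loci_independent_of_truth(self):
        """With equal per-genotype probabilities, association p-values are null."""
        from scipy import stats
        eff = sd.PlantedEffect("L", (0.5, 0.5, 0.5))
        cfg = small_cfg(n_genes=10, n_samples_female=500, frac_escape=0.1,
                        frac_subject=0.4, frac_variable=0.5,
                        planted_effects=(eff,))
        t = sd.simulate_truth(cfg)
        (resolved,) = t.planted
        status = t.states.loc[resolved.gene_id, t.female_ids]
        geno = t.planted_genotypes.loc[t.female_ids, "L"]
        table = pd.crosstab(status, geno)
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01
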