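"""DNAme threshold tables, per-read and per-allele profiles, array filters."""

import math

import numpy as np
import pandas as pd
import pytest

from xciescape import methylation as meth


def read(n_meth, n_total, allele=None, snp="rs1", island="i1", rid="r"):
    return meth.MethylRead(rid, island, n_meth, n_total, allele,
                           snp if allele else None)


class TestCallFromDname:
    @pytest.mark.parametrize("female,male,status", [
        (0.05, 0.02, "escape"),
        (0.40, 0.02, "subject"),
        (0.12, 0.02, "intermediate"),    # 10-15% threshold gap
        (0.60, 0.02, "intermediate"),    # exactly at the 60% boundary
        (0.70, 0.02, "hypermethylated"),
        (0.40, 0.20, "uninformative"),   # methylated in males
    ])
    def test_band_examples(self, female, male, status):
        assert meth.call_from_dname(female, male).status == status

    def test_missing_male_uninformative(self):
        call = meth.call_from_dname(0.4, None)
        assert call.status == "uninformative"
        assert "male" in call.detail["reason"]

    def test_grid_matches_rule_table(self):
        """Coarse grid against a directly coded rule table (fine grid elsewhere)."""
        cfg = meth.DnameCallConfig()
        for female in np.round(np.arange(0, 1.001, 0.01), 3):
            for male in (0.0, 0.10, 0.149, 0.15, 0.30):
                got = meth.call_from_dname(float(female), float(male), cfg).status
                if male >= 0.15:
                    want = "uninformative"
                elif female < 0.10:
                    want = "escape"
                elif 0.15 < female < 0.60:
                    want = "subject"
                elif female > 0.60:
                    want = "hypermethylated"
                else:
                    want = "intermediate"
                assert got == want, (female, male)


class TestPerReadProfile:
    def test_two_extreme_reads(self):
        prof = meth.per_read_profile([read(0, 5), read(5, 5)])
        assert prof.mean_dname == 0.5
        assert prof.read_fractions == (0.5, 0.0, 0.5)
        assert prof.bin == 5

    def test_uniform_intermediate_reads(self):
        prof = meth.per_read_profile([read(2, 5)] * 4)
        assert prof.mean_dname == pytest.approx(0.4)
        assert prof.read_fractions[1] == 1.0    # 0.4 is inside 33-66%

    def test_bin_floor_rule_against_oracle(self):
        for m in np.arange(0, 1.0001, 0.05):
            n = int(round(m * 20))
            prof = meth.per_read_profile([read(n, 20)])
            assert prof.bin == min(int(m * 10 + 1e-9), 9)

    def test_fractions_disjoint_and_bounded(self, rng):
        for _ in range(100):
            reads = [read(int(rng.integers(0, 11)), 10) for _ in range(20)]
            fr = meth.per_read_profile(reads).read_fractions
            assert all(0 <= f <= 1 for f in fr)
            assert sum(fr) <= 1 + 1e-12


class TestAllelicCall:
    def _reads(self, mean_ct, mean_ga, n=20):
        out = []
        for i in range(n):
            out.append(read(int(round(mean_ct * 100)), 100, "C", rid=f"c{i}"))
            out.append(read(int(round(mean_ga * 100)), 100, "G", rid=f"g{i}"))
        return out

    @pytest.mark.parametrize("ct,ga,status", [
        (0.05, 0.95, "subject"),
        (0.10, 0.10, "escape"),
        (0.95, 0.90, "hypermethylated"),
        (0.40, 0.90, "uninformative"),
    ])
    def test_threshold_rules(self, ct, ga, status):
        call = meth.allelic_dname_call(self._reads(ct, ga), "C", "G")
        assert call.status == status

    def test_ct_and_ga_polymorphisms_excluded(self):
        for ref, alt in (("C", "T"), ("T", "C"), ("G", "A")):
            call = meth.allelic_dname_call(self._reads(0.1, 0.9), ref, alt)
            assert call.status == "uninformative"
            assert "CT/GA" in call.detail["reason"]

    def test_min_reads_per_allele(self):
        reads = self._reads(0.05, 0.95, n=4)  # below the 5-read floor
        call = meth.allelic_dname_call(reads, "C", "G")
        assert call.status == "uninformative"

    def test_planted_means_called_perfectly(self, rng):
        """Synthetic reads at (0.05, 0.95) -> subject; (0.05, 0.05) -> escape."""
        for mean_ga, expected in ((0.95, "subject"), (0.05, "escape")):
            statuses = []
            for _ in range(50):
                reads = []
                for i in range(25):
                    reads.append(read(int(rng.binomial(10, 0.05)), 10, "C",
                                      rid=f"c{i}"))
                    reads.append(read(int(rng.binomial(10, mean_ga)), 10, "G",
                                      rid=f"g{i}"))
                statuses.append(meth.allelic_dname_call(reads, "C", "G").status)
            assert statuses.count(expected) == len(statuses)


class TestAllelicBinProfile:
    def test_bin_uses_mean_of_allele_means(self):
        prof = meth.allelic_bin_profile(
            [read(0, 10, "C"), read(10, 10, "G")])
        assert prof["bin"] == 5
        assert prof["low_mean"] == 0.0 and prof["high_mean"] == 1.0

    def test_tie_breaks_to_ct_group(self):
        prof = meth.allelic_bin_profile([read(5, 10, "C"), read(5, 10, "G")])
        assert prof["low_allele"] == "CT" and prof["high_allele"] == "GA"

    def test_intermediate_means(self):
        prof = meth.allelic_bin_profile([read(2, 10, "C"), read(4, 10, "G")])
        assert prof["bin"] == 3  # floor(10 * 0.3)


class TestAdjacentCpG:
    @pytest.mark.parametrize("values,expected", [
        ((0.2, 0.2, 0.2), 0.0),
        ((0.0, 1.0, 0.0), 1.0),
        ((0.1, 0.4, 0.2), 0.25),
    ])
    def test_examples(self, values, expected):
        assert meth.adjacent_cpg_difference(values) == pytest.approx(expected)

    def test_missing_members_skip_pairs(self):
        vals = (0.1, math.nan, 0.2, 0.5)
        assert meth.adjacent_cpg_difference(vals) == pytest.approx(0.3)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            meth.adjacent_cpg_difference([0.5])


class TestFilter450k:
    def test_male_methylated_probe_dropped(self):
        probes = pd.DataFrame({"M1": [0.20, 0.05], "F1": [0.4, 0.4],
                               "F2": [0.4, 0.4], "F3": [0.4, 0.4]},
                              index=["p1", "p2"])
        sex = {"M1": "male", "F1": "female", "F2": "female", "F3": "female"}
        kept_probes, kept_females = meth.filter_450k_style(probes, sex)
        assert kept_probes == ["p2"]
        assert kept_females == ["F1", "F2", "F3"]

    def test_identical_females_all_retained(self):
        probes = pd.DataFrame({"F1": [0.3], "F2": [0.3], "F3": [0.3]},
                              index=["p1"])
        sex = {s: "female" for s in probes.columns}
        _, kept = meth.filter_450k_style(probes, sex)
        assert kept == ["F1", "F2", "F3"]

    def test_low_outlier_female_dropped_boundary_retained(self):
        # ten ordinary females plus one far-low outlier (presumed mislabelled)
        cols = {f"F{i}": [0.40 + 0.002 * i] for i in range(10)}
        cols["Fx"] = [0.05]
        probes = pd.DataFrame(cols, index=["p1"])
        sex = {s: "female" for s in probes.columns}
        _, kept = meth.filter_450k_style(probes, sex)
        assert "Fx" not in kept and len(kept) == 10


class TestVariableEscape:
    def test_informative_only_denominator(self):
        statuses = ["escape"] * 4 + ["subject"] * 4 + ["uninformative"] * 2
        assert meth.dname_variable_escape(statuses).status == "variable"

    def test_dominant_status_constitutive(self):
        statuses = ["subject"] * 9 + ["escape"]
        assert meth.dname_variable_escape(statuses).status == "subject"

    def test_gene_level_between_tss_flag(self):
        calls = pd.DataFrame({
            "transcript_id": ["t1", "t2", "t3"],
            "gene_id": ["g1", "g1", "g2"],
            "status": ["escape", "subject", "escape"]})
        out = meth.gene_level_dname_calls(calls).set_index("gene_id")
        assert out.loc["g1", "status"] == "variable"
        assert bool(out.loc["g1", "variable_between_tss"])
        assert out.loc["g2", "status"] == "escape"


def test_read_table_round_trip(tmp_path):
    reads = [read(3, 5, "C", rid="r1"), read(0, 5, rid="r2")]
    path = tmp_path / "reads.tsv"
    meth.write_methyl_reads(reads, path)
    back = meth.read_methyl_reads(path)
    assert [(r.n_meth, r.n_total, r.snp_allele) for r in back] == \
        [(3, 5, "C"), (0, 5, None)]
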