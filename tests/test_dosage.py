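import numpy as np
import pandas as pd
import pytest

from zdosage.dosage import (
    CountTable,
    bh_adjust,
    compute_ratios,
    normalize,
    summarize_by_chromosome,
    timecourse_profile,
    z_shift_test,
)
from zdosage.errors import (
    DegenerateSampleError,
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
    NotFoundError,
)
from zdosage.simulate import SimDesign, simulate_experiment, simulate_reference


def _ratio_table(m_values, chromosomes):
    return pd.DataFrame({
        "contig_id": [f"c{i}" for i in range(len(m_values))],
        "chromosome": chromosomes,
        "M": m_values,
        "A": np.zeros(len(m_values)),
    })


class TestNormalize:
    def test_simple_cpm(self):
        df = pd.DataFrame({"s1": [1, 1, 2]}, index=["a", "b", "c"])
        out = normalize(df)
        assert out["s1"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 100, size=(30, 3)),
                          columns=list("abc"))
        doubled = df.copy()
        doubled["b"] = df["b"] * 2
        pd.testing.assert_frame_equal(normalize(df), normalize(doubled))

    def test_column_sums_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            df = pd.DataFrame(rng.integers(0, 50, size=(20, 4)) + 1)
            sums = normalize(df).sum(axis=0)
            assert np.allclose(sums, 1e6)

    def test_all_zero_sample_named(self):
        df = pd.DataFrame({"good": [1, 2], "bad": [0, 0]})
        with pytest.raises(DegenerateSampleError, match="bad"):
            normalize(df)

    def test_median_method_recenters_bulk(self):
        # 80% of contigs unchanged, 20% doubled: median normalization
        # should leave the unchanged bulk at ratio ~1
        rng = np.random.default_rng(2)
        base = rng.integers(100, 1000, size=100)
        df = pd.DataFrame({"u": base, "i": base})
        df.iloc[:20, 1] *= 2
        out = normalize(df, method="median")
        bulk_ratio = (out.iloc[20:, 1] / out.iloc[20:, 0]).median()
        assert bulk_ratio == pytest.approx(1.0, rel=1e-6)

    def test_unknown_method(self):
        with pytest.raises(InvalidInputError):
            normalize(pd.DataFrame({"a": [1]}), method="quantile")


class TestComputeRatios:
    @staticmethod
    def _norm(values):
        return pd.DataFrame(values,
                            index=[f"c{i}" for i in range(len(values))])

    def test_equal_means_zero_m(self):
        norm = self._norm({"i1": [10.0, 20.0], "u1": [10.0, 20.0]})
        chrom = pd.Series(["Z", "A1"], index=["c0", "c1"])
        rt = compute_ratios(norm, chrom, ["i1"], ["u1"])
        assert np.allclose(rt["M"], 0.0)

    def test_swapping_groups_negates_m(self):
        norm = self._norm({"i1": [10.0, 60.0], "u1": [30.0, 20.0]})
        chrom = pd.Series(["Z", "A1"], index=["c0", "c1"])
        fwd = compute_ratios(norm, chrom, ["i1"], ["u1"])
        rev = compute_ratios(norm, chrom, ["u1"], ["i1"])
        assert np.allclose(fwd["M"], -rev["M"])

    def test_threefold_ratio_limit(self):
        norm = self._norm({"i1": [3000.0], "u1": [1000.0]})
        chrom = pd.Series(["Z"], index=["c0"])
        rt = compute_ratios(norm, chrom, ["i1"], ["u1"], pseudocount=1e-9)
        assert rt["M"].iloc[0] == pytest.approx(np.log2(3), abs=1e-6)

    def test_low_abundance_dropped_and_reported(self):
        norm = self._norm({"i1": [0.1, 50.0], "u1": [0.2, 40.0]})
        chrom = pd.Series(["Z", "A1"], index=["c0", "c1"])
        rt = compute_ratios(norm, chrom, ["i1"], ["u1"], min_abundance=1.0)
        assert list(rt["contig_id"]) == ["c1"]
        assert rt.attrs["n_dropped"] == 1

    def test_empty_group_rejected(self):
        norm = self._norm({"i1": [1.0]})
        with pytest.raises(InvalidDesignError):
            compute_ratios(norm, pd.Series(dtype=object), [], ["i1"])

    def test_finite_m_and_a(self):
        norm = self._norm({"i1": [0.0, 5.0], "u1": [3.0, 0.0]})
        chrom = pd.Series(["Z", "A1"], index=["c0", "c1"])
        rt = compute_ratios(norm, chrom, ["i1"], ["u1"])
        assert np.isfinite(rt[["M", "A"]].to_numpy()).all()


class TestSummarize:
    def test_all_zero(self):
        rt = _ratio_table([0.0] * 6, ["Z"] * 3 + ["A1"] * 3)
        s = summarize_by_chromosome(rt).set_index("chromosome")
        assert (s[["q25", "median", "q75"]].to_numpy() == 0).all()

    def test_hand_quantiles(self):
        rt = _ratio_table([1, 2, 3, 4, 5], ["Z"] * 5)
        s = summarize_by_chromosome(rt).iloc[0]
        assert (s["q25"], s["median"], s["q75"]) == (2.0, 3.0, 4.0)

    def test_z_first_then_sorted_autosomes(self):
        rt = _ratio_table(range(8), ["A2", "A10", "Z", "A1"] * 2)
        s = summarize_by_chromosome(rt)
        assert list(s["chromosome"]) == ["Z", "A1", "A10", "A2"]

    def test_quartile_order_invariant(self):
        rng = np.random.default_rng(3)
        rt = _ratio_table(rng.normal(size=40), ["Z"] * 20 + ["A1"] * 20)
        s = summarize_by_chromosome(rt)
        assert (s["q25"] <= s["median"]).all()
        assert (s["median"] <= s["q75"]).all()

    def test_simulated_dose_recovery(self, dose_design):
        counts, samples, ref = simulate_experiment(dose_design)
        table = CountTable(counts, samples)
        chrom = ref.contig_chromosomes()
        autosomal = list(chrom.index[chrom != "Z"])
        norm = normalize(table, method="median",
                         reference_contigs=autosomal)
        rt = compute_ratios(norm, chrom, table.sample_ids(True, 48.0),
                            table.sample_ids(False, 48.0))
        s = summarize_by_chromosome(rt).set_index("chromosome")
        assert s.loc["Z", "median"] == pytest.approx(np.log2(1.5),
                                                     abs=0.12)
        for c in ("A1", "A2", "A3", "A4"):
            assert abs(s.loc[c, "median"]) < 0.1


class TestZShift:
    def test_constant_m_null(self):
        rt = _ratio_table([0.5] * 30, ["Z"] * 10 + ["A1"] * 20)
        res = z_shift_test(rt, n_permutations=199, seed=0)
        assert res.observed_shift == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_power_under_failure(self, dose_design):
        counts, samples, ref = simulate_experiment(dose_design)
        table = CountTable(counts, samples)
        chrom = ref.contig_chromosomes()
        norm = normalize(table)
        rt = compute_ratios(norm, chrom, table.sample_ids(True, 48.0),
                            table.sample_ids(False, 48.0))
        res = z_shift_test(rt, n_permutations=999, seed=1)
        assert res.p_value < 0.01

    def test_antisymmetry_of_shift(self, dose_design):
        counts, samples, ref = simulate_experiment(dose_design)
        table = CountTable(counts, samples)
        chrom = ref.contig_chromosomes()
        norm = normalize(table)
        inf = table.sample_ids(True, 48.0)
        ctl = table.sample_ids(False, 48.0)
        fwd = compute_ratios(norm, chrom, inf, ctl)
        rev = compute_ratios(norm, chrom, ctl, inf)
        sf = z_shift_test(fwd, n_permutations=199, seed=0)
        sr = z_shift_test(rev, n_permutations=199, seed=0)
        assert sf.observed_shift == pytest.approx(-sr.observed_shift)

    def test_too_few_z_contigs(self):
        rt = _ratio_table(range(10), ["Z"] * 3 + ["A1"] * 7)
        with pytest.raises(InsufficientDataError):
            z_shift_test(rt, n_permutations=199)

    def test_single_chromosome_rejected(self):
        rt = _ratio_table(range(10), ["Z"] * 10)
        with pytest.raises(InsufficientDataError):
            z_shift_test(rt, n_permutations=199)

    def test_minimum_permutations_enforced(self):
        rt = _ratio_table(range(10), ["Z"] * 5 + ["A1"] * 5)
        with pytest.raises(InvalidDesignError):
            z_shift_test(rt, n_permutations=10)

    def test_null_p_values_roughly_uniform(self):
        # Kolmogorov-Smirnov check of permutation validity under f=1
        from scipy import stats

        design = SimDesign(n_chromosomes=3, genes_per_chromosome=100,
                           compensation_failure_factor=1.0,
                           masc_knockdown=1.0, dispersion=0.05,
                           library_size=2e5, timepoints=(48.0,), seed=31,
                           protein_length=10)
        ref = simulate_reference(design)
        chrom = ref.contig_chromosomes()
        pvals = []
        for rep in range(200):
            d = SimDesign(**{**design.__dict__, "seed": 1000 + rep})
            counts, samples, _ = simulate_experiment(d, ref=ref)
            table = CountTable(counts, samples)
            rt = compute_ratios(normalize(table), chrom,
                                table.sample_ids(True, 48.0),
                                table.sample_ids(False, 48.0))
            pvals.append(z_shift_test(rt, n_permutations=199,
                                      seed=rep).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTimecourse:
    @staticmethod
    def _table(design):
        counts, samples, ref = simulate_experiment(design, noise=False)
        return CountTable(counts, samples), ref

    def test_null_knockdown_ratio_one(self):
        d = SimDesign(n_chromosomes=2, genes_per_chromosome=30,
                      compensation_failure_factor=1.0, masc_knockdown=1.0,
                      dispersion=0.0, timepoints=(0.0, 6.0, 12.0, 18.0),
                      seed=41, protein_length=20)
        table, ref = self._table(d)
        prof = timecourse_profile(table, _masc_contig(ref))
        assert np.allclose(prof["ratio"], 1.0, atol=0.01)

    def test_knockdown_recovered_exactly(self):
        # many genes so the knocked-down gene itself cannot move the
        # per-sample normalization appreciably
        d = SimDesign(n_chromosomes=2, genes_per_chromosome=400,
                      compensation_failure_factor=1.0, masc_knockdown=0.2,
                      dispersion=0.0, timepoints=(0.0, 6.0, 12.0, 18.0),
                      seed=41, protein_length=10)
        table, ref = self._table(d)
        prof = timecourse_profile(table, _masc_contig(ref))
        assert np.allclose(prof["ratio"], 0.2, atol=0.01)

    def test_uninfected_peak_at_6(self):
        d = SimDesign(n_chromosomes=2, genes_per_chromosome=30,
                      masc_knockdown=0.2, dispersion=0.0,
                      timepoints=(0.0, 6.0, 12.0, 18.0), seed=41,
                      protein_length=20)
        table, ref = self._table(d)
        prof = timecourse_profile(table, _masc_contig(ref))
        peak = prof.loc[prof["uninfected"].idxmax(), "hpo"]
        assert peak == 6.0

    def test_missing_contig(self, tiny_design):
        counts, samples, _ = simulate_experiment(tiny_design)
        with pytest.raises(NotFoundError):
            timecourse_profile(CountTable(counts, samples), "nope")


def _masc_contig(ref):
    masc_gene = ref.masc_like_gene.gene_id
    return next(c for c, g in ref.contig_to_gene.items() if g == masc_gene)


class TestCountTable:
    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [1, -2]})
        samples = pd.DataFrame({"sample_id": ["s1"], "hpo": [0.0],
                                "infected": [True]}).set_index("sample_id")
        with pytest.raises(InvalidInputError):
            CountTable(counts, samples)

    def test_metadata_must_cover_samples(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]})
        samples = pd.DataFrame({"sample_id": ["s1"], "hpo": [0.0],
                                "infected": [True]}).set_index("sample_id")
        with pytest.raises(InvalidInputError):
            CountTable(counts, samples)


class TestBHAdjust:
    def test_monotone_and_bounded(self):
        p = [0.001, 0.02, 0.7, 0.04]
        adj = bh_adjust(p)
        assert (adj >= p).all() and (adj <= 1).all()

    def test_matches_hand_computation(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
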