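"""RPM normalization, QC screen, probe ratios and gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genotox import ProbeCountMatrix, aggregate_probes_to_genes, build_profiles, \
    probe_log_ratios, qc_pairwise_correlation, rpm_normalize
from genotox.panel import biomarker_panel
from genotox.simulate import SimulationParams, default_test_panel, \
    generate_test_study


def matrix_from(counts: dict, genes: dict | None = None) -> ProbeCountMatrix:
    df = pd.DataFrame(counts)
    gene_map = pd.Series(genes or {p: p.split("_")[0] for p in df.index},
                         name="gene_symbol")
    return ProbeCountMatrix(counts=df, gene_symbols=gene_map)


class TestRPM:
    def test_proportions_scaled_to_million(self):
        m = matrix_from({"s1": pd.Series([10, 90], index=["g1_p1", "g2_p1"])})
        rpm = rpm_normalize(m)
        assert rpm["s1"].tolist() == [100_000.0, 900_000.0]

    def test_equal_counts_give_equal_rpm(self):
        m = matrix_from({"s1": pd.Series([7] * 4,
                                         index=[f"g{i}_p1" for i in range(4)])})
        assert (rpm_normalize(m)["s1"] == 250_000.0).all()

    def test_zero_library_errors_with_sample_name(self):
        m = matrix_from({"good": pd.Series([5, 5], index=["a_p1", "b_p1"]),
                         "empty": pd.Series([0, 0], index=["a_p1", "b_p1"])})
        with pytest.raises(ValueError, match="empty"):
            rpm_normalize(m)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(20, 4))
        counts[0] += 1  # keep libraries non-empty
        m = matrix_from({f"s{j}": pd.Series(counts[:, j],
                                            index=[f"g{i}_p1" for i in range(20)])
                         for j in range(4)})
        sums = rpm_normalize(m).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)


class TestQC:
    def test_duplicated_sample_correlates_perfectly(self):
        col = pd.Series([3, 50, 200, 7], index=[f"g{i}_p1" for i in range(4)])
        m = matrix_from({"s1": col, "s2": col})
        report = qc_pairwise_correlation(rpm_normalize(m))
        assert report.min_correlation == pytest.approx(1.0)
        assert report.passed

    def test_fails_closed_below_threshold(self, rng):
        a = rng.integers(10, 1000, 200)
        noisy = (a * np.exp(rng.normal(0, 1.5, 200))).astype(int) + 1
        m = matrix_from({"s1": pd.Series(a, index=[f"g{i}_p1" for i in range(200)]),
                         "s2": pd.Series(noisy,
                                         index=[f"g{i}_p1" for i in range(200)])})
        report = qc_pairwise_correlation(rpm_normalize(m), threshold=0.97)
        assert report.min_correlation < 0.97
        assert not report.passed

    def test_min_matches_bruteforce(self, rng):
        counts = rng.integers(0, 300, size=(50, 3))
        m = matrix_from({f"s{j}": pd.Series(counts[:, j],
                                            index=[f"g{i}_p1" for i in range(50)])
                         for j in range(3)})
        rpm = rpm_normalize(m)
        report = qc_pairwise_correlation(rpm)
        log = np.log2(rpm.to_numpy() + 0.5)
        brute = min(np.corrcoef(log[:, i], log[:, j])[0, 1]
                    for i in range(3) for j in range(i + 1, 3))
        assert report.min_correlation == pytest.approx(brute, abs=1e-12)

    def test_constant_sample_excluded_with_warning(self):
        m = matrix_from({"s1": pd.Series([5, 5], index=["a_p1", "b_p1"]),
                         "s2": pd.Series([9, 1], index=["a_p1", "b_p1"]),
                         "s3": pd.Series([8, 2], index=["a_p1", "b_p1"])})
        with pytest.warns(UserWarning, match="excluded"):
            report = qc_pairwise_correlation(rpm_normalize(m))
        assert len(report.excluded_pairs) == 2
        assert len(report.pairs) == 1


class TestProbeRatios:
    def test_identical_samples_give_zero_ratio(self):
        col = pd.Series([100, 50], index=["a_p1", "b_p1"])
        m = matrix_from({"t": col, "c": col})
        out = probe_log_ratios(m, "t", "c")
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_variance_formula(self):
        m = matrix_from({"t": pd.Series([100, 900], index=["a_p1", "b_p1"]),
                         "c": pd.Series([100, 900], index=["a_p1", "b_p1"])})
        out = probe_log_ratios(m, "t", "c", pseudo=0.5)
        expected = (2.0 / 100.5) / np.log(2) ** 2
        assert out.loc["a_p1", "variance"] == pytest.approx(expected, rel=1e-12)

    def test_variance_matches_numeric_propagation(self):
        """Delta-method variance vs finite-difference Poisson propagation."""
        n_t, n_c, lib = 250.0, 100.0, 10_000.0
        pseudo, h = 0.5, 1e-5

        def ratio(nt, nc):
            return (np.log2(nt / lib * 1e6 + pseudo)
                    - np.log2(nc / lib * 1e6 + pseudo))

        g_t = (ratio(n_t + h, n_c) - ratio(n_t - h, n_c)) / (2 * h)
        g_c = (ratio(n_t, n_c + h) - ratio(n_t, n_c - h)) / (2 * h)
        numeric = g_t ** 2 * n_t + g_c ** 2 * n_c  # Var(Poisson n) = n
        formula = (1 / (n_t + pseudo) + 1 / (n_c + pseudo)) / np.log(2) ** 2
        assert formula == pytest.approx(numeric, rel=0.02)

    def test_fourfold_ratio(self):
        m = matrix_from({"t": pd.Series([8000, 2000], index=["a_p1", "b_p1"]),
                         "c": pd.Series([2000, 8000], index=["a_p1", "b_p1"])})
        out = probe_log_ratios(m, "t", "c")
        assert out.loc["a_p1", "log2_ratio"] == pytest.approx(2.0, abs=0.01)

    def test_missing_sample_errors(self):
        m = matrix_from({"t": pd.Series([1], index=["a_p1"])})
        with pytest.raises(KeyError):
            probe_log_ratios(m, "t", "nope")


class TestAggregation:
    def make_ratios(self, genes, ratios, variances):
        return pd.DataFrame({"gene_symbol": genes, "log2_ratio": ratios,
                             "variance": variances},
                            index=[f"p{i}" for i in range(len(genes))])

    def test_single_probe_passthrough(self):
        out = aggregate_probes_to_genes(
            self.make_ratios(["g1"], [1.5], [0.3]), ["g1"])
        assert out.log2fc["g1"] == pytest.approx(1.5)
        assert out.variance["g1"] == pytest.approx(0.3)

    def test_equal_weights_average(self):
        out = aggregate_probes_to_genes(
            self.make_ratios(["g1", "g1"], [1.0, 3.0], [0.2, 0.2]), ["g1"])
        assert out.log2fc["g1"] == pytest.approx(2.0)

    def test_inverse_variance_weighting_hand_example(self):
        """Variances (1, 2, 4) and ratios (0, 1, 2) give 4/7."""
        out = aggregate_probes_to_genes(
            self.make_ratios(["g1"] * 3, [0.0, 1.0, 2.0], [1.0, 2.0, 4.0]),
            ["g1"])
        assert out.log2fc["g1"] == pytest.approx(4.0 / 7.0, rel=1e-12)
        assert out.variance["g1"] == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_missing_gene_listed(self):
        with pytest.raises(ValueError, match="g2"):
            aggregate_probes_to_genes(
                self.make_ratios(["g1"], [0.0], [1.0]), ["g1", "g2"])

    def test_aggregation_never_increases_variance(self, rng):
        for _ in range(20):
            k = rng.integers(1, 5)
            var = rng.uniform(0.05, 2.0, k)
            out = aggregate_probes_to_genes(
                self.make_ratios(["g"] * k, rng.normal(size=k), var), ["g"])
            assert out.variance["g"] <= var.min() + 1e-12

    @given(st.floats(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, shift):
        """Adding a constant to all probe ratios shifts the gene value."""
        base = self.make_ratios(["g"] * 3, [0.2, -0.4, 1.1], [0.5, 1.0, 0.25])
        shifted = base.assign(log2_ratio=base["log2_ratio"] + shift)
        a = aggregate_probes_to_genes(base, ["g"]).log2fc["g"]
        b = aggregate_probes_to_genes(shifted, ["g"]).log2fc["g"]
        assert b == pytest.approx(a + shift, abs=1e-9)


class TestEndToEnd:
    def test_null_conditions_have_small_profiles(self):
        """Zero-effect conditions give panel-mean |log2fc| within noise."""
        p = SimulationParams(seed=5, n_background_genes=100)
        inert = [c for c in default_test_panel() if c.truth_class == "non-DDI"]
        counts, samples = generate_test_study(inert, p)
        profiles = build_profiles(counts, samples,
                                  biomarker_panel(p.n_biomarker_genes))
        for profile in profiles:
            typical_sd = np.sqrt(profile.variance.mean())
            bound = 3.0 * typical_sd / np.sqrt(len(profile.genes))
            assert abs(profile.log2fc.mean()) < bound

    def test_build_profiles_requires_one_vehicle(self, test_study):
        counts, samples = test_study
        broken = samples[samples["role"] == "test"]
        with pytest.raises(ValueError, match="vehicle"):
            build_profiles(counts, broken, biomarker_panel(64))
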