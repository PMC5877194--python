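import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eegssa as e
from eegssa.embedding import _zeta_table


def _noise(n, seed=42, fs=200.0):
    return e.TimeSeries(np.random.default_rng(seed).normal(size=n), fs)


class TestSelectionRule:
    @pytest.mark.parametrize(
        "fs, fb, expected",
        [(200, 5, 40), (200, 2.5, 80), (250, 4, 63), (200, 20, 10)],
    )
    def test_rule_is_ceiling_of_ratio(self, fs, fb, expected):
        assert e.select_embedding(fs, fb) == expected

    @pytest.mark.parametrize("fs, fb", [(200, 0), (200, -1), (200, 101), (0, 5)])
    def test_unresolvable_band_rejected(self, fs, fb):
        with pytest.raises(ValueError):
            e.select_embedding(fs, fb)

    @pytest.mark.parametrize("L, expected", [(20, 10.0), (40, 5.0), (80, 2.5)])
    def test_component_bandwidth(self, L, expected):
        assert e.component_bandwidth(200, L) == expected

    @given(
        fs=st.floats(1.0, 5000.0),
        fb=st.floats(0.01, 1000.0),
    )
    def test_bandwidth_bound_always_guaranteed(self, fs, fb):
        """ceil() in the rule keeps the component bandwidth within fb."""
        if not 0 < fb <= fs / 2:
            return
        L = e.select_embedding(fs, fb)
        assert e.component_bandwidth(fs, L) <= fb * (1 + 1e-12)


class TestToeplitzCovariance:
    def test_constant_series_lags(self):
        with pytest.warns(UserWarning):  # K=4 < 10*L on purpose: tiny example
            cov = e.toeplitz_covariance(e.TimeSeries([1.0] * 5, 10.0), 2)
        assert np.array_equal(cov.lags, [4.0, 4.0])
        assert np.array_equal(cov.matrix, [[4.0, 4.0], [4.0, 4.0]])

    def test_close_to_exact_covariance_for_long_records(self):
        ts = _noise(1600)
        cov = e.toeplitz_covariance(ts, 40)
        XtX = e.embed(ts, 40).matrix.T @ e.embed(ts, 40).matrix
        dist = np.linalg.norm(XtX - cov.matrix) / np.linalg.norm(XtX)
        assert dist < 0.05

    def test_short_record_warns(self):
        with pytest.warns(UserWarning, match="Toeplitz approximation"):
            e.toeplitz_covariance(_noise(100), 40)

    def test_L_too_large_rejected(self):
        with pytest.raises(ValueError):
            e.toeplitz_covariance(_noise(100), 100)

    def test_circulant_formula_tracks_true_eigenvalues(self):
        """Fourier eigenvalue formula vs. a direct symmetric eigensolve."""
        cov = e.toeplitz_covariance(_noise(1600, seed=1), 40)
        approx = np.sort(e.circulant_eigenvalues(cov))[::-1]
        true = np.sort(np.linalg.eigvalsh(cov.matrix))[::-1]
        rel = np.abs(approx[:20] - true[:20]) / true[:20]
        assert rel.mean() < 0.10

    def test_trace_equals_eigenvalue_sum(self):
        cov = e.toeplitz_covariance(_noise(800), 25)
        assert np.trace(cov.matrix) == pytest.approx(
            np.linalg.eigvalsh(cov.matrix).sum(), rel=1e-9
        )


class TestSpectralApproximation:
    def test_zeta_at_origin_is_2L_minus_1(self):
        for L in (5, 20, 40):
            assert _zeta_table(L, 50)[0, 0] == pytest.approx(2 * L - 1)

    def test_zeta_depends_only_on_fractional_part(self):
        # p/L + q/K = 1/4 exactly at (p, q) = (1, 0) with L=4 and (0, 2) with K=8
        table = _zeta_table(4, 8)
        assert table[1, 0] == pytest.approx(table[0, 2], rel=1e-12)
        # integer x hits the 2L-1 ridge
        assert table[2, 4] == pytest.approx(7.0)  # 2/4 + 4/8 = 1

    def test_zero_signal_gives_zero_eigenvalues(self):
        sa = e.spectral_approximation(e.TimeSeries([0.0] * 100, 200.0), 10)
        assert np.allclose(sa.approx_eigenvalues, 0.0)

    def test_eigenvalue_sum_preserves_trace(self, noise_series):
        """sum_p lambda_p^approx equals trace(T) exactly (Parseval)."""
        sa = e.spectral_approximation(noise_series, 40)
        cov = e.toeplitz_covariance(noise_series, 40)
        assert sa.approx_eigenvalues.sum() == pytest.approx(
            np.trace(cov.matrix), rel=1e-9
        )

    def test_sinusoid_peak_index_maps_to_line_frequency(self, sinusoid_series):
        """The dominant approximate eigenvalue sits at the index whose
        spectral window (width fs/L) contains the 10.5 Hz line."""
        sa = e.spectral_approximation(sinusoid_series, 40)
        p_star = int(np.argmax(sa.approx_eigenvalues))
        assert abs(sa.component_frequencies[p_star] - 10.5) <= 200.0 / 40

    def test_sinusoid_dominant_pair_carries_dirichlet_weight(self, sinusoid_series):
        """For a line spectrum the approximation concentrates a (2L-1)/L
        Dirichlet weight on the dominant pair: ~2x the true eigenvalues."""
        sa = e.spectral_approximation(sinusoid_series, 40)
        cov = e.toeplitz_covariance(sinusoid_series, 40)
        approx = np.sort(sa.approx_eigenvalues)[::-1]
        true = np.sort(np.linalg.eigvalsh(cov.matrix))[::-1]
        ratio = approx[:2].sum() / true[:2].sum()
        assert 1.5 < ratio < 2.0

    def test_broadband_accuracy_on_dominant_half(self):
        """On broadband input the approximation tracks the true Toeplitz
        eigenvalues closely over the dominant half of the spectrum."""
        ts = _noise(1600, seed=3)
        sa = e.spectral_approximation(ts, 40)
        cov = e.toeplitz_covariance(ts, 40)
        approx = np.sort(sa.approx_eigenvalues)[::-1][:20]
        true = np.sort(np.linalg.eigvalsh(cov.matrix))[::-1][:20]
        assert np.mean(np.abs(approx - true) / true) < 0.15

    def test_accuracy_improves_with_record_length(self):
        import warnings

        errs = []
        for n in (400, 1600, 6400):
            ts = _noise(n, seed=7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # K < 10L at n=400
                sa = e.spectral_approximation(ts, 40)
                cov = e.toeplitz_covariance(ts, 40)
            approx = np.sort(sa.approx_eigenvalues)[::-1][:20]
            true = np.sort(np.linalg.eigvalsh(cov.matrix))[::-1][:20]
            errs.append(np.mean(np.abs(approx - true) / true))
        assert errs[2] < errs[1] < errs[0]


class TestTraceProfile:
    def test_zero_series_traces_are_zero(self):
        prof = e.trace_profile(e.TimeSeries([0.0] * 100, 200.0), [5, 10, 20])
        assert np.all(prof.traces == 0)

    def test_traces_positive_for_nonzero_signal(self, noise_series):
        prof = e.trace_profile(noise_series, range(10, 101, 10))
        assert np.all(prof.traces > 0)

    def test_delta_identity_is_exact(self, noise_series):
        """Tr_L - Tr_{L-1} equals the sample sum over j = L..K exactly."""
        s2 = noise_series.values**2
        N = noise_series.n
        prof = e.trace_profile(noise_series, [10, 40, 100])
        for L, delta in zip(prof.L_values, prof.deltas):
            oracle = s2[L - 1 : N - L + 1].sum()
            assert delta == pytest.approx(oracle, rel=1e-12)

    def test_deltas_shrink_with_L(self, noise_series):
        """The trace change rate is large at small L and decreases."""
        prof = e.trace_profile(noise_series, range(10, 101))
        slope = np.polyfit(prof.L_values, prof.deltas, 1)[0]
        assert slope < 0

    def test_unsorted_grid_is_sorted_internally(self, noise_series):
        prof = e.trace_profile(noise_series, [40, 10, 20])
        assert np.array_equal(prof.L_values, [10, 20, 40])


class TestEmbeddingReport:
    def test_alpha_recommendation(self, noise_series):
        rep = e.recommend_embedding_report(noise_series, e.ALPHA)
        assert rep.L == 40
        assert rep.component_bandwidth_hz == 5.0
        assert not rep.degenerate

    def test_warns_when_rule_exceeds_half_record(self):
        ts = e.TimeSeries(np.random.default_rng(0).normal(size=100), 200.0)
        rep = e.recommend_embedding_report(ts, e.RhythmBand("narrow", 10.0, 11.0))
        assert any("N/2" in w for w in rep.warnings)

    def test_constant_series_flagged_degenerate(self):
        rep = e.recommend_embedding_report(e.TimeSeries([3.0] * 400, 200.0), e.ALPHA)
        assert rep.degenerate
        assert any("rank-1" in w for w in rep.warnings)
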