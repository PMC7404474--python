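import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_cow, identity_warp_objective
from olivegrade.core import Category, Chromatogram, OliveGradeError
from olivegrade.preprocess import (
    FingerprintMatrix,
    autoscale_apply,
    autoscale_fit,
    build_fingerprints,
    choose_reference,
    cow_align,
    select_signal_region,
)


def _noisy_signal(rng, n):
    return rng.normal(0.0, 1.0, n).cumsum() + 20.0


class TestCowAlign:
    def test_identity_signal_gives_identity_map(self, rng):
        sig = _noisy_signal(rng, 400)
        r = cow_align(sig, sig, 50, 5)
        assert r.is_identity
        assert r.objective == pytest.approx(r.n_segments, abs=1e-9)
        np.testing.assert_array_equal(r.warped, sig)

    def test_shifted_gaussian_apex_recovered(self):
        t = np.arange(10_000) * 0.01
        ref = 1000.0 * np.exp(-0.5 * ((t - 50.0) / 0.35) ** 2) + 50.0
        sig = 1000.0 * np.exp(-0.5 * ((t - 50.10) / 0.35) ** 2) + 50.0
        r = cow_align(sig, ref, 100, 15, band=45)
        assert abs(int(np.argmax(r.warped)) - 5000) <= 1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 61))
            k_seg = int(rng.integers(2, 5))  # <= 4 segments keeps enumeration tractable
            m = -(-(n - 1) // k_seg)
            slack = int(rng.integers(1, 4))
            ref = _noisy_signal(rng, n)
            sig = _noisy_signal(rng, n)
            result = cow_align(sig, ref, m, slack)
            obj, seq = brute_force_cow(sig, ref, m, slack)
            assert [s for _, s in result.boundary_map] == list(seq)
            assert result.objective == pytest.approx(obj, abs=1e-9)

    def test_never_worse_than_identity_warp(self, rng):
        for _ in range(10):
            ref = _noisy_signal(rng, 300)
            sig = _noisy_signal(rng, 300)
            r = cow_align(sig, ref, 40, 6)
            assert r.objective >= identity_warp_objective(sig, ref, 40) - 1e-9

    def test_realignment_gains_nothing_and_stays_near_identity(self):
        # a second COW pass on an aligned signal may polish away residual
        # interpolation error but must never lose correlation, and its warp
        # must be a small perturbation of the identity
        t = np.arange(3000) * 0.01

        def base(x):
            return (
                100.0 * np.sin(2 * np.pi * x / 7.0)
                + 40.0 * np.sin(2 * np.pi * x / 2.3 + 1.0)
                + 300.0 * np.exp(-0.5 * ((x - 15.0) / 0.4) ** 2)
            )

        ref = base(t) + 500.0
        sig = base(t + 0.15) + 500.0
        once = cow_align(sig, ref, 100, 15)
        again = cow_align(once.warped, ref, 100, 15)
        assert again.objective >= once.objective - 1e-9
        # pinned endpoints leave residual mismatch in the edge segments, so a
        # couple of boundaries near the ends may still move on the second pass
        displacements = [abs(s - r) for r, s in again.boundary_map]
        assert sum(d > 3 for d in displacements) <= 2
        assert np.median(displacements) == 0

    def test_objective_bounded_by_segment_count(self, rng):
        ref, sig = _noisy_signal(rng, 200), _noisy_signal(rng, 200)
        r = cow_align(sig, ref, 30, 4)
        assert r.objective <= r.n_segments + 1e-12

    def test_boundary_map_strictly_increasing(self, rng):
        ref, sig = _noisy_signal(rng, 200), _noisy_signal(rng, 200)
        r = cow_align(sig, ref, 30, 4)
        refs, srcs = zip(*r.boundary_map)
        assert all(np.diff(refs) > 0) and all(np.diff(srcs) > 0)
        assert r.boundary_map[0] == (0, 0)
        assert r.boundary_map[-1] == (199, 199)

    def test_too_short_signal_rejected(self, rng):
        with pytest.raises(OliveGradeError, match="two segments"):
            cow_align(np.ones(30), np.ones(30), 20, 3)

    def test_bad_slack_rejected(self):
        with pytest.raises(OliveGradeError, match="slack"):
            cow_align(np.ones(100), np.ones(100), 10, 10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15)
    def test_property_dp_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 56))
        k_seg = int(rng.integers(2, 5))
        m = -(-(n - 1) // k_seg)
        slack = int(rng.integers(1, 4))
        ref, sig = _noisy_signal(rng, n), _noisy_signal(rng, n)
        result = cow_align(sig, ref, m, slack)
        obj, seq = brute_force_cow(sig, ref, m, slack)
        assert [s for _, s in result.boundary_map] == list(seq)
        assert result.objective == pytest.approx(obj, abs=1e-9)


@pytest.fixture(scope="module")
def trio():
    from olivegrade.synthetic_data import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(seed=21)
    samples, _ = generate_dataset(
        cfg, {Category.EVOO: 1, Category.VOO: 1, Category.LOO: 1}, seed=21
    )
    return samples


class TestBuildFingerprints:

    def test_width_is_19900_with_default_trim(self, trio):
        F = build_fingerprints(trio, trio[0])
        assert F.n_points == 19_900
        assert F.aligned
        assert (F.point_source == "nonpolar").sum() == 9950

    def test_reference_row_equals_raw_concatenation(self, trio):
        F = build_fingerprints(trio, trio[0])
        expected = np.concatenate([trio[0].trace_nonpolar[:9950], trio[0].trace_polar[:9950]])
        np.testing.assert_array_equal(F.X[0], expected)

    def test_permuting_samples_permutes_rows_only(self, trio):
        F = build_fingerprints(trio, trio[0])
        G = build_fingerprints([trio[2], trio[0], trio[1]], trio[0])
        np.testing.assert_array_equal(G.X[1], F.X[0])
        np.testing.assert_array_equal(G.X[0], F.X[2])

    def test_mixed_time_grids_rejected(self, trio):
        short = Chromatogram(
            "short", Category.VOO, np.arange(5000) * 0.01, np.zeros(5000), np.zeros(5000)
        )
        with pytest.raises(OliveGradeError, match="grid"):
            build_fingerprints([trio[0], short], trio[0])

    def test_medoid_reference_prefers_central_sample(self, trio):
        ref = choose_reference(trio)
        assert ref.sample_id in {c.sample_id for c in trio}


class TestSelectSignalRegion:
    def _matrix_with_peak(self, lo=2100, hi=2400, n=10_000, height=500.0):
        t = np.arange(n) * 0.01
        rng = np.random.default_rng(0)
        ref_np = np.zeros(n) + 50.0 + rng.normal(0, 2.0, n)
        block = np.zeros(n) + 50.0
        block[lo : hi + 1] += height
        X = np.stack([np.concatenate([block, block])] * 3)
        ref = Chromatogram("r", Category.UNKNOWN, t, ref_np, ref_np.copy())
        F = FingerprintMatrix(
            X=X,
            sample_ids=["a", "b", "c"],
            point_source=np.array(["nonpolar"] * n + ["polar"] * n),
            point_time=np.concatenate([t, t]),
            aligned=True,
        )
        return F, ref

    def test_retained_run_covers_the_peak(self):
        F, ref = self._matrix_with_peak()
        out = select_signal_region(F, ref)
        block = out.point_source == "nonpolar"
        times = out.point_time[block]
        assert times.min() == pytest.approx(21.0, abs=0.01)
        assert times.max() == pytest.approx(24.0, abs=0.01)

    def test_all_noise_matrix_rejected(self):
        F, ref = self._matrix_with_peak(height=0.0)
        with pytest.raises(OliveGradeError, match="no signal region"):
            select_signal_region(F, ref)

    def test_invariant_to_noise_outside_the_run(self):
        F, ref = self._matrix_with_peak()
        out1 = select_signal_region(F, ref)
        # bury extra sub-threshold noise far from the peak
        F2 = FingerprintMatrix(
            X=F.X.copy(),
            sample_ids=F.sample_ids,
            point_source=F.point_source,
            point_time=F.point_time,
            aligned=True,
        )
        F2.X[:, 8000:8200] += 5.0  # below 10 x noise SD
        out2 = select_signal_region(F2, ref)
        np.testing.assert_array_equal(out1.point_time, out2.point_time)

    def test_autoscaled_input_rejected(self):
        F, ref = self._matrix_with_peak()
        scaled = autoscale_apply(F, autoscale_fit(F))
        with pytest.raises(OliveGradeError, match="unscaled"):
            select_signal_region(scaled, ref)


class TestAutoscale:
    def test_1_2_3_column_maps_to_unit_scores(self):
        X = np.array([[1.0], [2.0], [3.0]])
        params = autoscale_fit(X)
        scaled = (X - params.mean) / params.sd
        np.testing.assert_allclose(scaled.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_centered_and_flagged(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        params = autoscale_fit(X)
        assert params.zero_variance.tolist() == [True, False]
        scaled = (X - params.mean) / params.sd
        np.testing.assert_allclose(scaled[:, 0], 0.0)

    def test_fitting_rows_have_zero_mean_unit_sd(self, rng):
        X = rng.lognormal(3, 1, (20, 30))
        F = FingerprintMatrix(
            X=X,
            sample_ids=[f"s{i}" for i in range(20)],
            point_source=np.array(["nonpolar"] * 30),
            point_time=np.arange(30) * 0.01,
        )
        out = autoscale_apply(F, autoscale_fit(F))
        assert out.autoscaled
        np.testing.assert_allclose(out.X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.X.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_external_rows_scaled_with_calibration_params_are_offset(self, rng):
        cal = rng.normal(0, 1, (15, 10))
        ext = cal[:5] + 3.0  # known shift
        params = autoscale_fit(cal)
        scaled_ext = (ext - params.mean) / params.sd
        assert np.abs(scaled_ext.mean(axis=0)).min() > 1.0

    def test_mismatched_width_rejected(self, rng):
        F = FingerprintMatrix(
            X=rng.normal(0, 1, (5, 8)),
            sample_ids=[f"s{i}" for i in range(5)],
            point_source=np.array(["nonpolar"] * 8),
            point_time=np.arange(8) * 0.01,
        )
        G = FingerprintMatrix(
            X=rng.normal(0, 1, (5, 9)),
            sample_ids=[f"s{i}" for i in range(5)],
            point_source=np.array(["nonpolar"] * 9),
            point_time=np.arange(9) * 0.01,
        )
        with pytest.raises(OliveGradeError, match="points"):
            autoscale_apply(G, autoscale_fit(F))
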