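"""Tests for the continuous-variation analysis: Job plot and global K fit."""

import numpy as np
import pytest

from cdbind import (
    CVDataset,
    CVSample,
    IdentifiabilityError,
    MissingObservationError,
    NMRGenConfig,
    ProtonAssignment,
    ValidationError,
    build_job_plot,
    fit_association_constant,
    gen_cv_dataset,
    observed_delta,
    select_protons,
)
from cdbind.nmr_titration import GUEST

NMR_TRUE_K = 6.181e3  # generator ground truth shared with conftest fixtures


def make_dataset(delta_fn, n=11, total=0.010, label="Hx", delta_free=7.0):
    """Single-guest-proton series; delta_fn(r, guest_total) -> ddelta (ppm)."""
    samples = []
    for i in range(1, n + 1):
        r = i / (n + 1)
        guest = r * total
        host = total - guest
        samples.append(
            CVSample(
                sample_id=i,
                host_total=host,
                guest_total=guest,
                observed_shifts={label: delta_free - delta_fn(r, guest)},
            )
        )
    return CVDataset(
        samples=tuple(samples),
        assignments=(ProtonAssignment(label, GUEST, delta_free),),
        total_concentration=total,
    )


class TestObservedDelta:
    @pytest.mark.parametrize(
        "free, obs, expected",
        [(7.843, 7.843, 0.0), (7.843, 7.800, 0.043), (6.387, 6.400, -0.013)],
    )
    def test_sign_preserving_subtraction(self, free, obs, expected):
        sample = CVSample(1, 5e-3, 5e-3, {"Hx": obs})
        assignment = ProtonAssignment("Hx", GUEST, free)
        assert observed_delta(sample, assignment) == pytest.approx(expected, abs=1e-12)

    def test_missing_proton_is_absent_not_zero(self):
        sample = CVSample(1, 5e-3, 5e-3, {})
        with pytest.raises(MissingObservationError):
            observed_delta(sample, ProtonAssignment("Hx", GUEST, 7.0))


class TestJobPlot:
    def test_analytic_parabola_peaks_at_half(self):
        # y = |ddelta| * [X] = r (1 - r) exactly -> symmetric parabola
        dataset = make_dataset(lambda r, guest: r * (1 - r) * 1e-3 / guest)
        result = build_job_plot(dataset)
        assert result.r_max == pytest.approx(0.5, abs=1e-9)
        assert result.inferred_ratio == "1:1"

    def test_noiseless_synthetic_dataset(self, noiseless_cv):
        result = build_job_plot(noiseless_cv)
        assert result.r_max == pytest.approx(0.5, abs=0.005)
        assert result.inferred_ratio == "1:1"

    def test_swapping_host_and_guest_preserves_peak(self, noiseless_cv):
        swapped_samples = tuple(
            CVSample(s.sample_id, s.guest_total, s.host_total, dict(s.observed_shifts))
            for s in noiseless_cv.samples
        )
        swapped_assignments = tuple(
            ProtonAssignment(a.label, "host" if a.species == "guest" else "guest", a.delta_free)
            for a in noiseless_cv.assignments
        )
        swapped = CVDataset(
            swapped_samples, swapped_assignments, noiseless_cv.total_concentration
        )
        a = build_job_plot(noiseless_cv).r_max
        b = build_job_plot(swapped).r_max
        assert a == pytest.approx(b, abs=1e-9)

    def test_symmetry_about_half_at_mirrored_design_points(self, noiseless_cv):
        """For an error-free 1:1 series at constant total, y(r) = y(1-r)."""
        result = build_job_plot(noiseless_cv, protons=["Hd"])
        (curve,) = result.curves
        mirrored = dict(zip(np.round(curve.r, 12), curve.y))
        for r, y in zip(curve.r, curve.y):
            assert abs(y - mirrored[round(1 - r, 12)]) <= 1e-12 * curve.y.max()

    def test_flat_curve_rejected(self):
        dataset = make_dataset(lambda r, guest: 0.0)
        from cdbind import DegenerateCurveError

        with pytest.raises(DegenerateCurveError):
            build_job_plot(dataset)


class TestAssociationConstantFit:
    def test_noiseless_recovery(self, noiseless_cv):
        fit = fit_association_constant(noiseless_cv)
        assert fit.K == pytest.approx(NMR_TRUE_K, rel=1e-3)
        assert fit.E <= 1e-12
        assert fit.correlation_r >= 0.999999
        assert fit.converged

    def test_recovered_amplitudes_match_generator(self, noiseless_cv):
        from cdbind.synthetic_data import DEFAULT_DELTA_C

        fit = fit_association_constant(noiseless_cv)
        for label, amp in fit.delta_c.items():
            assert amp == pytest.approx(DEFAULT_DELTA_C[label], rel=1e-3)

    def test_all_zero_amplitudes_not_identifiable(self):
        config = NMRGenConfig(delta_c={k: 0.0 for k in "abcdef"},
                              delta_free={k: ("guest", 7.0) for k in "abcdef"},
                              shift_noise_sd=0.0)
        dataset = gen_cv_dataset(config, seed=0)
        with pytest.raises(IdentifiabilityError):
            fit_association_constant(dataset, protons=list("abcdef"))

    def test_single_proton_matches_brute_force_grid(self):
        """Exhaustive grid over log10 K at 1e-4 resolution as oracle, K=500."""
        true_k, amp = 500.0, 0.21
        dataset = make_dataset(
            lambda r, guest: amp
            * _complex_vec(0.010 - guest, guest, true_k)
            / guest
        )
        fit = fit_association_constant(dataset, protons=["Hx"])

        H = np.array([s.host_total for s in dataset.samples])
        G = np.array([s.guest_total for s in dataset.samples])
        dd = np.array([7.0 - s.observed_shifts["Hx"] for s in dataset.samples])
        logk = np.arange(0.0, 7.0 + 1e-9, 1e-4)
        k_grid = 10.0**logk
        b = H[:, None] + G[:, None] + 1.0 / k_grid[None, :]
        c = (b - np.sqrt(b * b - 4.0 * H[:, None] * G[:, None])) / 2.0
        x = c / G[:, None]
        amps = (x * dd[:, None]).sum(axis=0) / (x * x).sum(axis=0)
        E = ((dd[:, None] - amps[None, :] * x) ** 2).sum(axis=0)
        k_oracle = k_grid[np.argmin(E)]
        assert fit.K == pytest.approx(k_oracle, rel=1e-3)
        assert fit.K == pytest.approx(true_k, rel=1e-3)

    def test_ppm_offset_invariance(self, noiseless_cv):
        baseline = fit_association_constant(noiseless_cv)
        offset = 1.7
        shifted_samples = tuple(
            CVSample(
                s.sample_id,
                s.host_total,
                s.guest_total,
                {
                    k: (v + offset if k == "Hd" else v)
                    for k, v in s.observed_shifts.items()
                },
            )
            for s in noiseless_cv.samples
        )
        shifted_assignments = tuple(
            ProtonAssignment(a.label, a.species,
                             a.delta_free + (offset if a.label == "Hd" else 0.0))
            for a in noiseless_cv.assignments
        )
        shifted = CVDataset(
            shifted_samples, shifted_assignments, noiseless_cv.total_concentration
        )
        result = fit_association_constant(shifted)
        assert result.K == pytest.approx(baseline.K, rel=1e-9)
        assert result.E == pytest.approx(baseline.E, abs=1e-18)

    def test_local_optimality_against_perturbations(self, noiseless_cv):
        fit = fit_association_constant(noiseless_cv)
        rng = np.random.default_rng(7)
        for _ in range(100):
            k_try = fit.K * np.exp(rng.normal(0, 0.2))
            amps_try = {k: v * (1 + rng.normal(0, 0.1)) for k, v in fit.delta_c.items()}
            assert _manual_E(noiseless_cv, k_try, amps_try) >= fit.E - 1e-18

    def test_noisy_recovery_median_error(self):
        """Median relative K error < 5% over 50 noisy simulated series."""
        rng = np.random.default_rng(2024)
        errors = []
        for i in range(50):
            k_true = 10.0 ** rng.uniform(2, 4)
            dataset = gen_cv_dataset(
                NMRGenConfig(K=k_true, shift_noise_sd=0.001), seed=int(rng.integers(2**31))
            )
            fit = fit_association_constant(dataset)
            errors.append(abs(fit.K / k_true - 1.0))
        assert np.median(errors) < 0.05

    def test_automatic_selection_drops_silent_protons(self):
        config = NMRGenConfig(shift_noise_sd=0.001)
        config.delta_c["Hf"] = 0.0  # silent proton
        dataset = gen_cv_dataset(config, seed=3)
        assert "Hf" not in select_protons(dataset)
        assert "Hd" in select_protons(dataset)

    def test_too_few_observations_rejected(self, noiseless_cv):
        truncated = CVDataset(
            noiseless_cv.samples[:2],
            noiseless_cv.assignments,
            noiseless_cv.total_concentration,
        )
        with pytest.raises(ValidationError):
            fit_association_constant(truncated, protons=["Hd"])


def _complex_vec(H, G, K):
    b = H + G + 1.0 / K
    return 2.0 * H * G / (b + np.sqrt(b * b - 4.0 * H * G))


def _manual_E(dataset, K, amps):
    """Loss at an arbitrary (K, amplitudes) point, computed independently."""
    E = 0.0
    for a in dataset.assignments:
        for s in dataset.samples:
            if a.label not in s.observed_shifts:
                continue
            x_tot = s.host_total if a.species == "host" else s.guest_total
            dd_obs = a.delta_free - s.observed_shifts[a.label]
            dd_calc = amps[a.label] * _complex_vec(s.host_total, s.guest_total, K) / x_tot
            E += (dd_obs - dd_calc) ** 2
    return E
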