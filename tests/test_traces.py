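"""Trace selection, correction factors and population fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretarch.photophysics import efficiency_to_distance
from fretarch.pipeline import analyze_cohort
from fretarch.presets import fluorophore_pair
from fretarch.simulate import TraceSimParams, simulate_alex_trace, simulate_trace_cohort
from fretarch.traces import (
    AlexTrace,
    CorrectionFactors,
    ESPoint,
    beta_from_means,
    compute_e_s,
    detect_bleach_steps,
    estimate_alpha_delta,
    estimate_gamma,
    fit_es_population,
    select_fret_traces,
)

R0_T = fluorophore_pair("cy3b_T").R0


def make_trace(I_DD, I_DA, I_AA, trace_id=""):
    n = len(I_DD)
    return AlexTrace(np.arange(n), I_DD, I_DA, I_AA, trace_id)


class TestBleachDetection:
    def test_constant_series_has_no_steps(self):
        assert detect_bleach_steps(np.full(100, 50.0)) == []

    def test_noiseless_drop_located_exactly(self):
        y = np.where(np.arange(100) < 50, 100.0, 0.0)
        steps = detect_bleach_steps(y)
        assert len(steps) == 1
        assert steps[0].frame == 50 and steps[0].sign == -1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_bleach_steps(np.ones(8), min_dwell=5)

    def test_simulated_bleach_frame_recovered(self):
        # 200 replicates with stored truth; located within +-2 frames in
        # at least 95% of cases
        p = TraceSimParams(
            true_distance=4.8,
            acceptor_bleach_rate=0.01,
            donor_bleach_rate=0.0,
            frames=600,
            seed=21,
        )
        ts = simulate_trace_cohort(200, p)
        hits = total = 0
        for tr, gt in zip(ts.traces, ts.truths):
            ab = gt.bleach_frames["acceptor"]
            if ab is None or not (10 < ab < 590):
                continue
            total += 1
            down = [s for s in detect_bleach_steps(tr.I_AA) if s.sign < 0]
            if len(down) == 1 and abs(down[0].frame - ab) <= 2:
                hits += 1
        assert total > 150
        assert hits / total >= 0.95


class TestSelection:
    def test_clean_fret_trace_accepted(self):
        n = 200
        I_AA = np.where(np.arange(n) < 120, 400.0, 0.0)
        I_DD = np.where(np.arange(n) < 120, 50.0, 300.0)
        I_DA = np.where(np.arange(n) < 120, 250.0, 0.0)
        sel = select_fret_traces([make_trace(I_DD, I_DA, I_AA)])
        assert len(sel) == 1
        assert abs(sel[0].acceptor_bleach - 120) <= 2

    def test_two_step_acceptor_decay_rejected(self):
        n = 300
        I_AA = np.select(
            [np.arange(n) < 100, np.arange(n) < 200], [800.0, 400.0], 0.0
        )
        I_DD = np.where(np.arange(n) < 200, 50.0, 300.0)
        I_DA = np.where(np.arange(n) < 200, 250.0, 0.0)
        assert select_fret_traces([make_trace(I_DD, I_DA, I_AA)]) == []

    def test_multifluorophore_contaminants_rejected(self):
        # contaminants built as sums of two independent FRET traces:
        # their acceptor channel decays in two steps
        p = TraceSimParams(
            true_distance=4.8, seed=31, acceptor_bleach_rate=0.008,
            donor_bleach_rate=0.0,
        )
        ts = simulate_trace_cohort(120, p)
        contaminated = []
        for a, b in zip(ts.traces[:60], ts.traces[60:]):
            contaminated.append(
                make_trace(a.I_DD + b.I_DD, a.I_DA + b.I_DA, a.I_AA + b.I_AA)
            )
        # drop pairs whose bleach frames nearly coincide (a genuine
        # single-step morphology)
        distinct = [
            t
            for t, ga, gb in zip(
                contaminated, ts.truths[:60], ts.truths[60:]
            )
            if abs(ga.bleach_frames["acceptor"] - gb.bleach_frames["acceptor"]) > 20
        ]
        accepted = select_fret_traces(distinct)
        assert len(distinct) >= 30
        assert len(accepted) <= 0.1 * len(distinct)


class TestFactorEstimation:
    def test_alpha_exact_on_proportional_channels(self):
        n = 100
        dd = np.full(n, 200.0)
        donor = make_trace(dd, 0.1 * dd, np.zeros(n))
        acceptor = make_trace(np.zeros(n), np.zeros(n), np.full(n, 300.0))
        alpha, delta = estimate_alpha_delta([donor], [acceptor])
        assert alpha == pytest.approx(0.1, rel=1e-12)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_alpha_delta_recovery_from_simulation(self):
        p = TraceSimParams(alpha=0.08, delta=0.05, seed=5,
                           donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)
        ts = simulate_trace_cohort(200, p, 0.5, 0.5)
        alpha, delta = estimate_alpha_delta(
            ts.by_species("donor_only"),
            ts.by_species("acceptor_only"),
            (10.0, 10.0, 10.0),
        )
        assert alpha == pytest.approx(0.08, abs=0.01)
        assert delta == pytest.approx(0.05, abs=0.01)

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            estimate_alpha_delta([], [])

    @pytest.mark.parametrize("gamma_true", [1.0, 1.5])
    def test_gamma_exact_on_noiseless_trace(self, gamma_true):
        # closed-form trace: E=0.6, N_D=500, acceptor bleaches at 100
        n, ab, E, N = 200, 100, 0.6, 500.0
        pre = np.arange(n) < ab
        I_DD = np.where(pre, (1 - E) * N, N)
        I_DA = np.where(pre, gamma_true * E * N, 0.0)
        I_AA = np.where(pre, 800.0, 0.0)
        sel = select_fret_traces([make_trace(I_DD, I_DA, I_AA)])
        assert len(sel) == 1
        assert estimate_gamma(sel, 0.0, 0.0) == pytest.approx(gamma_true, rel=1e-9)

    def test_gamma_recovery_from_noisy_cohort(self):
        p = TraceSimParams(true_distance=5.5, gamma=0.9, alpha=0.05, delta=0.05,
                           seed=17)
        ts = simulate_trace_cohort(150, p)
        sel = select_fret_traces(ts.traces)
        assert len(sel) >= 50
        g = estimate_gamma(sel, 0.05, 0.05)
        assert g == pytest.approx(0.9, abs=0.05)

    @pytest.mark.parametrize(
        "aa,dd,gamma,expected", [(100.0, 100.0, 1.0, 1.0), (200.0, 100.0, 1.0, 2.0)]
    )
    def test_beta_direct_ratio(self, aa, dd, gamma, expected):
        assert beta_from_means(aa, dd, gamma) == expected

    def test_beta_recovery_from_cohort(self):
        p = TraceSimParams(true_distance=4.8, beta=1.3, seed=23)
        ts = simulate_trace_cohort(150, p)
        sel = select_fret_traces(ts.traces)
        g = estimate_gamma(sel, p.alpha, p.delta)
        from fretarch.traces import compute_beta

        assert compute_beta(sel, g) == pytest.approx(1.3, abs=0.05)


class TestComputeES:
    def test_symmetric_channels(self):
        pt = compute_e_s(100.0, 100.0, 100.0, CorrectionFactors())
        assert pt.E == pytest.approx(0.5)
        assert pt.S == pytest.approx(2 / 3)

    def test_donor_only_gives_e0_s1(self):
        f = CorrectionFactors(alpha=0.1)
        pt = compute_e_s(100.0, 10.0, 0.0, f)
        assert pt.E == pytest.approx(0.0, abs=1e-12)
        assert pt.S == pytest.approx(1.0)

    def test_correction_arithmetic(self):
        f = CorrectionFactors(alpha=0.1, delta=0.05, gamma=1.0, beta=1.0)
        pt = compute_e_s(100.0, 20.0, 100.0, f)
        assert pt.E == pytest.approx(5 / 105, rel=1e-12)
        assert pt.S == pytest.approx(105 / 205, rel=1e-12)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            compute_e_s(0.0, 0.0, 0.0, CorrectionFactors())

    @settings(derandomize=True, max_examples=40)
    @given(
        e=st.floats(0.05, 0.95),
        alpha=st.floats(0.0, 0.2),
        delta=st.floats(0.0, 0.2),
        gamma=st.floats(0.5, 2.0),
        beta=st.floats(0.5, 2.0),
    )
    def test_round_trip_exactness_on_noiseless_windows(
        self, e, alpha, delta, gamma, beta
    ):
        # windows generated with factors F are inverted exactly by
        # compute_e_s with the same F
        N = 1000.0
        aa = beta * gamma * N
        dd = (1 - e) * N
        da = gamma * e * N + alpha * dd + delta * aa
        f = CorrectionFactors(alpha, delta, gamma, beta)
        pt = compute_e_s(dd, da, aa, f)
        assert pt.E == pytest.approx(e, rel=1e-10, abs=1e-12)
        assert pt.S == pytest.approx(0.5, rel=1e-10)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 50.0))
    def test_efficiency_invariant_under_common_rescale(self, scale):
        f = CorrectionFactors(0.07, 0.04, 1.2, 1.1)
        a = compute_e_s(100.0, 60.0, 130.0, f)
        b = compute_e_s(100.0 * scale, 60.0 * scale, 130.0 * scale, f)
        assert b.E == pytest.approx(a.E, rel=1e-9)
        assert b.S == pytest.approx(a.S, rel=1e-9)


class TestPopulationFit:
    def test_gaussian_sample_recovered(self):
        rng = np.random.default_rng(0)
        pts = [
            ESPoint(E=float(e), S=0.5)
            for e in rng.normal(0.84, 0.06, 113)
        ]
        pop = fit_es_population(pts)
        assert pop.mean_E == pytest.approx(0.84, abs=0.02)

    def test_degenerate_sample_short_circuits(self):
        pts = [ESPoint(E=0.5, S=0.5) for _ in range(20)]
        pop = fit_es_population(pts)
        assert pop.mean_E == 0.5 and pop.sigma_E == 0.0

    def test_too_few_points_in_window(self):
        pts = [ESPoint(E=0.5, S=0.9) for _ in range(20)]
        with pytest.raises(ValueError):
            fit_es_population(pts, s_window=(0.3, 0.7))


class TestEndToEndRecovery:
    @pytest.mark.parametrize("e_true", [0.1, 0.3, 0.55, 0.84, 0.90])
    def test_cohort_recovers_true_efficiency(self, e_true):
        distance = efficiency_to_distance(e_true, R0_T)
        p = TraceSimParams(
            true_distance=distance,
            alpha=0.06,
            delta=0.05,
            gamma=1.1,
            beta=1.2,
            seed=int(1000 * e_true),
        )
        ts = simulate_trace_cohort(250, p, 0.1, 0.1)
        res = analyze_cohort(ts)
        assert abs(res.population.mean_E - e_true) < 0.02
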