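"""ALEX trace selection, correction-factor estimation and E/S population fits.

The analysis chain for camera-based alternating-laser-excitation (ALEX)
single-molecule FRET:

1. detect single-step photobleaching in the donor and acceptor channels;
2. keep traces with exactly one acceptor bleach step, an anticorrelated
   donor-intensity rise at that frame, and at most one later donor step
   (the single-pair criterion);
3. estimate the correction factors: leakage ``alpha`` from donor-only
   traces, direct excitation ``delta`` from acceptor-only traces, the
   detection/quantum-yield factor ``gamma`` trace-wise across the acceptor
   bleach, and the excitation-balance factor
   ``beta = avg(I_AA) / avg(gamma * I_DD)``;
4. compute corrected FRET efficiency E and stoichiometry S on window
   averages:

       F_corr = I_DA - alpha*I_DD - delta*I_AA
       E      = F_corr / (gamma*I_DD + F_corr)
       S      = (gamma*I_DD + F_corr) / (gamma*I_DD + F_corr + I_AA/beta)

5. fit a Gaussian to the E histogram of points inside an S window to
   obtain the population mean and width.

Background handling: the per-trace post-bleach window (both fluorophores
dark) provides a per-channel background estimate that is subtracted before
corrections; when a trace never goes fully dark a caller-supplied
background (e.g. from simulation settings) can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AlexTrace",
    "CorrectionFactors",
    "ESPoint",
    "FretPopulation",
    "BleachStep",
    "detect_bleach_steps",
    "select_fret_traces",
    "estimate_alpha_delta",
    "estimate_gamma",
    "compute_beta",
    "compute_e_s",
    "fit_es_population",
    "trace_background",
]

MIN_DWELL_DEFAULT = 5


@dataclass
class AlexTrace:
    """Per-frame three-channel ALEX intensity record.

    ``I_DD``: donor emission under donor excitation; ``I_DA``: acceptor
    emission under donor excitation (FRET channel); ``I_AA``: acceptor
    emission under acceptor excitation.  Channels are photons/frame.
    """

    frame: np.ndarray
    I_DD: np.ndarray
    I_DA: np.ndarray
    I_AA: np.ndarray
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        for name in ("I_DD", "I_DA", "I_AA"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.frame)
        if not all(len(getattr(self, c)) == n for c in ("I_DD", "I_DA", "I_AA")):
            raise ValueError("channel lengths differ")
        if n > 1 and not np.all(np.diff(self.frame) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CorrectionFactors:
    """Leakage alpha, direct-excitation delta, detection factor gamma and
    excitation-balance beta."""

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")


@dataclass(frozen=True)
class ESPoint:
    E: float
    S: float
    trace_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.E) and np.isfinite(self.S)):
            raise ValueError("E and S must be finite")


@dataclass(frozen=True)
class FretPopulation:
    """Gaussian fit of the efficiency histogram of one population."""

    mean_E: float
    sigma_E: float
    n_traces: int
    s_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_traces < 1 or self.sigma_E < 0:
            raise ValueError("need n_traces >= 1 and sigma_E >= 0")


@dataclass(frozen=True)
class BleachStep:
    frame: int
    sign: int  # -1 for an intensity drop, +1 for a rise
    amplitude: float


def _local_noise_sd(series: np.ndarray) -> float:
    """Robust noise scale from first differences (steps affect few points)."""
    d = np.diff(series)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_bleach_steps(
    series: Sequence[float],
    min_dwell: int = MIN_DWELL_DEFAULT,
    threshold: float = 5.0,
) -> list[BleachStep]:
    """Detect abrupt intensity steps via binary segmentation on a
    two-window mean-shift statistic.

    At candidate frame ``t`` the statistic is the difference between the
    means of the ``min_dwell`` frames ending before ``t`` and starting at
    ``t``; a step is accepted when it exceeds ``threshold`` times the
    local noise standard deviation.  Segmentation recurses on both sides
    so multi-step traces (contaminants) are found and can be rejected.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 2 * min_dwell:
        raise ValueError(f"series of length {len(y)} shorter than 2*min_dwell")
    steps: list[BleachStep] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_dwell:
            return
        seg = y[lo:hi]
        # cumulative sums for O(1) window means at each split
        cs = np.concatenate([[0.0], np.cumsum(seg)])
        best_t, best_amp = -1, 0.0
        for t in range(min_dwell, n - min_dwell + 1):
            left = (cs[t] - cs[t - min_dwell]) / min_dwell
            right = (cs[t + min_dwell] - cs[t]) / min_dwell
            amp = right - left
            if abs(amp) > abs(best_amp):
                best_amp, best_t = amp, t
        if best_t < 0:
            return
        # shot noise is level-dependent, so the scale must be local: use
        # the larger of the two flanking-region noise estimates
        flank = 5 * min_dwell
        sd = max(
            _local_noise_sd(seg[max(0, best_t - flank) : best_t]),
            _local_noise_sd(seg[best_t : best_t + flank]),
        )
        se_amp = sd * np.sqrt(2.0 / min_dwell)
        if sd == 0.0:
            significant = abs(best_amp) > 0.0
        else:
            significant = abs(best_amp) > threshold * se_amp
        if not significant:
            return
        steps.append(
            BleachStep(
                frame=lo + best_t,
                sign=int(np.sign(best_amp)),
                amplitude=float(best_amp),
            )
        )
        recurse(lo, lo + best_t)
        recurse(lo + best_t, hi)

    recurse(0, len(y))
    return sorted(steps, key=lambda s: s.frame)


def trace_background(
    trace: AlexTrace,
    donor_bleach: int | None,
    acceptor_bleach: int | None,
    min_dwell: int = MIN_DWELL_DEFAULT,
) -> tuple[float, float, float] | None:
    """Per-channel background from the window where both dyes are dark.

    Returns ``(bg_DD, bg_DA, bg_AA)`` or ``None`` when the trace has no
    post-bleach window of at least ``min_dwell`` frames.
    """
    if donor_bleach is None or acceptor_bleach is None:
        return None
    start = max(donor_bleach, acceptor_bleach)
    if len(trace) - start < min_dwell:
        return None
    sl = slice(start, None)
    return (
        float(np.mean(trace.I_DD[sl])),
        float(np.mean(trace.I_DA[sl])),
        float(np.mean(trace.I_AA[sl])),
    )


@dataclass
class SelectedTrace:
    trace: AlexTrace
    acceptor_bleach: int
    donor_bleach: int | None
    background: tuple[float, float, float]


def select_fret_traces(
    traces: Sequence[AlexTrace],
    min_dwell: int = MIN_DWELL_DEFAULT,
    threshold: float = 5.0,
    default_background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    require_rise: bool = False,
) -> list[SelectedTrace]:
    """Keep single-pair FRET traces.

    A trace is accepted when its acceptor channel (``I_AA``) shows exactly
    one downward bleach step, the donor channel shows at most one downward
    step occurring later, and the donor intensity behaves anticorrelated
    at the acceptor bleach frame: a detected donor rise there confirms the
    pair, a detected donor *drop* there contradicts it and rejects the
    trace.  At low transfer efficiency the expected rise (E times the
    donor budget) sinks below the step-detection threshold, so the
    absence of any detected donor change at the bleach frame is accepted;
    with ``require_rise`` the strict rule (rise mandatory) is enforced.
    Multi-step decays from multiple fluorophores are rejected.
    """
    accepted: list[SelectedTrace] = []
    for tr in traces:
        if len(tr) < 2 * min_dwell:
            continue
        aa_steps = detect_bleach_steps(tr.I_AA, min_dwell, threshold)
        aa_down = [s for s in aa_steps if s.sign < 0]
        if len(aa_down) != 1 or len(aa_steps) != 1:
            continue
        a_bleach = aa_down[0].frame
        dd_steps = detect_bleach_steps(tr.I_DD, min_dwell, threshold)
        # the donor rise at the acceptor bleach is expected; drops elsewhere
        # must be a single, later donor bleach
        rises = [s for s in dd_steps if s.sign > 0]
        drops = [s for s in dd_steps if s.sign < 0]
        drops_at_bleach = [s for s in drops if abs(s.frame - a_bleach) <= min_dwell]
        late_drops = [s for s in drops if s.frame > a_bleach + min_dwell]
        if drops_at_bleach or len(late_drops) > 1:
            continue
        if len(drops) > len(late_drops):  # early donor loss
            continue
        rise_at_bleach = any(abs(s.frame - a_bleach) <= min_dwell for s in rises)
        if require_rise and not rise_at_bleach:
            continue
        if len(rises) > 1 or (rises and not rise_at_bleach):
            continue
        d_bleach = late_drops[0].frame if late_drops else None
        bg = trace_background(tr, d_bleach, a_bleach, min_dwell)
        accepted.append(
            SelectedTrace(
                trace=tr,
                acceptor_bleach=a_bleach,
                donor_bleach=d_bleach,
                background=bg if bg is not None else default_background,
            )
        )
    return accepted


def estimate_alpha_delta(
    donor_only: Sequence[AlexTrace],
    acceptor_only: Sequence[AlexTrace],
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[float, float]:
    """Leakage and direct-excitation factors from single-dye species.

    ``alpha`` is the mean over donor-only traces of ``I_DA / I_DD`` and
    ``delta`` the mean over acceptor-only traces of ``I_DA / I_AA``, each
    on background-subtracted pre-bleach window averages.
    """
    if len(donor_only) == 0 or len(acceptor_only) == 0:
        raise ValueError("need at least one trace per single-dye species")
    bg_dd, bg_da, bg_aa = background

    def prebleach_mean(tr: AlexTrace, channel: np.ndarray, ref: np.ndarray):
        steps = [s for s in detect_bleach_steps(ref) if s.sign < 0]
        end = steps[0].frame if steps else len(tr)
        return np.mean(channel[:end]) if end >= MIN_DWELL_DEFAULT else None

    alphas = []
    for tr in donor_only:
        dd = prebleach_mean(tr, tr.I_DD, tr.I_DD)
        da = prebleach_mean(tr, tr.I_DA, tr.I_DD)
        if dd is not None and da is not None and dd - bg_dd > 0:
            alphas.append((da - bg_da) / (dd - bg_dd))
    deltas = []
    for tr in acceptor_only:
        aa = prebleach_mean(tr, tr.I_AA, tr.I_AA)
        da = prebleach_mean(tr, tr.I_DA, tr.I_AA)
        if aa is not None and da is not None and aa - bg_aa > 0:
            deltas.append((da - bg_da) / (aa - bg_aa))
    if not alphas or not deltas:
        raise ValueError("no usable single-dye traces for alpha/delta")
    return float(np.mean(alphas)), float(np.mean(deltas))


def estimate_gamma(
    selected: Sequence[SelectedTrace],
    alpha: float,
    delta: float,
    min_dwell: int = MIN_DWELL_DEFAULT,
    robust: bool = False,
) -> float:
    """Detection/quantum-yield factor from the acceptor-bleach step.

    Per trace, gamma = -dI_DA' / dI_DD across the acceptor bleach, where
    primes denote leakage- and direct-excitation-corrected intensities and
    d is (post - pre) window mean change.  The returned value is the mean
    over traces (median when ``robust``), matching the convention of
    applying mean correction factors to a dataset.
    """
    gammas = []
    for sel in selected:
        tr, ab = sel.trace, sel.acceptor_bleach
        end = sel.donor_bleach if sel.donor_bleach is not None else len(tr)
        if ab < min_dwell or end - ab < min_dwell:
            continue
        bg_dd, bg_da, bg_aa = sel.background
        pre = slice(0, ab)
        post = slice(ab, end)

        def corr_da(sl):
            return (
                np.mean(tr.I_DA[sl]) - bg_da
                - alpha * (np.mean(tr.I_DD[sl]) - bg_dd)
                - delta * (np.mean(tr.I_AA[sl]) - bg_aa)
            )

        d_da = corr_da(post) - corr_da(pre)
        d_dd = (np.mean(tr.I_DD[post]) - np.mean(tr.I_DD[pre]))
        if d_dd > 0:
            gammas.append(-d_da / d_dd)
    if not gammas:
        raise ValueError("no traces with usable pre/post acceptor-bleach windows")
    return float(np.median(gammas) if robust else np.mean(gammas))


def compute_beta(
    selected: Sequence[SelectedTrace],
    gamma: float,
    min_dwell: int = MIN_DWELL_DEFAULT,
) -> float:
    """Excitation-balance factor ``beta = avg(I_AA) / (gamma * avg(I_DD))``.

    The numerator averages the directly excited acceptor signal over the
    pre-acceptor-bleach windows.  The denominator wants the *unquenched*
    donor emission ("donor emission from direct excitation"), which in a
    FRET trace is only observed after the acceptor has bleached — so the
    donor mean is taken on the post-acceptor-bleach window when one of at
    least ``min_dwell`` frames exists, falling back to the pre-bleach
    window otherwise.  All means are background-subtracted.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    aa_vals, dd_vals = [], []
    for sel in selected:
        if sel.acceptor_bleach < min_dwell:
            continue
        bg_dd, _, bg_aa = sel.background
        pre = slice(0, sel.acceptor_bleach)
        aa_vals.append(np.mean(sel.trace.I_AA[pre]) - bg_aa)
        # total donor photons: donor emission plus FRET-transferred quanta
        end = sel.donor_bleach if sel.donor_bleach is not None else len(sel.trace)
        post = slice(sel.acceptor_bleach, end)
        if end - sel.acceptor_bleach >= min_dwell:
            dd_vals.append(np.mean(sel.trace.I_DD[post]) - bg_dd)
        else:
            dd_vals.append(np.mean(sel.trace.I_DD[pre]) - bg_dd)
    if not aa_vals or np.mean(dd_vals) <= 0:
        raise ValueError("beta denominator is zero or no usable windows")
    return float(np.mean(aa_vals) / (gamma * np.mean(dd_vals)))


def beta_from_means(avg_I_AA: float, avg_I_DD: float, gamma: float) -> float:
    """``beta = avg(I_AA) / (gamma * avg(I_DD))`` on given window means."""
    denom = gamma * avg_I_DD
    if denom == 0:
        raise ZeroDivisionError("zero denominator in beta")
    return avg_I_AA / denom


def compute_e_s(
    I_DD: float,
    I_DA: float,
    I_AA: float,
    factors: CorrectionFactors,
    trace_id: str = "",
) -> ESPoint:
    """Corrected FRET efficiency and stoichiometry from window-averaged
    background-subtracted intensities.

    ``F_corr = I_DA - alpha*I_DD - delta*I_AA``;
    ``E = F_corr / (gamma*I_DD + F_corr)``;
    ``S = (gamma*I_DD + F_corr) / (gamma*I_DD + F_corr + I_AA/beta)``.
    """
    f = factors
    f_corr = I_DA - f.alpha * I_DD - f.delta * I_AA
    denom_e = f.gamma * I_DD + f_corr
    denom_s = denom_e + I_AA / f.beta
    if denom_e == 0 or denom_s == 0:
        raise ZeroDivisionError(f"zero denominator in E/S for trace {trace_id!r}")
    return ESPoint(E=f_corr / denom_e, S=denom_e / denom_s, trace_id=trace_id)


def es_points_from_selected(
    selected: Sequence[SelectedTrace],
    factors: CorrectionFactors,
    min_dwell: int = MIN_DWELL_DEFAULT,
) -> list[ESPoint]:
    """E/S per accepted trace on the pre-first-bleach window average."""
    points = []
    for sel in selected:
        end = sel.acceptor_bleach
        if sel.donor_bleach is not None:
            end = min(end, sel.donor_bleach)
        if end < min_dwell:
            continue
        bg_dd, bg_da, bg_aa = sel.background
        pre = slice(0, end)
        try:
            points.append(
                compute_e_s(
                    float(np.mean(sel.trace.I_DD[pre]) - bg_dd),
                    float(np.mean(sel.trace.I_DA[pre]) - bg_da),
                    float(np.mean(sel.trace.I_AA[pre]) - bg_aa),
                    factors,
                    trace_id=sel.trace.trace_id,
                )
            )
        except ZeroDivisionError:
            continue
    return points


def fit_es_population(
    points: Sequence[ESPoint],
    s_window: tuple[float, float] = (0.3, 0.7),
    bins: int = 40,
    e_range: tuple[float, float] | None = None,
) -> FretPopulation:
    """Gaussian fit to the E histogram of points inside the S window.

    Least-squares fit of ``a * exp(-(x - mu)^2 / (2 sigma^2))`` to the
    histogram counts.  The histogram range defaults to the sample mean
    ±8 sample standard deviations so that narrow populations are still
    resolved by several bins; a degenerate (near-constant) sample
    short-circuits to its mean with sigma ~ 0.
    """
    lo, hi = s_window
    e_vals = np.array([p.E for p in points if lo <= p.S <= hi])
    if len(e_vals) < 10:
        raise ValueError(
            f"only {len(e_vals)} points inside S window {s_window}; need >= 10"
        )
    if np.std(e_vals) < 1e-12:
        return FretPopulation(float(e_vals[0]), 0.0, len(e_vals), s_window)
    if e_range is None:
        m, s = float(np.mean(e_vals)), float(np.std(e_vals))
        e_range = (m - 8.0 * s, m + 8.0 * s)
    counts, edges = np.histogram(e_vals, bins=bins, range=e_range)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = (float(counts.max()), float(np.mean(e_vals)), float(np.std(e_vals)))
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian population fit did not converge: {exc}")
    return FretPopulation(
        mean_E=float(popt[1]),
        sigma_E=float(abs(popt[2])),
        n_traces=len(e_vals),
        s_window=s_window,
    )
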