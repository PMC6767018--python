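"""Spectrum matching: correcting NaI(Tl) readings against an ion chamber.

A measured well-counter spectrum is compared to simulated spectra of
the same sample at a sweep of candidate activities (the three gamma
emitters taken at equal activities — the secular-equilibrium
condition).  The comparison statistic is the mean percent difference
over analogous bins, with the symmetric mean denominator

    %diff(a, b) = 100 * (a - b) / ((a + b) / 2)

(signed, simulated minus measured; the absolute form for reporting).
The signed differences are close to linear in the simulated activity,
so a straight-line fit over the sweep gives the matched activity as
the x-intercept — the activity whose simulation best reproduces the
measurement.  Repeating per sample yields the response curve between
ion-chamber readings and matched NaI(Tl)-equivalent activities; its
flattening at high activity is the signature of dead-time losses the
ideal simulation does not contain.

Matched-activity uncertainty combines counting statistics of the
measurement, the ion-chamber reading uncertainty and Monte Carlo
statistics in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spectra import PulseHeightSpectrum

#: bins where both spectra fall below this count are excluded from the mean
DEFAULT_COUNT_THRESHOLD = 10.0


class BracketError(ValueError):
    """The activity sweep does not bracket a sign change; widen the sweep."""


def mean_percent_diff(a: float, b: float) -> float:
    """Percent difference of two scalars with the symmetric mean denominator."""
    if a + b <= 0:
        raise ValueError("a + b must be positive")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


def spectrum_percent_diff(
    measured: PulseHeightSpectrum,
    simulated: PulseHeightSpectrum,
    *,
    signed: bool = False,
    count_threshold: float = DEFAULT_COUNT_THRESHOLD,
) -> float:
    """Mean (signed or absolute) percent difference over analogous bins.

    Signed convention: simulated minus measured.  Bins where both
    spectra are below ``count_threshold`` carry no information about
    the match and are excluded.
    """
    if not measured.same_binning(simulated):
        raise ValueError("spectra binning mismatch")
    m, s = measured.counts, simulated.counts
    include = (m >= count_threshold) | (s >= count_threshold)
    include &= (m + s) > 0
    if not include.any():
        raise ValueError("no bins above the count threshold")
    diff = 200.0 * (s[include] - m[include]) / (s[include] + m[include])
    if not signed:
        diff = np.abs(diff)
    return float(diff.mean())


@dataclass
class MatchResult:
    ic_reading_kbq: float
    sigma_ic_kbq: float
    swept_activities_kbq: np.ndarray
    signed_diffs: np.ndarray
    abs_diffs: np.ndarray
    slope: float
    intercept: float
    matched_activity_kbq: float
    residual_abs_diff: float
    sigma_nai_kbq: float
    sigma_mc_kbq: float

    @property
    def sigma_total_kbq(self) -> float:
        return combine_uncertainty(
            self.sigma_nai_kbq, self.sigma_ic_kbq, self.sigma_mc_kbq
        )


def combine_uncertainty(sigma_nai: float, sigma_ic: float, sigma_mc: float) -> float:
    """Quadrature combination of the three uncertainty components."""
    return math.sqrt(sigma_nai**2 + sigma_ic**2 + sigma_mc**2)


def _mean_diff_noise(
    measured: PulseHeightSpectrum,
    simulated: PulseHeightSpectrum,
    count_threshold: float,
) -> tuple[float, float]:
    """Std. of the mean signed %diff from (measurement, MC) counting noise."""
    m, s = measured.counts, simulated.counts
    include = ((m >= count_threshold) | (s >= count_threshold)) & ((m + s) > 0)
    k = int(include.sum())
    m_in, s_in = m[include], s[include]
    # d/ds of 200(s-m)/(s+m) = 400 m/(s+m)^2 ; d/dm is the negative with s<->m
    rel_mc = (
        simulated.rel_err[include]
        if simulated.rel_err is not None
        else np.zeros(k)
    )
    var_mc = np.sum((400.0 * m_in / (s_in + m_in) ** 2 * s_in * rel_mc) ** 2) / k**2
    sig_m = np.sqrt(np.maximum(m_in, 0.0))  # Poisson counting noise
    var_nai = np.sum((400.0 * s_in / (s_in + m_in) ** 2 * sig_m) ** 2) / k**2
    return math.sqrt(var_nai), math.sqrt(var_mc)


def sweep_match(
    measured: PulseHeightSpectrum,
    initial_guess_kbq: float,
    simulate: Callable[[float, int], PulseHeightSpectrum],
    *,
    ic_reading_kbq: float | None = None,
    sigma_ic_kbq: float = 0.0,
    sweep_fraction: float = 0.5,
    n_points: int = 7,
    seed: int = 0,
    count_threshold: float = DEFAULT_COUNT_THRESHOLD,
    auto_expand: bool = False,
    max_expansions: int = 6,
    refine_fraction: float | None = 0.15,
) -> MatchResult:
    """Find the simulated activity matching a measured spectrum.

    ``simulate(activity_kbq, seed)`` must return a broadened simulated
    spectrum on the measured binning (equal per-nuclide activities).
    Activities ``initial_guess * linspace(1 - f, 1 + f, n)`` are swept;
    the signed mean percent differences are fitted with a straight line
    whose x-intercept is the matched activity.  If the sweep does not
    bracket a sign change a :class:`BracketError` is raised, unless
    ``auto_expand`` recenters/widens the sweep (geometric steps, up to
    ``max_expansions`` times).

    The per-bin percent difference saturates at +-200, so over a wide
    sweep the signed mean is concave in activity and a single straight
    line overshoots the root by a few percent.  With ``refine_fraction``
    set (default 0.15) a second, narrow sweep recentered on the first
    x-intercept removes that curvature bias; pass ``None`` to keep the
    single-pass behavior.
    """
    if initial_guess_kbq <= 0:
        raise ValueError("initial guess must be positive")
    if not 0 < sweep_fraction < 1:
        raise ValueError("sweep_fraction must be in (0, 1)")

    def run_sweep(center: float, fraction: float, seed0: int):
        acts = center * np.linspace(1 - fraction, 1 + fraction, n_points)
        sims = [simulate(a, seed0 + k) for k, a in enumerate(acts)]
        ds = np.array(
            [
                spectrum_percent_diff(
                    measured, s, signed=True, count_threshold=count_threshold
                )
                for s in sims
            ]
        )
        return acts, ds

    guess = initial_guess_kbq
    for attempt in range(max_expansions + 1):
        activities, diffs = run_sweep(guess, sweep_fraction, seed + 1000 * attempt)
        if diffs.min() < 0 < diffs.max():
            break
        if not auto_expand or attempt == max_expansions:
            raise BracketError(
                f"signed differences do not change sign over "
                f"[{activities[0]:.4g}, {activities[-1]:.4g}] kBq: bracket wider"
            )
        # all-positive: simulation overshoots everywhere -> go lower, and v.v.
        guess *= 0.5 if diffs.min() > 0 else 2.0

    def intercept_of(acts, ds):
        sl, ic = np.polyfit(acts, ds, 1)
        if abs(sl) < 1e-12:
            raise ValueError("near-zero slope: sweep uninformative")
        return sl, ic, -ic / sl

    slope, intercept, matched = intercept_of(activities, diffs)
    if matched <= 0:
        raise ValueError(f"x-intercept {matched:.4g} kBq is nonpositive")
    if refine_fraction is not None and refine_fraction < sweep_fraction:
        acts2, diffs2 = run_sweep(matched, refine_fraction, seed + 500_000)
        sl2, ic2, matched2 = intercept_of(acts2, diffs2)
        # keep the refinement only if it stayed inside the narrow sweep's reach
        if sl2 > 0 and acts2[0] / 2 < matched2 < acts2[-1] * 2:
            activities, diffs = acts2, diffs2
            slope, intercept, matched = sl2, ic2, matched2
    final = simulate(matched, seed + 7919)
    residual = spectrum_percent_diff(
        measured, final, signed=False, count_threshold=count_threshold
    )
    sig_d_nai, sig_d_mc = _mean_diff_noise(measured, final, count_threshold)
    return MatchResult(
        ic_reading_kbq=ic_reading_kbq if ic_reading_kbq is not None else guess,
        sigma_ic_kbq=sigma_ic_kbq,
        swept_activities_kbq=activities,
        signed_diffs=diffs,
        abs_diffs=np.abs(diffs),
        slope=float(slope),
        intercept=float(intercept),
        matched_activity_kbq=float(matched),
        residual_abs_diff=float(residual),
        sigma_nai_kbq=sig_d_nai / abs(slope),
        sigma_mc_kbq=sig_d_mc / abs(slope),
    )


@dataclass
class ResponseCurve:
    """Ordered (ion-chamber reading, matched activity) pairs with uncertainties."""

    ic_readings_kbq: np.ndarray
    matched_kbq: np.ndarray
    sigmas_kbq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ic_readings_kbq = np.asarray(self.ic_readings_kbq, dtype=float)
        self.matched_kbq = np.asarray(self.matched_kbq, dtype=float)
        order = np.argsort(self.ic_readings_kbq)
        self.ic_readings_kbq = self.ic_readings_kbq[order]
        self.matched_kbq = self.matched_kbq[order]
        if self.sigmas_kbq is None:
            self.sigmas_kbq = np.zeros_like(self.matched_kbq)
        else:
            self.sigmas_kbq = np.asarray(self.sigmas_kbq, dtype=float)[order]

    def correction(self, ic_reading_kbq: float) -> tuple[float, float]:
        """Interpolated corrected activity (and sigma) for an ion-chamber reading."""
        if len(self.ic_readings_kbq) < 2:
            raise ValueError("need at least 2 distinct points to interpolate")
        if len(np.unique(self.ic_readings_kbq)) < 2:
            raise ValueError("response-curve readings are all identical")
        a = float(np.interp(ic_reading_kbq, self.ic_readings_kbq, self.matched_kbq))
        s = float(np.interp(ic_reading_kbq, self.ic_readings_kbq, self.sigmas_kbq))
        return a, s


def build_response_curve(
    matches: list[tuple[float, MatchResult]] | list[MatchResult],
) -> ResponseCurve:
    """Assemble a sorted response curve from per-sample match results."""
    if matches and isinstance(matches[0], MatchResult):
        pairs = [(m.ic_reading_kbq, m) for m in matches]  # type: ignore[union-attr]
    else:
        pairs = list(matches)  # type: ignore[assignment]
    ic = np.array([p[0] for p in pairs])
    matched = np.array([p[1].matched_activity_kbq for p in pairs])
    sig = np.array([p[1].sigma_total_kbq for p in pairs])
    return ResponseCurve(ic, matched, sig)
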