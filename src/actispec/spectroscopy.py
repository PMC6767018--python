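"""Analysis of measured spectra: from counts to per-nuclide activities.

The quantification pipeline is the standard gamma-spectroscopy one:
subtract a background spectrum, fit each photopeak with a Gaussian on a
linear baseline to get net counts N, estimate the nonparalyzable dead
time tau by the two-source method and correct observed rates, then
convert net counts to activity

    A = f * N / (t * eps * Y)

with live time t, detection efficiency eps at the peak energy, gamma
abundance per alpha decay Y, and an optional instrument calibration
factor f (default 1).  Uncertainties propagate from the fitted net
area and the efficiency in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .nuclides import GAMMA_EMITTERS
from .spectra import PulseHeightSpectrum

#: principal analysis peaks (keV) of the three gamma emitters
PRINCIPAL_PEAKS_KEV = {"Ac-225": 99.8, "Fr-221": 218.1, "Bi-213": 440.5}
#: gamma abundance per alpha decay at the principal (composite) peaks
ABUNDANCE_FACTORS = {"Ac-225": 0.010, "Fr-221": 0.114, "Bi-213": 0.259}


@dataclass
class PeakFit:
    centroid_kev: float
    sigma_kev: float
    amplitude: float
    net_area: float
    net_area_sigma: float
    baseline: tuple[float, float]
    window_kev: tuple[float, float]
    ok: bool = True
    message: str = ""


@dataclass
class ActivityResult:
    nuclide: str
    activity_kbq: float
    sigma_kbq: float
    inputs: dict = field(default_factory=dict)


@dataclass
class DeadTime:
    """Nonparalyzable dead time: observed rate m = n / (1 + n*tau)."""

    tau_s: float
    model: str = "nonparalyzable"

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("dead time must be nonnegative")


@dataclass
class EfficiencyCurve:
    """Peak detection efficiency vs energy with log-linear interpolation."""

    energies_kev: np.ndarray
    efficiencies: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.efficiencies = np.asarray(self.efficiencies, dtype=float)
        order = np.argsort(self.energies_kev)
        self.energies_kev = self.energies_kev[order]
        self.efficiencies = self.efficiencies[order]
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)[order]
        if np.any((self.efficiencies <= 0) | (self.efficiencies >= 1)):
            raise ValueError("efficiencies must lie in (0, 1)")

    def __call__(self, energy_kev, *, extrapolate: bool = False):
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        if not extrapolate and (np.any(e < lo) or np.any(e > hi)):
            raise ValueError(
                f"energy outside calibrated range [{lo}, {hi}] keV; "
                "pass extrapolate=True to allow"
            )
        out = np.exp(np.interp(e, self.energies_kev, np.log(self.efficiencies)))
        return float(out) if np.isscalar(energy_kev) else out

    def sigma(self, energy_kev):
        if self.sigmas is None:
            return 0.0 if np.isscalar(energy_kev) else np.zeros_like(
                np.asarray(energy_kev, dtype=float)
            )
        out = np.interp(energy_kev, self.energies_kev, self.sigmas)
        return float(out) if np.isscalar(energy_kev) else out


def subtract_background(
    spectrum: PulseHeightSpectrum, background: PulseHeightSpectrum
) -> PulseHeightSpectrum:
    """Live-time-normalized background subtraction, clipped at zero."""
    if not spectrum.same_binning(background):
        raise ValueError("sample and background binning differ")
    scale = spectrum.live_time_s / background.live_time_s
    net = np.clip(spectrum.counts - background.counts * scale, 0.0, None)
    out = spectrum.with_counts(net)
    out.meta = {**spectrum.meta, "background_subtracted": True}
    return out


def default_windows(half_width_bins: float = 2.5, bin_width: float = 12.5):
    """Energy windows of +-``half_width_bins`` bins around the principal peaks."""
    hw = half_width_bins * bin_width
    return {n: (e - hw, e + hw) for n, e in PRINCIPAL_PEAKS_KEV.items()}


def _gauss_lin(x, amp, mu, sig, c0, c1):
    return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c0 + c1 * x


def fit_peaks(
    spectrum: PulseHeightSpectrum,
    windows: dict[str, tuple[float, float]] | list[tuple[float, float]] | None = None,
    *,
    resolution=None,
) -> dict[str, PeakFit] | list[PeakFit]:
    """Gaussian + linear-baseline fit in each window; N is the Gaussian integral.

    Windows spanning fewer than 4 bins are rejected.  Non-convergent or
    null fits come back flagged (``ok=False``, net area 0), not raised.

    The default windows are narrow (a handful of analyzer bins), which
    under counting noise under-determines a free five-parameter model;
    passing the detector's resolution calibration as ``resolution``
    (a GEBParams) fixes the Gaussian width to the calibrated sigma at
    each window center — the standard stabilization when the
    resolution function is known.
    """
    named = not isinstance(windows, list)
    if windows is None:
        windows = default_windows()
    items = windows.items() if named else list(enumerate(windows))
    results: dict[str, PeakFit] = {}
    x = spectrum.centers_kev
    width = float(np.mean(spectrum.widths_kev))
    for key, (lo, hi) in items:
        sel = (x >= lo) & (x <= hi)
        if sel.sum() < 4:
            raise ValueError(f"window {key} spans {int(sel.sum())} bins; need >= 4")
        xs, ys = x[sel], spectrum.counts[sel]
        if ys.sum() <= 0:
            results[key] = PeakFit(
                0.5 * (lo + hi), 0.0, 0.0, 0.0, 0.0, (0.0, 0.0), (lo, hi),
                ok=False, message="empty window",
            )
            continue
        mu0 = float(xs[np.argmax(ys)])
        base0 = float(min(ys))
        amp0 = max(float(ys.max() - base0), 1e-9)
        weights = np.sqrt(np.maximum(ys, 1.0))
        try:
            if resolution is not None:
                sig_cal = float(resolution.sigma_kev(0.5 * (lo + hi)))

                def model(x, amp, mu, c0, c1):
                    return _gauss_lin(x, amp, mu, sig_cal, c0, c1)

                popt, pcov = curve_fit(
                    model, xs, ys,
                    p0=(amp0, mu0, max(base0, 0.0), 0.0),
                    sigma=weights, absolute_sigma=True,
                    bounds=([0.0, lo, 0.0, -np.inf], [np.inf, hi, np.inf, np.inf]),
                    maxfev=20000,
                )
                amp, mu, c0, c1 = popt
                sig = sig_cal
                # sigma fixed: the area variance comes from the amplitude
                var = pcov[0, 0] * (sig * math.sqrt(2 * math.pi) / width) ** 2
            else:
                popt, pcov = curve_fit(
                    _gauss_lin, xs, ys,
                    p0=(amp0, mu0, max((hi - lo) / 6.0, width / 2.0), base0, 0.0),
                    sigma=weights, absolute_sigma=True,
                    bounds=(
                        [0.0, lo, width / 3.0, -np.inf, -np.inf],
                        [np.inf, hi, (hi - lo) / 2.0, np.inf, np.inf],
                    ),
                    maxfev=20000,
                )
                amp, mu, sig, c0, c1 = popt
                jac = (
                    np.array([sig, 0.0, amp, 0.0, 0.0])
                    * math.sqrt(2 * math.pi) / width
                )
                var = float(jac @ pcov @ jac)
        except (RuntimeError, ValueError) as err:
            results[key] = PeakFit(
                mu0, 0.0, 0.0, 0.0, 0.0, (base0, 0.0), (lo, hi),
                ok=False, message=f"fit failed: {err}",
            )
            continue
        area = amp * sig * math.sqrt(2 * math.pi) / width  # counts
        sigma_area = math.sqrt(max(var, 0.0))
        ok = area > 0 and area > sigma_area
        results[key] = PeakFit(
            float(mu), float(sig), float(amp), float(max(area, 0.0)), sigma_area,
            (float(c0), float(c1)), (lo, hi),
            ok=bool(ok), message="" if ok else "net area consistent with zero",
        )
    return results if named else [results[k] for k, _ in items]


def activity_from_peak(
    net_counts: float,
    live_time_s: float,
    efficiency: float,
    abundance: float,
    *,
    nuclide: str = "",
    calibration_factor: float = 1.0,
    sigma_counts: float = 0.0,
    sigma_efficiency: float = 0.0,
) -> ActivityResult:
    """Convert a net peak area to activity in kBq with propagated uncertainty."""
    if live_time_s <= 0 or efficiency <= 0 or abundance <= 0:
        raise ValueError("live time, efficiency and abundance must be positive")
    a_bq = calibration_factor * net_counts / (live_time_s * efficiency * abundance)
    rel2 = 0.0
    if net_counts > 0:
        rel2 += (sigma_counts / net_counts) ** 2
    rel2 += (sigma_efficiency / efficiency) ** 2
    return ActivityResult(
        nuclide=nuclide,
        activity_kbq=a_bq / 1e3,
        sigma_kbq=a_bq / 1e3 * math.sqrt(rel2),
        inputs={
            "net_counts": net_counts,
            "live_time_s": live_time_s,
            "efficiency": efficiency,
            "abundance": abundance,
            "calibration_factor": calibration_factor,
        },
    )


def dead_time_two_source(
    m1: float, m2: float, m12: float, b: float = 0.0, *, simplified: bool = False
) -> DeadTime:
    """Two-source dead-time estimate (nonparalyzable model).

    ``m1``/``m2`` are observed rates of each source alone (background
    included), ``m12`` both together, ``b`` background alone, all in
    1/s.  The exact solution is

        X = m1*m2 - b*m12
        Y = m1*m2*(m12 + b) - b*m12*(m1 + m2)
        Z = Y*(m1 + m2 - m12 - b) / X^2
        tau = X*(1 - sqrt(1 - Z)) / Y

    ``simplified=True`` uses the first-order cross-check formula
    tau = (m1 + m2 - m12 - b) / (m12^2 + b^2 - m1^2 - m2^2), valid for
    m*tau << 1.
    """
    if min(m1, m2, m12) < 0 or b < 0:
        raise ValueError("rates must be nonnegative")
    if m12 > m1 + m2 - b:
        raise ValueError(
            "m12 > m1 + m2 - b: no dead-time losses resolvable (inconsistent rates)"
        )
    if simplified:
        denom = m12**2 + b**2 - m1**2 - m2**2
        if denom <= 0:
            raise ValueError("simplified formula undefined for these rates")
        return DeadTime((m1 + m2 - m12 - b) / denom)
    x = m1 * m2 - b * m12
    y = m1 * m2 * (m12 + b) - b * m12 * (m1 + m2)
    if x <= 0 or y <= 0:
        raise ValueError("inconsistent rates (X or Y nonpositive)")
    z = y * (m1 + m2 - m12 - b) / x**2
    if z > 1:
        raise ValueError("inconsistent rates (Z > 1)")
    tau = x * (1.0 - math.sqrt(1.0 - z)) / y
    return DeadTime(max(tau, 0.0))


def dead_time_apply(rate_or_spectrum, dead_time: DeadTime):
    """Observed from true: m = n / (1 + n*tau).

    For a spectrum the total true rate drives a single thinning factor
    applied proportionally to every bin (single-channel-analyzer
    behavior: losses are count-rate driven, energy independent).
    """
    tau = dead_time.tau_s
    if isinstance(rate_or_spectrum, PulseHeightSpectrum):
        s = rate_or_spectrum
        n = s.total_rate
        factor = 1.0 / (1.0 + n * tau)
        out = s.scaled(factor)
        out.meta = {**s.meta, "dead_time_applied_s": tau}
        return out
    n = float(rate_or_spectrum)
    return n / (1.0 + n * tau)


def dead_time_correct(rate_or_spectrum, dead_time: DeadTime):
    """True from observed: n = m / (1 - m*tau); requires m*tau < 1."""
    tau = dead_time.tau_s
    if isinstance(rate_or_spectrum, PulseHeightSpectrum):
        s = rate_or_spectrum
        m = s.total_rate
        if m * tau >= 1:
            raise ValueError(f"observed rate {m:.4g}/s saturates dead time {tau:g} s")
        factor = 1.0 / (1.0 - m * tau)
        out = s.scaled(factor)
        out.meta = {**s.meta, "dead_time_corrected_s": tau}
        return out
    m = float(rate_or_spectrum)
    if m * tau >= 1:
        raise ValueError(f"observed rate {m:.4g}/s saturates dead time {tau:g} s")
    return m / (1.0 - m * tau)


def efficiency_from_sources(
    calibrations: list[dict],
) -> EfficiencyCurve:
    """Build an efficiency curve from calibration-source measurements.

    Each entry needs: ``spectrum`` (background-subtracted), ``energy_kev``
    of the principal line, ``activity_kbq`` (known), ``line_intensity``
    (photons per decay of that line) and optionally ``window_kev``.
    eps(E) = N / (t * A * Y_line) at each source energy.
    """
    energies, effs, sigs = [], [], []
    for cal in calibrations:
        spec: PulseHeightSpectrum = cal["spectrum"]
        e0 = float(cal["energy_kev"])
        act_bq = float(cal["activity_kbq"]) * 1e3
        intensity = float(cal["line_intensity"])
        window = cal.get("window_kev")
        if window is None:
            hw = 2.5 * float(np.mean(spec.widths_kev))
            window = (e0 - hw, e0 + hw)
        fit = fit_peaks(spec, [window])[0]
        if not fit.ok:
            raise ValueError(f"calibration peak at {e0} keV failed: {fit.message}")
        eps = fit.net_area / (spec.live_time_s * act_bq * intensity)
        if not 0 < eps < 1:
            raise ValueError(f"efficiency {eps:.4g} at {e0} keV outside (0, 1)")
        energies.append(e0)
        effs.append(eps)
        sigs.append(eps * fit.net_area_sigma / fit.net_area)
    return EfficiencyCurve(np.array(energies), np.array(effs), np.array(sigs))


def analyze_spectrum(
    spectrum: PulseHeightSpectrum,
    efficiency: EfficiencyCurve,
    *,
    background: PulseHeightSpectrum | None = None,
    dead_time: DeadTime | None = None,
    calibration_factor: float = 1.0,
    windows: dict[str, tuple[float, float]] | None = None,
    abundances: dict[str, float] | None = None,
    resolution=None,
) -> dict[str, ActivityResult]:
    """Full per-nuclide activity analysis of a measured chain spectrum.

    Dead-time correction (when given) is applied to the count rates
    before peak fitting; background is subtracted first.
    """
    abundances = abundances or ABUNDANCE_FACTORS
    if background is not None:
        spectrum = subtract_background(spectrum, background)
    if dead_time is not None and dead_time.tau_s > 0:
        spectrum = dead_time_correct(spectrum, dead_time)
    fits = fit_peaks(spectrum, windows or default_windows(), resolution=resolution)
    results = {}
    for name in GAMMA_EMITTERS:
        fit = fits[name]
        eps = efficiency(PRINCIPAL_PEAKS_KEV[name], extrapolate=True)
        sig_eps = efficiency.sigma(PRINCIPAL_PEAKS_KEV[name])
        results[name] = activity_from_peak(
            fit.net_area,
            spectrum.live_time_s,
            eps,
            abundances[name],
            nuclide=name,
            calibration_factor=calibration_factor,
            sigma_counts=fit.net_area_sigma,
            sigma_efficiency=float(sig_eps),
        )
        results[name].inputs["peak_ok"] = fit.ok
    return results
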