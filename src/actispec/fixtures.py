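"""Synthetic measurement fixtures built from the forward model.

No real well-counter spectra are distributed with the package, so
every pipeline input is emulated: a synthetic "measured" spectrum is
the ideal transport spectrum pushed through the full acquisition
chain — deterministic Gaussian energy broadening, nonparalyzable
dead-time thinning of the total count rate, per-bin Poisson sampling,
and additive background counts.  The generating truth (activities,
tau, background rate, seed) is recorded in the spectrum metadata so
recovery tests can close the loop.

Defaults mirror the study conditions of the measurement campaign the
model emulates: 30 s acquisitions, a flat background of 150 counts per
minute, dead time 4.6e-5 s, and a six-sample activity ladder of
ion-chamber readings 70.3-447.7 kBq with the three gamma emitters in
secular equilibrium (equal activities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montecarlo import TransportConfig, simulate_spectrum
from .response import FWHMPoint, GEBParams, apply_geb
from .spectra import PulseHeightSpectrum
from .spectroscopy import DeadTime, dead_time_apply

#: published GEB parameter set of the modeled instrument (MeV units)
DEFAULT_GEB = GEBParams(a=0.005616, b=0.0521, c=2.027, energy_unit="MeV")
#: FWHM calibration energies (keV) of the five reference sources
CALIBRATION_ENERGIES_KEV = (39.5, 59.5, 122.0, 511.0, 661.6)
#: six-sample ion-chamber reading ladder (kBq, summed chain activity)
LADDER_IC_KBQ = (70.3, 144.3, 222.0, 299.7, 370.0, 447.7)
DEFAULT_DEAD_TIME_S = 4.6e-5
DEFAULT_LIVE_TIME_S = 30.0
DEFAULT_BACKGROUND_CPM = 150.0


@dataclass
class FixtureConfig:
    """Everything needed to generate one synthetic measured spectrum."""

    activities_kbq: dict[str, float]
    live_time_s: float = DEFAULT_LIVE_TIME_S
    dead_time_s: float = DEFAULT_DEAD_TIME_S
    background_cpm: float = DEFAULT_BACKGROUND_CPM
    background_shape: str = "flat"  # or "exponential"
    geb: GEBParams = field(default_factory=lambda: DEFAULT_GEB)
    n_histories: int = 200_000
    seed: int = 0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.activities_kbq.values()):
            raise ValueError("activities must be nonnegative")
        if min(self.live_time_s, self.n_histories) <= 0:
            raise ValueError("live time and histories must be positive")
        if self.dead_time_s < 0 or self.background_cpm < 0:
            raise ValueError("dead time and background must be nonnegative")


def background_counts(
    edges_kev: np.ndarray,
    cpm: float,
    live_time_s: float,
    shape: str = "flat",
) -> np.ndarray:
    """Expected background counts per bin for the given total rate."""
    n_bins = len(edges_kev) - 1
    total = cpm / 60.0 * live_time_s
    if shape == "flat":
        weights = np.ones(n_bins)
    elif shape == "exponential":
        centers = 0.5 * (edges_kev[:-1] + edges_kev[1:])
        weights = np.exp(-centers / 200.0)
    else:
        raise ValueError(f"unknown background shape {shape!r}")
    return total * weights / weights.sum()


def make_measured_spectrum(
    cfg: FixtureConfig,
    *,
    transport_config: TransportConfig | None = None,
) -> PulseHeightSpectrum:
    """Forward-model a synthetic measured spectrum.

    ideal MC -> deterministic GEB -> dead-time thinning (total-rate
    driven) -> per-bin Poisson sampling -> + Poisson background.
    With ``poisson_noise=False`` the expected (noise-free) spectrum is
    returned, still including broadening, dead time and background.
    """
    rng = np.random.default_rng(cfg.seed)
    ideal = simulate_spectrum(
        cfg.activities_kbq,
        cfg.live_time_s,
        cfg.n_histories,
        config=transport_config,
        seed=rng,
    )
    broadened = apply_geb(ideal, cfg.geb)
    true_rate = broadened.total_rate
    thinned = dead_time_apply(broadened, DeadTime(cfg.dead_time_s))
    bkg = background_counts(
        thinned.edges_kev, cfg.background_cpm, cfg.live_time_s, cfg.background_shape
    )
    expected = thinned.counts + bkg
    counts = rng.poisson(expected).astype(float) if cfg.poisson_noise else expected
    return PulseHeightSpectrum(
        thinned.edges_kev,
        counts,
        cfg.live_time_s,
        "measured",
        cfg.n_histories,
        meta={
            "truth": {
                "activities_kbq": dict(cfg.activities_kbq),
                "dead_time_s": cfg.dead_time_s,
                "background_cpm": cfg.background_cpm,
                "true_count_rate": true_rate,
                "seed": cfg.seed,
            }
        },
    )


def make_fwhm_dataset(
    params: GEBParams = DEFAULT_GEB,
    energies_kev: tuple[float, ...] = CALIBRATION_ENERGIES_KEV,
    noise: float = 0.0,
    seed: int = 0,
) -> list[FWHMPoint]:
    """FWHM calibration points from the GEB law, optionally with relative noise."""
    rng = np.random.default_rng(seed)
    points = []
    for e in energies_kev:
        f = float(params.fwhm_kev(e))
        if noise > 0:
            f *= 1.0 + noise * rng.standard_normal()
        points.append(FWHMPoint(e, f))
    return points


def make_two_source_counts(
    tau_s: float,
    n1: float,
    n2: float,
    b: float = 0.0,
    *,
    counting_time_s: float | None = None,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Observed two-source rates from true rates through m = n/(1 + n*tau).

    Losses act on the total incident rate (source plus background).
    With ``counting_time_s`` set, Poisson counting noise at that
    duration is added; otherwise the rates are exact.
    """
    rng = np.random.default_rng(seed)

    def observe(n_true: float) -> float:
        m = n_true / (1.0 + n_true * tau_s)
        if counting_time_s is not None:
            return rng.poisson(m * counting_time_s) / counting_time_s
        return m

    return (
        observe(n1 + b),
        observe(n2 + b),
        observe(n1 + n2 + b),
        observe(b) if b > 0 else 0.0,
    )


def ladder_configs(
    *,
    ic_readings_kbq: tuple[float, ...] = LADDER_IC_KBQ,
    dead_time_s: float = DEFAULT_DEAD_TIME_S,
    live_time_s: float = DEFAULT_LIVE_TIME_S,
    n_histories: int = 200_000,
    seed: int = 0,
) -> list[FixtureConfig]:
    """Fixture configs for the six-sample ladder (equal-activity equilibrium).

    Each ion-chamber reading is the summed activity of the three gamma
    emitters, so the per-nuclide activity is one third of the reading.
    """
    return [
        FixtureConfig(
            activities_kbq={
                "Ac-225": ic / 3.0, "Fr-221": ic / 3.0, "Bi-213": ic / 3.0
            },
            live_time_s=live_time_s,
            dead_time_s=dead_time_s,
            n_histories=n_histories,
            seed=seed + 17 * k,
        )
        for k, ic in enumerate(ic_readings_kbq)
    ]
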