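"""Pulse-height spectrum container and its on-disk format.

A spectrum is a binned energy-deposition histogram: contiguous
half-open bins [lo, hi) in keV, real-valued counts, a live time, and a
``kind`` tag (``ideal`` straight from transport, ``broadened`` after
Gaussian energy broadening, ``measured`` for real or synthetic detector
output).  The default analyzer binning is 64 bins x 12.5 keV over
0-800 keV.

On disk a spectrum is a CSV (bin_lo_keV, bin_hi_keV, counts, rel_err)
plus a JSON sidecar ``<stem>.meta.json`` holding live time, kind,
history count, seed and free-form provenance.  ``read_spectrum`` of a
written spectrum is exact for counts and metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_N_BINS = 64
DEFAULT_BIN_WIDTH_KEV = 12.5


def default_edges(
    n_bins: int = DEFAULT_N_BINS, width_kev: float = DEFAULT_BIN_WIDTH_KEV
) -> np.ndarray:
    return np.arange(n_bins + 1, dtype=float) * width_kev


@dataclass
class PulseHeightSpectrum:
    edges_kev: np.ndarray
    counts: np.ndarray
    live_time_s: float = 1.0
    kind: str = "ideal"
    n_histories: int = 0
    rel_err: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges_kev = np.asarray(self.edges_kev, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.edges_kev.ndim != 1 or len(self.edges_kev) < 2:
            raise ValueError("edges must be a 1-D array of at least 2 values")
        if np.any(np.diff(self.edges_kev) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges_kev) - 1:
            raise ValueError("counts length must equal number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.kind not in ("ideal", "broadened", "measured"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.rel_err is not None:
            self.rel_err = np.asarray(self.rel_err, dtype=float)
            if len(self.rel_err) != len(self.counts):
                raise ValueError("rel_err length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centers_kev(self) -> np.ndarray:
        return 0.5 * (self.edges_kev[:-1] + self.edges_kev[1:])

    @property
    def widths_kev(self) -> np.ndarray:
        return np.diff(self.edges_kev)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def total_rate(self) -> float:
        """Total count rate in 1/s over the live time."""
        return self.total_counts / self.live_time_s

    def same_binning(self, other: "PulseHeightSpectrum", atol: float = 1e-9) -> bool:
        return len(self.edges_kev) == len(other.edges_kev) and np.allclose(
            self.edges_kev, other.edges_kev, atol=atol
        )

    def with_counts(self, counts: np.ndarray, **changes) -> "PulseHeightSpectrum":
        return replace(self, counts=np.asarray(counts, dtype=float), **changes)

    def scaled(self, factor: float) -> "PulseHeightSpectrum":
        return self.with_counts(self.counts * factor)


def rebin(spectrum: PulseHeightSpectrum, edges_kev: np.ndarray) -> PulseHeightSpectrum:
    """Rebin onto coarser edges by proportional mass assignment."""
    edges_kev = np.asarray(edges_kev, dtype=float)
    src_lo, src_hi = spectrum.edges_kev[:-1], spectrum.edges_kev[1:]
    out = np.zeros(len(edges_kev) - 1)
    for k, (lo, hi) in enumerate(zip(edges_kev[:-1], edges_kev[1:])):
        overlap = np.clip(np.minimum(src_hi, hi) - np.maximum(src_lo, lo), 0.0, None)
        out[k] = np.sum(spectrum.counts * overlap / (src_hi - src_lo))
    return replace(spectrum, edges_kev=edges_kev, counts=out, rel_err=None)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_spectrum(spectrum: PulseHeightSpectrum, path: str | Path) -> None:
    path = Path(path)
    rel = (
        spectrum.rel_err
        if spectrum.rel_err is not None
        else np.zeros_like(spectrum.counts)
    )
    with open(path, "w") as fh:
        fh.write("bin_lo_keV,bin_hi_keV,counts,rel_err\n")
        for lo, hi, cnt, re_ in zip(
            spectrum.edges_kev[:-1], spectrum.edges_kev[1:], spectrum.counts, rel
        ):
            fh.write(f"{lo:.6g},{hi:.6g},{float(cnt)!r},{float(re_):.6g}\n")
    meta = {
        "live_time_s": spectrum.live_time_s,
        "kind": spectrum.kind,
        "n_histories": spectrum.n_histories,
        **spectrum.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_spectrum(path: str | Path) -> PulseHeightSpectrum:
    path = Path(path)
    lo, hi, counts, rel = [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bin_lo_keV"):
            raise ValueError(f"{path}:1: missing spectrum CSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from None
            lo.append(vals[0]); hi.append(vals[1])
            counts.append(vals[2]); rel.append(vals[3])
    for i in range(1, len(lo)):
        if abs(lo[i] - hi[i - 1]) > 1e-9:
            raise ValueError(
                f"{path}:{i + 2}: non-contiguous bins ({hi[i - 1]} -> {lo[i]})"
            )
        if hi[i] <= lo[i]:
            raise ValueError(f"{path}:{i + 2}: empty or inverted bin")
    edges = np.array(lo + [hi[-1]], dtype=float)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        live = meta.pop("live_time_s", 1.0)
        kind = meta.pop("kind", "measured")
        n_hist = meta.pop("n_histories", 0)
    else:
        warnings.warn(
            f"no metadata sidecar next to {path}; assuming kind='measured', "
            "live_time=1 s",
            stacklevel=2,
        )
        meta, live, kind, n_hist = {}, 1.0, "measured", 0
    return PulseHeightSpectrum(
        edges_kev=edges,
        counts=np.array(counts),
        live_time_s=live,
        kind=kind,
        n_histories=n_hist,
        rel_err=np.array(rel),
        meta=meta,
    )
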