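"""Nuclide data for the Ac-225 decay chain.

The chain Ac-225 -> Fr-221 -> At-217 -> Bi-213 -> (Po-213 | Tl-209) ->
Pb-209 -> Bi-209 is shipped as a plain-text table
(``data/ac225_chain.tsv``).  Three members emit the gamma lines used for
quantification: Ac-225 (composite peak 99.8 keV, Y = 1.0 %), Fr-221
(218.1 keV, 11.4 %) and Bi-213 (440.5 keV, 25.9 %), where Y is the gamma
abundance per alpha decay used to convert net peak counts to activity.
The remaining members carry no modeled photon lines and exist only so the
decay kinetics are complete.

Any table with the same layout can be substituted via
:func:`load_chain`, e.g. to use a full evaluated-data line list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

LN2 = math.log(2.0)

_UNIT_SECONDS = {
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "d": 86400.0,
    "yr": 365.25 * 86400.0,
    "ms": 1e-3,
    "us": 1e-6,
}

#: Members whose photon emissions are modeled.
GAMMA_EMITTERS = ("Ac-225", "Fr-221", "Bi-213")


@dataclass(frozen=True)
class PhotonLine:
    """A discrete photon emission: energy in keV, intensity in photons/decay."""

    energy_kev: float
    intensity: float

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError(f"line energy must be positive, got {self.energy_kev}")
        if not 0 < self.intensity <= 1:
            raise ValueError(f"line intensity must be in (0, 1], got {self.intensity}")


@dataclass(frozen=True)
class NuclideSpec:
    name: str
    half_life_s: float  # math.inf marks the stable sink
    lines: tuple[PhotonLine, ...] = ()
    principal_peak_kev: float | None = None
    abundance_factor: float | None = None  # Y, photons per alpha decay at the peak
    #: children as (name, branching fraction); empty for the sink
    decays_to: tuple[tuple[str, float], ...] = ()

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / T_half in 1/s (0 for a stable nuclide)."""
        if math.isinf(self.half_life_s):
            return 0.0
        return LN2 / self.half_life_s

    @property
    def is_stable(self) -> bool:
        return math.isinf(self.half_life_s)


@dataclass
class DecayChain:
    """Ordered (parent-before-child) decay network with branching."""

    nuclides: tuple[NuclideSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nuclides]
        if len(set(names)) != len(names):
            raise ValueError("duplicate nuclide names in chain")
        seen: set[str] = set()
        for nuc in self.nuclides:
            if nuc.decays_to:
                total = sum(f for _, f in nuc.decays_to)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{nuc.name}: branching fractions sum to {total}, not 1"
                    )
                for child, _ in nuc.decays_to:
                    if child in seen or child == nuc.name:
                        raise ValueError(f"{nuc.name} -> {child} breaks topological order")
            seen.add(nuc.name)
        # a chain must terminate
        if self.nuclides and not any(
            n.is_stable or not n.decays_to for n in self.nuclides
        ):
            raise ValueError("chain has no stable/terminal sink")

    def __iter__(self):
        return iter(self.nuclides)

    def __len__(self) -> int:
        return len(self.nuclides)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nuclides)

    def __getitem__(self, name: str) -> NuclideSpec:
        for nuc in self.nuclides:
            if nuc.name == name:
                return nuc
        raise KeyError(f"unknown nuclide {name!r}; chain has {self.names}")

    @property
    def parent(self) -> NuclideSpec:
        return self.nuclides[0]

    def gamma_emitters(self) -> tuple[NuclideSpec, ...]:
        return tuple(n for n in self.nuclides if n.lines)


def _parse_half_life(value: str, unit: str) -> float:
    if value == "stable":
        return math.inf
    try:
        scale = _UNIT_SECONDS[unit]
    except KeyError:
        raise ValueError(f"unknown half-life unit {unit!r}") from None
    return float(value) * scale


def load_chain(path: str | Path) -> DecayChain:
    """Read a decay chain from a tab-separated nuclide table."""
    nuclides = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        name, hl, unit, decays, gammas, peak, yfac = parts
        decays_to: tuple[tuple[str, float], ...] = ()
        if decays != "-":
            decays_to = tuple(
                (tok.split(":")[0], float(tok.split(":")[1]))
                for tok in decays.split(",")
            )
        lines: tuple[PhotonLine, ...] = ()
        if gammas != "-":
            lines = tuple(
                PhotonLine(float(tok.split(":")[0]), float(tok.split(":")[1]))
                for tok in gammas.split(";")
            )
        nuclides.append(
            NuclideSpec(
                name=name,
                half_life_s=_parse_half_life(hl, unit),
                lines=lines,
                principal_peak_kev=None if peak == "-" else float(peak),
                abundance_factor=None if yfac == "-" else float(yfac),
                decays_to=decays_to,
            )
        )
    return DecayChain(tuple(nuclides))


def builtin_ac225_chain() -> DecayChain:
    """The bundled Ac-225 chain (rounded working half-lives: 10 d, 4.9 min, 46 min)."""
    ref = resources.files("actispec.data").joinpath("ac225_chain.tsv")
    with resources.as_file(ref) as path:
        return load_chain(path)


def photon_lines(nuclide: str, chain: DecayChain | None = None) -> tuple[PhotonLine, ...]:
    """Photon emission lines of a gamma-emitting chain member.

    Raises ``KeyError`` for an unknown nuclide and ``ValueError`` for a
    member with no modeled photon emissions.
    """
    chain = chain if chain is not None else builtin_ac225_chain()
    spec = chain[nuclide]
    if not spec.lines:
        raise ValueError(f"{nuclide} has no modeled photon lines")
    return spec.lines
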