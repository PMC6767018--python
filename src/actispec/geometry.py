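"""Detector geometry for photon transport.

The well counter is modeled as nested axially symmetric regions.  A
declared list of cylindrical cells (r_in, r_out, z_lo, z_hi, material)
is compiled onto an (r, z) grid partition of a bounding cylinder: every
grid box carries one material, gaps default to air, and the NaI boxes
are flagged as the scoring (energy-deposition) region.  Grid boxes make
both point location and surface-distance queries trivial to vectorize.

The default layout follows the published description of the instrument
— a 2" x 2" NaI(Tl) crystal with an axial well, MgO reflector,
aluminum housing, 1.2 cm lead side shield, a 30 mm aluminum cylinder
standing in for the photomultiplier, and a 5 mL polyethylene tube
holding 1 mL of water (the source volume) in the well.  Well bore and
liner dimensions are not published; the defaults (16 mm bore, 38 mm
depth) are config parameters, not constants the analysis depends on.

A homogeneous sphere geometry is provided for validation against the
closed-form attenuation law 1 - exp(-mu R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-9


@dataclass(frozen=True)
class Cell:
    r_in: float
    r_out: float
    z_lo: float
    z_hi: float
    material: str


class CylinderGridGeometry:
    """(r, z) grid partition of a bounding cylinder."""

    def __init__(
        self,
        cells: list[Cell],
        *,
        ambient: str = "air",
        scoring_material: str = "NaI",
        source_cylinder: tuple[float, float, float] | None = None,
    ) -> None:
        r_break = {0.0}
        z_break = set()
        for c in cells:
            if not (0 <= c.r_in < c.r_out and c.z_lo < c.z_hi):
                raise ValueError(f"degenerate cell {c}")
            r_break.update((c.r_in, c.r_out))
            z_break.update((c.z_lo, c.z_hi))
        self.r_edges = np.array(sorted(r_break))
        self.z_edges = np.array(sorted(z_break))
        nr, nz = len(self.r_edges) - 1, len(self.z_edges) - 1
        mat_names = sorted({c.material for c in cells} | {ambient})
        self.material_names = mat_names
        self._mat_index = {m: i for i, m in enumerate(mat_names)}
        self.material_map = np.full((nr, nz), self._mat_index[ambient], dtype=np.int32)
        rc = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        zc = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        for c in cells:
            ri = np.nonzero((rc > c.r_in) & (rc < c.r_out))[0]
            zi = np.nonzero((zc > c.z_lo) & (zc < c.z_hi))[0]
            for i in ri:
                for j in zi:
                    if self.material_map[i, j] != self._mat_index[ambient]:
                        raise ValueError(f"overlapping cells at box ({i}, {j})")
                    self.material_map[i, j] = self._mat_index[c.material]
        self.scoring_mask = self.material_map == self._mat_index.get(
            scoring_material, -1
        )
        self.source_cylinder = source_cylinder  # (radius, z_lo, z_hi)
        if source_cylinder is not None:
            r, z0, z1 = source_cylinder
            if not (
                r <= self.r_edges[-1] and self.z_edges[0] <= z0 < z1 <= self.z_edges[-1]
            ):
                raise ValueError("source volume must lie inside the geometry")

    # -- queries (all vectorized over photons) ---------------------------

    def locate(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices (i_r, j_z) of each position; -1 marks outside."""
        rho = np.hypot(pos[:, 0], pos[:, 1])
        i = np.searchsorted(self.r_edges, rho, side="right") - 1
        j = np.searchsorted(self.z_edges, pos[:, 2], side="right") - 1
        i = np.where((rho >= self.r_edges[-1]) | (i < 0), -1, i)
        j = np.where(
            (pos[:, 2] < self.z_edges[0]) | (pos[:, 2] >= self.z_edges[-1]), -1, j
        )
        outside = (i < 0) | (j < 0)
        return np.where(outside, -1, i), np.where(outside, -1, j)

    def material_at(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Material index per photon (-1 outside)."""
        out = np.full(len(i), -1, dtype=np.int32)
        ok = (i >= 0) & (j >= 0)
        out[ok] = self.material_map[i[ok], j[ok]]
        return out

    def is_scoring(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        ok = (i >= 0) & (j >= 0)
        out = np.zeros(len(i), dtype=bool)
        out[ok] = self.scoring_mask[i[ok], j[ok]]
        return out

    def distance_to_exit(
        self, pos: np.ndarray, direction: np.ndarray, i: np.ndarray, j: np.ndarray
    ) -> np.ndarray:
        """Distance to leave the current grid box along ``direction``."""
        x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
        dx, dy, dz = direction[:, 0], direction[:, 1], direction[:, 2]
        big = np.inf
        # axial planes
        t_z = np.where(
            dz > _EPS,
            (self.z_edges[np.minimum(j + 1, len(self.z_edges) - 1)] - z) / dz,
            np.where(dz < -_EPS, (self.z_edges[np.maximum(j, 0)] - z) / dz, big),
        )
        # radial surfaces
        a = dx * dx + dy * dy
        b = x * dx + y * dy  # half-b
        rho2 = x * x + y * y
        r_out = self.r_edges[np.minimum(i + 1, len(self.r_edges) - 1)]
        r_in = self.r_edges[np.maximum(i, 0)]
        with np.errstate(invalid="ignore", divide="ignore"):
            disc_out = b * b - a * (rho2 - r_out**2)
            t_out = np.where(
                a > _EPS, (-b + np.sqrt(np.maximum(disc_out, 0.0))) / a, big
            )
            disc_in = b * b - a * (rho2 - r_in**2)
            t_in_valid = (r_in > 0) & (a > _EPS) & (b < 0) & (disc_in > 0)
            t_in = np.where(
                t_in_valid, (-b - np.sqrt(np.maximum(disc_in, 0.0))) / a, big
            )
            t_in = np.where(t_in > _EPS, t_in, big)
        t = np.minimum(np.minimum(np.maximum(t_z, 0.0), t_out), t_in)
        return np.maximum(t, 0.0)


class HomogeneousSphereGeometry:
    """A single material sphere centered at the origin; vacuum outside."""

    def __init__(self, radius: float, material: str, *, scoring: bool = True) -> None:
        self.radius = radius
        self.material_names = [material]
        self._scoring = scoring
        self.source_cylinder = None

    def locate(self, pos: np.ndarray):
        inside = np.einsum("ij,ij->i", pos, pos) < self.radius**2
        idx = np.where(inside, 0, -1).astype(np.int32)
        return idx, idx

    def material_at(self, i, j):
        return i

    def is_scoring(self, i, j):
        return (i >= 0) & self._scoring

    def distance_to_exit(self, pos, direction, i, j):
        b = np.einsum("ij,ij->i", pos, direction)
        c = np.einsum("ij,ij->i", pos, pos) - self.radius**2
        disc = np.maximum(b * b - c, 0.0)
        return np.maximum(-b + np.sqrt(disc), 0.0)


def well_detector_geometry(
    *,
    crystal_radius: float = 2.54,
    crystal_height: float = 5.08,
    well_radius: float = 0.80,
    well_depth: float = 3.80,
    reflector_thickness: float = 0.16,
    housing_thickness: float = 0.10,
    shield_thickness: float = 1.20,
    tube_outer_radius: float = 0.56,
    tube_wall: float = 0.06,
    water_height: float = 1.27,
    pmt_radius: float = 1.50,
    pmt_length: float = 3.00,
) -> CylinderGridGeometry:
    """Default well-counter geometry (dimensions in cm).

    The water column height default (1.27 cm at 0.50 cm radius) holds
    1.0 mL.  All dimensions are overridable; only the crystal size,
    shield thickness, tube volumes and PMT diameter are published.
    """
    liner = reflector_thickness
    z_cr0, z_cr1 = 0.0, crystal_height
    z_well = crystal_height - well_depth  # bottom of the well cavity
    r_cav = well_radius - liner / 2  # air cavity inside the well liner
    top = crystal_height + liner + housing_thickness
    cells = [
        # NaI crystal (scoring): solid disc below the well + annulus around it
        Cell(0.0, crystal_radius, z_cr0, z_well, "NaI"),
        Cell(well_radius, crystal_radius, z_well, z_cr1, "NaI"),
        # MgO reflector: outer side, bottom, top annulus, well sleeve and pad
        Cell(crystal_radius, crystal_radius + liner, z_cr0, z_cr1, "MgO"),
        Cell(0.0, crystal_radius + liner, -liner, z_cr0, "MgO"),
        Cell(well_radius, crystal_radius + liner, z_cr1, z_cr1 + liner, "MgO"),
        Cell(r_cav, well_radius, z_well, z_cr1 + liner, "MgO"),
        Cell(0.0, r_cav, z_well, z_well + liner / 2, "MgO"),
        # Al housing: side wall, bottom plate, top annulus
        Cell(
            crystal_radius + liner,
            crystal_radius + liner + housing_thickness,
            -liner - housing_thickness,
            top,
            "Al",
        ),
        Cell(0.0, crystal_radius + liner, -liner - housing_thickness, -liner, "Al"),
        Cell(r_cav, crystal_radius + liner, z_cr1 + liner, top, "Al"),
        # Pb side shield
        Cell(
            crystal_radius + liner + housing_thickness,
            crystal_radius + liner + housing_thickness + shield_thickness,
            -liner - housing_thickness,
            top,
            "Pb",
        ),
        # PMT stand-in below the housing
        Cell(0.0, pmt_radius, -liner - housing_thickness - pmt_length,
             -liner - housing_thickness, "Al"),
    ]
    # polyethylene tube + water source resting on the well bottom pad
    z_tb0 = z_well + liner / 2
    z_tb1 = z_tb0 + tube_wall
    z_w1 = z_tb1 + water_height
    z_top = top + 0.5  # tube sticks out of the well opening
    r_wat = tube_outer_radius - tube_wall
    cells += [
        Cell(0.0, tube_outer_radius, z_tb0, z_tb1, "polyethylene"),
        Cell(r_wat, tube_outer_radius, z_tb1, z_top, "polyethylene"),
        Cell(0.0, r_wat, z_tb1, z_w1, "water"),
    ]
    return CylinderGridGeometry(
        cells,
        source_cylinder=(r_wat, z_tb1, z_w1),
    )
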