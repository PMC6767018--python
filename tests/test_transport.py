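import numpy as np
import pytest

from actispec.geometry import Cell, CylinderGridGeometry, HomogeneousSphereGeometry, \
    well_detector_geometry
from actispec.materials import BUILTIN_MATERIALS, CrossSectionTable
from actispec.montecarlo import (
    TransportConfig,
    _isotropic,
    find_compton_edge,
    hd_spectrum,
    sample_emission,
    simulate_spectrum,
    track_history,
    transport,
)
from actispec.nuclides import PhotonLine
from actispec.response import apply_geb
from actispec.fixtures import DEFAULT_GEB


class TestMaterials:
    def test_mass_fractions_normalized(self):
        for mat in BUILTIN_MATERIALS.values():
            assert sum(f for _, f in mat.composition) == pytest.approx(1.0, abs=1e-6)
            assert mat.density > 0

    def test_table_grid_and_positivity(self, xs_library):
        for name in BUILTIN_MATERIALS:
            table = xs_library.table(name)
            assert table.energy_kev[0] <= 10.0 + 1e-9
            assert table.energy_kev[-1] >= 800.0 - 1e-9
            assert np.all(table.photoelectric >= 0)
            assert np.all(table.incoherent >= 0)
            assert np.all(table.coherent >= 0)
            assert np.allclose(
                table.total, table.photoelectric + table.incoherent + table.coherent
            )

    def test_attenuation_decreases_with_energy(self, xs_library):
        nai = xs_library.table("NaI")
        mus = nai.mu_total(np.array([122.0, 364.0, 661.6]))
        assert np.all(np.diff(mus) < 0)

    def test_iodine_k_edge_discontinuity(self, xs_library):
        nai = xs_library.table("NaI")
        below, above = nai.mu_total(np.array([33.0, 33.4]))
        assert above > 2 * below


class TestEmissionSampling:
    def test_single_line_degenerate(self, rng):
        e, pos, d = sample_emission(
            [PhotonLine(218.1, 0.114)], 1000, rng, (0.5, 1.0, 2.0)
        )
        assert np.all(e == 218.1)

    def test_intensity_ratio(self, rng):
        lines = [PhotonLine(100.0, 0.2), PhotonLine(200.0, 0.1)]
        e, _, _ = sample_emission(lines, 100_000, rng, (0.5, 1.0, 2.0))
        p_hat = np.mean(e == 100.0)
        sigma = np.sqrt(2 / 3 * 1 / 3 / 100_000)
        assert abs(p_hat - 2 / 3) < 3 * sigma

    def test_position_centroid_and_containment(self, rng):
        radius, z0, z1 = 0.5, 1.0, 2.27
        _, pos, _ = sample_emission(
            [PhotonLine(100.0, 1.0)], 100_000, rng, (radius, z0, z1)
        )
        rho = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(rho <= radius) and np.all((pos[:, 2] >= z0) & (pos[:, 2] <= z1))
        z_sigma = (z1 - z0) / np.sqrt(12 * 100_000)
        assert abs(pos[:, 2].mean() - 0.5 * (z0 + z1)) < 3 * z_sigma
        assert abs(pos[:, 0].mean()) < 3 * radius / np.sqrt(8 * 100_000) * 2

    def test_isotropy(self, rng):
        d = _isotropic(100_000, rng)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert abs(d[:, 2].mean()) < 3 / np.sqrt(3 * 100_000)

    def test_empty_lines_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_emission([], 10, rng, (0.5, 1.0, 2.0))


class TestTransportPhysics:
    @pytest.mark.parametrize("energy", [60.0, 218.1, 661.6])
    def test_sphere_attenuation_oracle(self, energy, xs_library):
        """Interacting fraction of a centered source matches 1 - exp(-mu R)."""
        radius = 1.0
        geom = HomogeneousSphereGeometry(radius, "water")
        config = TransportConfig(geometry=geom, library=xs_library, rayleigh=False)
        rng = np.random.default_rng(7)
        n = 100_000
        deposits = transport(
            np.full(n, energy), np.zeros((n, 3)), _isotropic(n, rng), config, rng
        )
        table = xs_library.table("water")
        pe, inc, _ = table.interp(energy)
        p = 1.0 - np.exp(-float(pe + inc) * radius)
        assert abs(np.mean(deposits > 0) - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_deposit_never_exceeds_emitted_energy(self, transport_config):
        rng = np.random.default_rng(3)
        geom = transport_config.geometry
        e, pos, d = sample_emission(
            [PhotonLine(661.6, 0.851)], 20_000, rng, geom.source_cylinder
        )
        deposits = transport(e, pos, d, transport_config, rng)
        assert np.all(deposits <= 661.6 + 1e-9)
        # full-absorption events deposit exactly the emitted energy
        assert np.any(np.isclose(deposits, 661.6))

    def test_track_history_scalar(self, transport_config, rng):
        dep = track_history(
            122.0, np.array([0.0, 0.0, 2.0]), np.array([0.0, 0.0, -1.0]),
            transport_config, rng,
        )
        assert 0.0 <= dep <= 122.0

    def test_compton_edge_position(self, transport_config):
        """661.6 keV Compton edge at E(1 - 1/(1 + 2E/511)) = 477.3 keV."""
        hd = hd_spectrum(
            [PhotonLine(661.6, 0.851)], 1_000_000, config=transport_config, seed=3
        )
        edge = find_compton_edge(hd, (430.0, 520.0))
        assert abs(edge - 477.3) <= 1.0

    def test_photopeak_efficiency_decreases_with_energy(self, transport_config):
        fracs = []
        for energy in (122.0, 364.5, 661.6):
            rng = np.random.default_rng(11)
            geom = transport_config.geometry
            e, pos, d = sample_emission(
                [PhotonLine(energy, 1.0)], 60_000, rng, geom.source_cylinder
            )
            deposits = transport(e, pos, d, transport_config, rng)
            fracs.append(np.mean(deposits >= energy - 1.0))
        assert fracs[0] > fracs[1] > fracs[2]


class TestSimulateSpectrum:
    def test_zero_activity_zero_spectrum(self, transport_config):
        spec = simulate_spectrum(
            {"Ac-225": 0.0}, 30.0, 1000, config=transport_config, seed=1
        )
        assert spec.total_counts == 0

    def test_seeded_reproducibility(self, transport_config):
        kw = dict(live_time_s=30.0, n_histories=20_000, config=transport_config)
        a = simulate_spectrum({"Fr-221": 50.0}, kw["live_time_s"], kw["n_histories"],
                              config=transport_config, seed=99)
        b = simulate_spectrum({"Fr-221": 50.0}, kw["live_time_s"], kw["n_histories"],
                              config=transport_config, seed=99)
        assert np.array_equal(a.counts, b.counts)

    def test_live_time_linearity(self, transport_config):
        a = simulate_spectrum({"Fr-221": 50.0}, 30.0, 20_000,
                              config=transport_config, seed=5)
        b = simulate_spectrum({"Fr-221": 50.0}, 60.0, 20_000,
                              config=transport_config, seed=5)
        assert np.allclose(2 * a.counts, b.counts)

    def test_default_binning_and_energy_ceiling(self, transport_config, chain):
        spec = simulate_spectrum(
            {"Bi-213": 100.0}, 30.0, 50_000, config=transport_config, seed=2
        )
        assert spec.n_bins == 64
        e_max = max(ln.energy_kev for ln in chain["Bi-213"].lines)
        above = spec.counts[spec.edges_kev[:-1] >= e_max]
        assert np.all(above == 0)

    def test_broadened_composite_peaks(self, transport_config):
        """Equal-activity source shows peaks near 99.8, 218.1 and 440.5 keV."""
        ideal = simulate_spectrum(
            {"Ac-225": 23.4, "Fr-221": 23.4, "Bi-213": 23.4},
            30.0, 300_000, config=transport_config, seed=8,
        )
        spec = apply_geb(ideal, DEFAULT_GEB)
        c = spec.counts
        maxima = [
            spec.centers_kev[i]
            for i in range(1, spec.n_bins - 1)
            if c[i] >= c[i - 1] and c[i] >= c[i + 1] and c[i] > 0.02 * c.max()
        ]
        for peak in (99.8, 218.1, 440.5):
            assert any(abs(m - peak) <= 12.5 for m in maxima), (peak, maxima)

    def test_statistical_error_reporting(self, transport_config):
        spec = simulate_spectrum(
            {"Fr-221": 50.0}, 30.0, 50_000, config=transport_config, seed=4
        )
        assert spec.rel_err is not None
        filled = spec.counts > 0
        assert np.all(spec.rel_err[filled] > 0)


class TestHDSpectrum:
    def test_binning_is_1_kev(self, transport_config):
        hd = hd_spectrum("Fr-221", 10_000, config=transport_config, seed=1)
        assert hd.n_bins == 800
        assert np.allclose(np.diff(hd.edges_kev), 1.0)

    def test_actinium_low_energy_content(self, transport_config):
        hd = hd_spectrum("Ac-225", 100_000, config=transport_config, seed=2)
        sel = (hd.centers_kev >= 90) & (hd.centers_kev <= 200)
        assert hd.counts[sel].sum() > 0

    def test_no_content_above_line_ceiling(self, transport_config, chain):
        hd = hd_spectrum("Fr-221", 50_000, config=transport_config, seed=3)
        e_max = max(ln.energy_kev for ln in chain["Fr-221"].lines)
        assert hd.counts[hd.edges_kev[:-1] >= e_max].sum() == 0


class TestGeometry:
    def test_overlapping_cells_rejected(self):
        cells = [
            Cell(0.0, 1.0, 0.0, 1.0, "NaI"),
            Cell(0.0, 0.5, 0.0, 1.0, "Al"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            CylinderGridGeometry(cells)

    def test_source_inside_well(self):
        geom = well_detector_geometry()
        radius, z0, z1 = geom.source_cylinder
        pts = np.array([[0.0, 0.0, 0.5 * (z0 + z1)], [radius * 0.9, 0.0, z0 + 0.01]])
        i, j = geom.locate(pts)
        mats = geom.material_at(i, j)
        water = geom.material_names.index("water")
        assert np.all(mats == water)
        assert not geom.is_scoring(i, j).any()

    def test_crystal_is_scoring(self):
        geom = well_detector_geometry()
        pts = np.array([[0.0, 0.0, 0.5], [2.0, 0.0, 2.5]])
        i, j = geom.locate(pts)
        assert geom.is_scoring(i, j).all()

    def test_source_volume_is_one_ml(self):
        geom = well_detector_geometry()
        radius, z0, z1 = geom.source_cylinder
        assert np.pi * radius**2 * (z1 - z0) == pytest.approx(1.0, rel=0.01)
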