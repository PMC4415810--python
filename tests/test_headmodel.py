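"""Forward model: montage geometry, grid, multilayer-sphere potentials."""

import numpy as np
import pytest

from bsnet import headmodel as hm


def hom_sphere_potential(sigma, elec_mm, loc_mm, mom_nAm, r_mm):
    """Closed-form dipole potential in a homogeneous sphere (uV, avg-ref).

    Independent oracle: the Legendre series of the single-sphere solution
    summed in closed form with generating functions.
    """
    R = r_mm * 1e-3
    e_hat = elec_mm / np.linalg.norm(elec_mm, axis=1, keepdims=True)
    a_vec = np.asarray(loc_mm, float) * 1e-3
    q = np.asarray(mom_nAm, float) * 1e-9
    a = np.linalg.norm(a_vec)
    a_hat = a_vec / a if a > 0 else np.array([0.0, 0.0, 1.0])
    t = a / R
    u = e_hat @ a_hat
    d = np.sqrt(1 - 2 * t * u + t * t)
    q_r = q @ a_hat
    w = e_hat @ q - q_r * u
    rad = q_r * (2 * (u - t) / d**3 + ((1 / d - 1) / t if t > 0 else 3 * u))
    tan = w * (2 / d**3 + (1 + d) / (d * (1 - t * u + d)))
    v = (rad + tan) / (4 * np.pi * sigma * R**2) * 1e6
    return v - v.mean()


class TestMontage:
    def test_vertex_and_scalp_radius(self, montage19, model):
        cz = montage19.positions[montage19.labels.index("Cz")]
        assert np.allclose(cz, [0, 0, model.scalp_radius])
        radii = np.linalg.norm(montage19.positions, axis=1)
        assert np.allclose(radii, model.scalp_radius, rtol=1e-9)

    def test_left_right_mirror_symmetry(self, montage19):
        pos = {lab: p for lab, p in zip(montage19.labels, montage19.positions)}
        pairs = [("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("T7", "T8"),
                 ("C3", "C4"), ("P7", "P8"), ("P3", "P4"), ("O1", "O2")]
        for left, right in pairs:
            mirrored = pos[right] * np.array([-1, 1, 1])
            assert np.allclose(pos[left], mirrored, atol=1e-9)

    def test_21_channel_set_adds_midline_electrodes(self):
        m = hm.standard_montage_1020(21)
        assert "Fpz" in m.labels and "Oz" in m.labels
        assert m.n_channels == 21

    def test_against_geometric_coordinate_table(self, montage19, model):
        """Spot-check angles against the published 10-20 construction.

        Independent trig: midline/coronal electrodes at 10/20% arc steps,
        ring electrodes at 72 deg inclination and 18/54 deg ring azimuth.
        """
        r = model.scalp_radius
        s72, c72 = np.sin(np.deg2rad(72)), np.cos(np.deg2rad(72))
        expected = {
            "Fz": r * np.array([0, np.sin(np.deg2rad(36)), np.cos(np.deg2rad(36))]),
            "Pz": r * np.array([0, -np.sin(np.deg2rad(36)), np.cos(np.deg2rad(36))]),
            "T7": r * np.array([-s72, 0, c72]),
            "Fp1": r * np.array([-s72 * np.sin(np.deg2rad(18)),
                                 s72 * np.cos(np.deg2rad(18)), c72]),
            "F7": r * np.array([-s72 * np.sin(np.deg2rad(54)),
                                s72 * np.cos(np.deg2rad(54)), c72]),
            "O2": r * np.array([s72 * np.sin(np.deg2rad(162)),
                                s72 * np.cos(np.deg2rad(162)), c72]),
        }
        pos = {lab: p for lab, p in zip(montage19.labels, montage19.positions)}
        for lab, exp in expected.items():
            assert np.allclose(pos[lab], exp, atol=1e-9), lab

    def test_unsupported_count_raises(self):
        with pytest.raises(ValueError, match="channel count"):
            hm.standard_montage_1020(32)


class TestSphereModel:
    def test_defaults_have_five_shells(self, model):
        assert len(model.radii) == 5 and len(model.conductivities) == 5

    @pytest.mark.parametrize("radii,cond", [
        ((60, 58, 62, 65, 70), (0.33,) * 5),  # non-increasing radii
        ((58, 60, 62, 65, 70), (0.33, 0.0, 1.79, 0.04, 0.33)),  # zero sigma
        ((58, 60, 62, 65), (0.33,) * 4),  # wrong shell count
    ])
    def test_invalid_models_raise(self, radii, cond):
        with pytest.raises(ValueError):
            hm.build_sphere_model(radii, cond)


class TestSourceGrid:
    def test_matches_brute_force_enumeration(self, model):
        grid = hm.build_source_grid(model, 10.0)
        rmax = model.inner_radius - 5.0
        count = 0
        k = int(rmax // 10) + 1
        for x in range(-k, k + 1):
            for y in range(-k, k + 1):
                for z in range(-k, k + 1):
                    if np.sqrt(x * x + y * y + z * z) * 10 < rmax:
                        count += 1
        assert grid.n_points == count
        assert np.all(np.linalg.norm(grid.points, axis=1) < rmax)

    def test_axis_permutation_invariance(self, model):
        grid = hm.build_source_grid(model, 10.0)
        pts = {tuple(p) for p in grid.points}
        assert {(y, z, x) for x, y, z in pts} == pts

    def test_oversized_spacing_raises(self, model):
        with pytest.raises(ValueError):
            hm.build_source_grid(model, 200.0)


class TestDipolePotential:
    def test_zero_moment_gives_zero(self, model, montage19):
        v = hm.dipole_potential(model, montage19, [0, 0, 30], [0, 0, 0])
        assert np.allclose(v, 0.0)

    def test_equal_conductivity_matches_homogeneous_closed_form(self, montage19):
        model = hm.build_sphere_model(conductivities=(0.33,) * 5)
        rng = np.random.default_rng(7)
        for _ in range(10):
            loc = rng.uniform(-1, 1, 3)
            loc = loc / np.linalg.norm(loc) * rng.uniform(0, 0.9) * model.inner_radius
            mom = rng.normal(size=3) * 40
            got = hm.dipole_potential(model, montage19, loc, mom)
            want = hom_sphere_potential(0.33, montage19.positions, loc, mom,
                                        model.scalp_radius)
            assert np.max(np.abs(got - want)) <= 1e-6 * np.max(np.abs(want))

    def test_tangential_dipole_antisymmetry(self, model, montage19):
        # x-oriented dipole on the z-axis: potential is odd in x
        v = hm.dipole_potential(model, montage19, [0, 0, 35], [50, 0, 0])
        pos = {lab: val for lab, val in zip(montage19.labels, v)}
        for left, right in [("C3", "C4"), ("F3", "F4"), ("P3", "P4"),
                            ("O1", "O2"), ("T7", "T8")]:
            assert abs(pos[left] + pos[right]) < 1e-9
        for mid in ("Cz", "Fz", "Pz"):
            assert abs(pos[mid]) < 1e-9

    def test_superposition(self, model, montage19):
        loc = [10, -20, 25]
        v1 = hm.dipole_potential(model, montage19, loc, [30, 0, 0])
        v2 = hm.dipole_potential(model, montage19, loc, [0, -20, 10])
        v12 = hm.dipole_potential(model, montage19, loc, [30, -20, 10])
        assert np.allclose(v1 + v2, v12, atol=1e-12 * np.max(np.abs(v12)) * 1e6)

    def test_lower_skull_conductivity_attenuates(self, montage19):
        mags = []
        for sk in (0.33, 0.08, 0.02):
            m = hm.build_sphere_model(conductivities=(0.33, 0.33, 1.79, sk, 0.33))
            v = hm.dipole_potential(m, montage19, [0, 0, 40], [0, 0, 50])
            mags.append(np.max(np.abs(v)))
        assert mags[0] > mags[1] > mags[2]

    def test_outside_brain_raises(self, model, montage19):
        with pytest.raises(ValueError, match="outside"):
            hm.dipole_potential(model, montage19, [0, 0, 60], [0, 0, 50])


class TestLeadField:
    def test_columns_average_referenced(self, leadfield):
        assert np.max(np.abs(leadfield.gain.sum(axis=0))) < 1e-9
        assert np.all(np.isfinite(leadfield.gain))

    def test_moment_linearity(self, model, montage19, leadfield):
        g = leadfield.grid.points[100]
        v1 = hm.dipole_potential(model, montage19, g, [25, 0, 0])
        v2 = hm.dipole_potential(model, montage19, g, [50, 0, 0])
        assert np.allclose(2 * v1, v2, rtol=1e-12)

    def test_adaptive_truncation_matches_full_series(self, model, montage19):
        loc, mom = [5, -30, 35], [20, 40, 10]
        adaptive = hm.dipole_potential(model, montage19, loc, mom)
        full = hm._potentials(model, montage19, np.asarray(loc), np.asarray(mom),
                              n_terms=200, rtol=0.0)[0]
        assert np.max(np.abs(adaptive - full)) <= 1e-6 * np.max(np.abs(full))

    def test_cache_round_trip(self, leadfield, tmp_path):
        hm.save_leadfield(leadfield, tmp_path / "lf")
        back = hm.load_leadfield(tmp_path / "lf", leadfield.montage,
                                 leadfield.grid, leadfield.model)
        assert np.array_equal(back.gain, leadfield.gain)
        other = hm.standard_montage_1020(21)
        with pytest.raises(ValueError, match="montage"):
            hm.load_leadfield(tmp_path / "lf", other, leadfield.grid, leadfield.model)


class TestAverageReference:
    def test_constant_becomes_zero(self):
        assert np.allclose(hm.apply_average_reference(np.full((4, 10), 5.0)), 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 50))
        once = hm.apply_average_reference(x)
        assert np.allclose(hm.apply_average_reference(once), once)
        assert np.max(np.abs(once.mean(axis=0))) < 1e-12

    def test_single_channel_raises(self):
        with pytest.raises(ValueError):
            hm.apply_average_reference(np.ones((1, 10)))
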