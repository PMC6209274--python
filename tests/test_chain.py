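import numpy as np
import pytest
from scipy.optimize import brentq

from amylogel.chain import (
    _ATOM_ORDER,
    ChainModel,
    EnergyMap,
    debye_intensity,
    debye_intensity_array,
    default_energy_map,
    delta_energy_map,
    end_to_end_distance,
    generate_chain,
    model_kratky_maximum,
    sphere_form_factor,
)
from amylogel.curves import ScatteringCurve
from amylogel.errors import NoValidStateError, PeakNotFoundError
from amylogel.models import rod_term

ATOMS_PER_RESIDUE = len(_ATOM_ORDER)


class TestEnergyMap:
    def test_normalized_to_zero_minimum(self):
        m = default_energy_map()
        assert m.energy.min() == 0.0
        assert np.isfinite(m.energy).all()

    def test_all_forbidden_rejected(self):
        phi = psi = np.arange(-180.0, 180.0, 90.0)
        with pytest.raises(NoValidStateError):
            EnergyMap(phi, psi, np.full((4, 4), np.inf))

    def test_file_round_trip(self, tmp_path):
        m = default_energy_map(grid_step=30.0)
        m.to_file(tmp_path / "map.txt")
        back = EnergyMap.from_file(tmp_path / "map.txt")
        np.testing.assert_allclose(back.phi, m.phi)
        np.testing.assert_allclose(back.energy, m.energy, rtol=1e-6, atol=1e-8)

    def test_boltzmann_weights_sum_to_one(self):
        w = default_energy_map().boltzmann_weights(0.7)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert (w >= 0).all()


class TestGenerateChain:
    def test_dp50_atom_count_and_residues(self):
        chain = generate_chain(50, seed=0)
        assert chain.dp == 50
        assert len(chain) == 50 * ATOMS_PER_RESIDUE
        assert chain.residue_index.max() == 49
        # every residue has the same atom count
        counts = np.bincount(chain.residue_index)
        assert (counts == ATOMS_PER_RESIDUE).all()

    def test_deterministic_given_seed(self):
        a = generate_chain(20, seed=42)
        b = generate_chain(20, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        c = generate_chain(20, seed=43)
        assert not np.allclose(a.positions, c.positions)

    def test_single_minimum_map_end_to_end_matches_screw_closed_form(self):
        """A delta map produces a regular helix whose end-to-end distance must
        match the closed-form chord length computed from the screw
        decomposition of the (independent) residue-to-residue transform."""
        phi0, psi0 = -40.0, 175.0
        emap = delta_energy_map(phi0, psi0)
        dp = 30
        chain = generate_chain(dp, emap, seed=0)

        # independent rigid-transform oracle from a 2-residue build
        pair = generate_chain(2, emap, seed=1)
        n = ATOMS_PER_RESIDUE
        p0, p1 = pair.positions[:n], pair.positions[n:]
        c0, c1 = p0.mean(0), p1.mean(0)
        H = (p0 - c0).T @ (p1 - c1)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        t = c1 - R @ c0
        ang = np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))
        w, V = np.linalg.eig(R)
        axis = np.real(V[:, np.argmin(np.abs(w - 1))])
        axis /= np.linalg.norm(axis)
        rise = np.dot(t, axis)
        radius = np.linalg.norm(t - rise * axis) / (2 * np.sin(ang / 2))
        # chord between reference atom images on the helix
        ref = chain.positions[_ATOM_ORDER.index("C1")]
        # helix radius of the C1 orbit (may differ from centroid orbit):
        # compute from the C1-specific offset
        c1_first = pair.positions[_ATOM_ORDER.index("C1")]
        c1_second = pair.positions[n + _ATOM_ORDER.index("C1")]
        delta = c1_second - c1_first
        rise_c1 = np.dot(delta, axis)
        radius_c1 = np.linalg.norm(delta - rise_c1 * axis) / (2 * np.sin(ang / 2))
        m = dp - 1
        expected = np.hypot(m * rise_c1, 2 * radius_c1 * np.sin(m * ang / 2))
        assert end_to_end_distance(chain, "C1") == pytest.approx(expected, rel=1e-9)

    def test_flat_map_samples_uniformly(self):
        phi = psi = np.arange(-180.0, 180.0, 45.0)  # 8 x 8 cells
        flat = EnergyMap(phi, psi, np.zeros((8, 8)))
        chain = generate_chain(10_001, flat, seed=7)
        counts = np.zeros(8)
        for phi_val in chain.dihedrals[:, 0]:
            counts[int((phi_val + 180.0) / 45.0)] += 1
        # chi-square against uniform: 7 dof, p=0.999 cutoff ~ 24
        expected = 10_000 / 8
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < 24.0

    def test_temperature_scale_controls_chain_extension(self):
        """With a map whose main well is the compact helix and whose minor
        well is an extended state, hotter sampling visits the extended well
        more often, so the mean end-to-end distance grows monotonically."""
        phi = np.arange(-180.0, 180.0, 5.0)
        psi = np.arange(-180.0, 180.0, 5.0)
        from amylogel.chain import _periodic_delta

        energy = np.full((phi.size, psi.size), 12.0)
        for phi0, psi0, sigma, depth in ((-45.0, -175.0, 15.0, 8.0),
                                         (30.0, -150.0, 15.0, 5.0)):
            dp_ = _periodic_delta(phi, phi0)[:, None]
            ds_ = _periodic_delta(psi, psi0)[None, :]
            energy -= depth * np.exp(-(dp_**2 + ds_**2) / (2 * sigma**2))
        emap = EnergyMap(phi, psi, energy)

        means = []
        for temp in (0.5, 1.0, 2.0):
            e2e = [
                end_to_end_distance(generate_chain(30, emap, temp, seed=s))
                for s in range(200)
            ]
            means.append(np.mean(e2e))
        assert means[0] < means[1] < means[2]


class TestSphereFormFactor:
    def test_q_zero_gives_volume(self):
        r = 0.2
        assert sphere_form_factor(0.0, r) == pytest.approx(4 / 3 * np.pi * r**3)

    def test_first_zero_at_tan_u_equals_u(self):
        # independent root-find on sin(u) - u cos(u)
        u0 = brentq(lambda u: np.sin(u) - u * np.cos(u), 3.5, 5.5, xtol=1e-13)
        assert u0 == pytest.approx(4.4934, abs=1e-4)
        r = 0.16
        assert abs(sphere_form_factor(u0 / r, r)) < 1e-16

    def test_even_in_q(self):
        q = np.linspace(0.1, 30.0, 17)
        np.testing.assert_allclose(
            sphere_form_factor(q, 0.2), sphere_form_factor(-q, 0.2), rtol=1e-14
        )

    def test_series_branch_continuous(self):
        # values just below and above the small-u switchover agree
        r = 0.2
        q = np.array([1e-3 / r * 0.999, 1e-3 / r * 1.001])
        vals = sphere_form_factor(q, r)
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)


class TestDebyeIntensity:
    def test_single_atom_is_squared_amplitude(self):
        chain = ChainModel(
            np.zeros((1, 3)), np.array([0.2]), np.array([0]), dp=1
        )
        q = np.linspace(0.1, 5.0, 20)
        curve = debye_intensity(chain, q)
        np.testing.assert_allclose(
            curve.intensity, sphere_form_factor(q, 0.2) ** 2, rtol=1e-12
        )

    def test_two_spheres_closed_form(self):
        d = 0.5
        chain = ChainModel(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]),
            np.array([0.2, 0.2]),
            np.array([0, 0]),
            dp=1,
        )
        q = np.linspace(0.05, 6.0, 40)
        f = sphere_form_factor(q, 0.2)
        expected = 2 * f**2 * (1 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(
            debye_intensity(chain, q).intensity, expected, rtol=1e-12
        )

    def test_matches_naive_double_loop_oracle(self):
        chain = generate_chain(4, seed=3)
        q = np.linspace(0.1, 4.0, 15)
        got = debye_intensity(chain, q).intensity
        # naive O(N^2) double loop, including diagonal
        expected = np.zeros_like(q)
        for k, qv in enumerate(q):
            total = 0.0
            for i in range(len(chain)):
                fi = sphere_form_factor(qv, chain.radii[i])
                for j in range(len(chain)):
                    fj = sphere_form_factor(qv, chain.radii[j])
                    r = np.linalg.norm(chain.positions[i] - chain.positions[j])
                    total += fi * fj * (np.sin(qv * r) / (qv * r) if r > 0 else 1.0)
            expected[k] = total
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_q_zero_analytic_limit(self):
        chain = generate_chain(3, seed=1)
        vals = debye_intensity_array(chain, np.array([0.0]))
        f0 = sum(sphere_form_factor(0.0, r) for r in chain.radii)
        assert vals[0] == pytest.approx(f0**2, rel=1e-12)

    def test_intensity_positive_on_generated_chain(self):
        chain = generate_chain(50, seed=0)
        curve = debye_intensity(chain, np.linspace(0.1, 8.0, 100))
        assert curve.intensity[0] > 0
        assert np.all(np.isfinite(curve.intensity))


class TestKratkyMaximum:
    def test_truncated_rod_curve_has_no_interior_maximum(self):
        q = np.linspace(0.05, 1.0, 60)  # well below the cross-section feature
        curve = ScatteringCurve(q, rod_term(q, 1.0, 0.6))
        with pytest.raises(PeakNotFoundError):
            model_kratky_maximum(curve, q_max_required=1.0)

    def test_gaussian_aggregate_peak_at_inverse_xi(self):
        from amylogel.models import stretched_exp_term

        xi = 0.5
        q = np.linspace(0.05, 4.5, 400)
        curve = ScatteringCurve(q, stretched_exp_term(q, 1.0, xi, 2.0))
        assert model_kratky_maximum(curve) == pytest.approx(2.0, abs=0.02)

    def test_default_chain_peak_near_two(self):
        chain = generate_chain(50, seed=0)
        q_peak = model_kratky_maximum(chain)
        assert q_peak == pytest.approx(2.0, abs=0.5)

    def test_single_state_map_reproducible(self):
        emap = delta_energy_map(-40.0, 175.0)
        a = debye_intensity(generate_chain(15, emap, seed=0), np.linspace(0.1, 4, 50))
        b = debye_intensity(generate_chain(15, emap, seed=99), np.linspace(0.1, 4, 50))
        np.testing.assert_array_equal(a.intensity, b.intensity)
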