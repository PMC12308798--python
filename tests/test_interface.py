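"""Hydrogen-bond detection/statistics, bond ACFs, double-exponential fits."""

import dataclasses
import math

import numpy as np
import pytest

from lamella.chain_order import ACFSeries

from lamella.interface import (
    detect_hbonds,
    fit_double_exponential,
    glycerol_acf,
    hbond_acf,
    hbond_statistics,
)
from lamella.synthetic import (
    SyntheticSystemSpec,
    generate_decay_curve,
    generate_membrane_trajectory,
    _axis_angle_matrix,
)
from tests.test_core import make_traj


def pair_traj(distance, angle_deg, n_frames=1):
    """Two lipids with one O5-H...O4 contact at given geometry; everything
    else parked far away."""
    traj = make_traj([float(i) for i in range(n_frames)], n_lipids=2)
    topo = traj.topology
    apl = topo.atoms_per_lipid
    traj.coords[:] = 0.0
    for lid in range(2):
        block = traj.coords[:, lid * apl : (lid + 1) * apl]
        block[:] = np.arange(apl)[None, :, None] * 50.0 + 2000.0 * (lid + 1)
    don = np.array([10.0, 10.0, 10.0])
    traj.coords[:, 0 * apl + topo.name_map["O5"]] = don
    ang = math.radians(angle_deg)
    # acceptor along +x; hydrogen at the requested A-D-H angle from +x
    traj.coords[:, 1 * apl + topo.name_map["O4"]] = don + [distance, 0.0, 0.0]
    traj.coords[:, 0 * apl + topo.name_map["HO5"]] = don + 0.97 * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    traj.box[:] = [4000.0, 4000.0, 4000.0]
    return traj


class TestDetectHbonds:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (2.9, 10.0, 1),  # inside both cutoffs
            (3.6, 5.0, 0),  # distance fails
            (3.0, 35.0, 0),  # angle fails
            (3.5, 30.0, 1),  # boundary inclusive
        ],
    )
    def test_geometric_truth_table(self, distance, angle, expected):
        traj = pair_traj(distance, angle)
        bonds = [b for b in detect_hbonds(traj, 0) if b.kind == "inter"]
        assert len(bonds) == expected
        if expected:
            assert bonds[0].donor_group == "O5-H"
            assert bonds[0].acceptor_group == "O4"

    def test_invariant_under_rigid_rotation_translation(self):
        traj = pair_traj(3.0, 12.0)
        R = _axis_angle_matrix(np.array([0.3, -0.5, 0.8]), 1.1)
        moved = dataclasses.replace(
            traj, coords=(traj.coords.astype(float) @ R.T + [5.0, -3.0, 8.0]).astype(
                traj.coords.dtype
            )
        )
        a = [(b.donor_atom, b.acceptor_atom) for b in detect_hbonds(traj, 0)]
        b = [(b.donor_atom, b.acceptor_atom) for b in detect_hbonds(moved, 0)]
        assert a == b and len(a) >= 1

    def test_minimum_image_across_boundary(self):
        traj = pair_traj(2.9, 5.0)
        topo = traj.topology
        # move acceptor across the periodic boundary
        apl = topo.atoms_per_lipid
        traj.box[:] = [100.0, 4000.0, 4000.0]
        don = np.array([1.0, 10.0, 10.0])
        traj.coords[:, 0 * apl + topo.name_map["O5"]] = don
        traj.coords[:, 0 * apl + topo.name_map["HO5"]] = don + [-0.97, 0.0, 0.0]
        traj.coords[:, 1 * apl + topo.name_map["O4"]] = [98.0, 10.0, 10.0]  # 3 A away via wrap
        bonds = [b for b in detect_hbonds(traj, 0) if b.kind == "inter"]
        assert len(bonds) == 1


class TestHbondStatistics:
    def test_planted_bonds_per_molecule_arithmetic(self):
        spec = SyntheticSystemSpec(n_per_leaflet=10, n_frames=2, seed=6, hbond_fraction=0.7)
        traj, gt = generate_membrane_trajectory(spec)
        st = hbond_statistics(traj)
        assert st["inter"][0] == pytest.approx(
            gt.attrs["n_planted_inter_hbonds"] / traj.n_lipids
        )
        assert st["inter"][0] == pytest.approx(0.7)
        assert st["intra"][0] == 0.0

    def test_no_water_means_zero_water_columns(self, small_bilayer):
        traj, _ = small_bilayer
        st = hbond_statistics(traj)
        assert all(v[0] == 0.0 for v in st["groups"].values())

    def test_group_specific_planting(self):
        spec = SyntheticSystemSpec(
            n_per_leaflet=5, n_frames=2, seed=7, water_hbond_counts={"O5-H": 3}
        )
        traj, _ = generate_membrane_trajectory(spec)
        st = hbond_statistics(traj)
        got = {g: v[0] for g, v in st["groups"].items()}
        assert got == {"O1-H": 0.0, "O2": 0.0, "O3-H": 0.0, "O4": 0.0, "O5-H": 0.3}

    def test_counts_scale_inversely_with_system_size(self):
        """Same planted bond count, more inert lipids -> per-molecule rate drops."""
        spec10 = SyntheticSystemSpec(n_per_leaflet=10, n_frames=1, seed=9, hbond_fraction=0.5)
        t10, g10 = generate_membrane_trajectory(spec10)
        st10 = hbond_statistics(t10)
        assert st10["inter"][0] == pytest.approx(
            g10.attrs["n_planted_inter_hbonds"] / 20
        )


class TestHbondAcf:
    def indicator_traj(self, h_series):
        """Trajectory whose single donor-acceptor pair follows ``h_series``."""
        F = len(h_series)
        traj = pair_traj(2.9, 5.0, n_frames=F)
        topo = traj.topology
        apl = topo.atoms_per_lipid
        off = np.where(np.asarray(h_series) > 0, 0.0, 10.0)  # break the bond
        traj.coords[:, 1 * apl + topo.name_map["O4"], 0] = 12.9 + off
        return traj

    def test_permanent_bond_flat_before_correction(self):
        traj = self.indicator_traj(np.ones(30))
        acf = hbond_acf(traj, tail_correct=False)
        np.testing.assert_allclose(acf.values, 1.0)
        corrected = hbond_acf(traj, tail_correct=True)
        assert "plateau" in corrected.meta
        assert corrected.meta["plateau"] == pytest.approx(1.0)

    def test_bernoulli_bonds_decorrelate_to_p(self):
        rng = np.random.default_rng(10)
        p = 0.4
        F = 400
        traj = self.indicator_traj((rng.random(F) < p).astype(float))
        raw = hbond_acf(traj, tail_correct=False)
        # C(0) = 1; independent frames decay to <h> = p
        assert raw.values[0] == 1.0
        assert abs(raw.values[1:].mean() - p) < 0.05
        corr = hbond_acf(traj, tail_correct=True)
        assert abs(corr.values[1:].mean()) < 0.08

    def test_two_state_markov_matches_closed_form(self):
        """Intermittent indicator of a two-state Markov bond decays as
        exp(-(k_on + k_off) t)."""
        rng = np.random.default_rng(11)
        k_on, k_off, dt = 0.08, 0.12, 1.0
        F = 20_000
        h = np.empty(F)
        state = 1
        for f in range(F):
            h[f] = state
            if state and rng.random() < k_off:
                state = 0
            elif not state and rng.random() < k_on:
                state = 1
        traj = self.indicator_traj(h)
        traj = dataclasses.replace(traj, times=np.arange(F) * dt)
        acf = hbond_acf(traj, tail_correct=False, max_lag=25)
        # closed form with the chain's empirical occupancy (one realisation)
        p_hat = h.mean()
        lam = -math.log(1 - k_on - k_off)  # discrete-time decay rate
        t = np.arange(26) * dt
        expected = p_hat + (1 - p_hat) * np.exp(-lam * t)
        assert np.all(np.abs(acf.values - expected) / expected < 0.05)

    def test_no_bonds_rejected(self, small_bilayer):
        traj, _ = small_bilayer  # hbond_fraction = 0
        with pytest.raises(ValueError):
            hbond_acf(traj)


class TestDoubleExpFit:
    def test_reference_interdigitated_parameters_recovered(self):
        # slow/fast glycerol rotation parameters of an interdigitated system
        a1, tau1, a2, tau2 = 0.13, 6.6, 0.13, 104.4
        b = 1 - a1 - a2
        curve = generate_decay_curve(a1, tau1, a2, tau2, b, 0.0, np.linspace(0, 400, 600))
        fit = fit_double_exponential(ACFSeries(lags=curve.x, values=curve.y))
        for got, want in ((fit.a1, a1), (fit.tau1, tau1), (fit.a2, a2),
                          (fit.tau2, tau2), (fit.b, b)):
            assert abs(got - want) / want < 0.01
        assert fit.tau1 <= fit.tau2
        assert not fit.degenerate

    def test_noisy_curve_recovered_within_ten_percent(self):
        a1, tau1, a2, tau2, b = 0.23, 2.1, 0.12, 57.3, 0.65
        curve = generate_decay_curve(a1, tau1, a2, tau2, b, 0.01,
                                     np.linspace(0, 250, 800), seed=12)
        fit = fit_double_exponential(ACFSeries(lags=curve.x, values=curve.y))
        for got, want in ((fit.a1, a1), (fit.tau1, tau1), (fit.a2, a2),
                          (fit.tau2, tau2), (fit.b, b)):
            assert abs(got - want) / want < 0.10

    def test_pure_constant_recovered(self):
        t = np.linspace(0, 100, 200)
        fit = fit_double_exponential(ACFSeries(lags=t, values=np.full_like(t, 0.5)))
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.degenerate  # amplitudes vanish

    def test_single_exponential_flagged_degenerate(self):
        t = np.linspace(0, 100, 300)
        y = 0.6 * np.exp(-t / 10.0) + 0.4
        fit = fit_double_exponential(ACFSeries(lags=t, values=y))
        assert fit.degenerate
        # the sum of amplitudes still reproduces the curve
        np.testing.assert_allclose(fit.evaluate(t), y, atol=1e-4)

    def test_lag_rescaling_scales_taus_linearly(self):
        a1, tau1, a2, tau2, b = 0.3, 4.0, 0.2, 60.0, 0.5
        t = np.linspace(0, 300, 500)
        y = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + b
        f1 = fit_double_exponential(ACFSeries(lags=t, values=y))
        f2 = fit_double_exponential(ACFSeries(lags=t * 1000.0, values=y))
        assert f2.tau1 == pytest.approx(f1.tau1 * 1000.0, rel=1e-3)
        assert f2.tau2 == pytest.approx(f1.tau2 * 1000.0, rel=1e-3)
        assert f2.a1 == pytest.approx(f1.a1, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_double_exponential(ACFSeries(lags=np.arange(5.0), values=np.ones(5)))


class TestGlycerolAcf:
    def test_static_headgroups_flat(self):
        traj = make_traj([float(i) for i in range(20)])
        acf = glycerol_acf(traj)
        np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)

    def test_planted_timescales_recovered(self):
        """Round trip: generator plants tau1/tau2, ACF + fit recover them."""
        spec = SyntheticSystemSpec(
            n_per_leaflet=150,
            n_frames=500,
            frame_dt=500.0,
            headgroup_tau1=2000.0,
            headgroup_tau2=50000.0,
            headgroup_a1=0.2,
            headgroup_a2=0.1,
            seed=17,
            tail_dynamics=False,
        )
        traj, _ = generate_membrane_trajectory(spec)
        acf = glycerol_acf(traj)
        fit = fit_double_exponential(acf)
        assert abs(fit.tau1 - 2000.0) / 2000.0 < 0.15
        assert abs(fit.tau2 - 50000.0) / 50000.0 < 0.15

    def test_equal_timescales_effectively_single_exponential(self):
        spec = SyntheticSystemSpec(
            n_per_leaflet=100,
            n_frames=200,
            frame_dt=500.0,
            headgroup_tau1=10000.0,
            headgroup_tau2=10000.0,
            headgroup_a1=0.2,
            headgroup_a2=0.2,
            seed=18,
            tail_dynamics=False,
        )
        traj, _ = generate_membrane_trajectory(spec)
        acf = glycerol_acf(traj)
        single = 0.4 * np.exp(-acf.lags / 10000.0) + 0.6
        assert np.max(np.abs(acf.values - single)) < 0.03
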