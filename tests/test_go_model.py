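import numpy as np
import pytest
from dataclasses import replace

from polyqlab import descriptors as desc
from polyqlab import go_model as go
from polyqlab import synthetic as syn


class TestBuildModel:
    def test_native_energy_is_minus_eps_per_contact(self, hairpin_model):
        model, cmap = hairpin_model
        e = go.potential_energy(model, model.native_coords)
        assert e == pytest.approx(-model.n_contacts, abs=1e-9)

    def test_contact_minimum_at_native_distance(self, hairpin_model):
        model, _ = hairpin_model
        # numerical derivative of one contact potential at its minimum
        r0 = model.contact_r0[0]
        h = 1e-6

        def vlj(r):
            return (r0 / r) ** 12 - 2 * (r0 / r) ** 6

        dv = (vlj(r0 + h) - vlj(r0 - h)) / (2 * h)
        assert abs(dv) < 1e-6

    def test_extended_chain_has_no_contacts(self, extended10):
        cmap = desc.build_contact_map(extended10)
        model = go.build_go_model(extended10, cmap)
        assert model.n_contacts == 0

    def test_forces_match_numerical_gradient(self, hairpin_model):
        model, _ = hairpin_model
        coords = model.native_coords + 0.05
        forces = go.forces_at(model, coords)
        h = 1e-6
        for a in (0, 5, 15):
            for d in range(3):
                cp = coords.copy()
                cp[a, d] += h
                cm = coords.copy()
                cm[a, d] -= h
                num = -(go.potential_energy(model, cp)
                        - go.potential_energy(model, cm)) / (2 * h)
                assert forces[a, d] == pytest.approx(num, abs=1e-5)


class TestLangevin:
    def test_energy_conservation_undamped(self, hairpin_model):
        """gamma = 0, T = 0: symplectic integration keeps energy flat."""
        model, _ = hairpin_model
        params = go.GoModelParams(temperature=0.0, damping=0.0, seed=1)
        start = syn.perturb(syn.make_ideal("hairpin", 16), 0.02, 1).ca_coords()
        res = go.run_langevin(model, params, 100000, record_every=100,
                              initial_coords=start)
        etot = res.kinetic + res.potential
        n = len(etot)
        drift = abs(etot[-n // 10:].mean() - etot[:n // 10].mean())
        assert drift < 1e-4

    def test_equipartition(self, hairpin_model):
        model, _ = hairpin_model
        params = go.GoModelParams(seed=2)
        res = go.run_langevin(model, params, 1000000, record_every=1000)
        ke_per_dof = res.kinetic[len(res.kinetic) // 10:].mean() / (3 * 16)
        assert ke_per_dof == pytest.approx(0.15, rel=0.10)

    def test_same_seed_same_trajectory(self, hairpin_model):
        model, _ = hairpin_model
        params = go.GoModelParams(seed=5)
        r1 = go.run_langevin(model, params, 5000, record_every=500)
        r2 = go.run_langevin(model, params, 5000, record_every=500)
        assert np.array_equal(r1.frames, r2.frames)


class TestPulling:
    def test_hairpin_articulates_a_peak(self, hairpin_pull):
        _, _, params, curve, _ = hairpin_pull
        assert curve.n_p >= 1
        assert curve.F_max > params.noise_level

    def test_final_extension_near_contour(self, hairpin_pull):
        model, _, _, _, traj = hairpin_pull
        ext = np.linalg.norm(traj[-1][-1] - traj[-1][0])
        assert ext >= 0.9 * model.contour_length

    def test_zero_contact_chain_has_no_peaks(self, extended10):
        cmap = desc.build_contact_map(extended10)
        model = go.build_go_model(extended10, cmap)
        curve, _ = go.pull_constant_speed(model, go.GoModelParams(seed=3))
        assert curve.n_p == 0
        assert curve.F_max == 0.0

    def test_fmax_stable_across_seeds(self, hairpin_model):
        """Relative spread of F_max over seeds stays below 30%."""
        model, _ = hairpin_model
        vals = []
        for s in range(6):
            curve, _ = go.pull_constant_speed(
                model, go.GoModelParams(seed=100 + s))
            vals.append(curve.F_max)
        vals = np.array(vals)
        assert vals.std() / vals.mean() < 0.30


class TestPeakDetection:
    def _bump_curve(self, heights, centers, width=5.0):
        d = np.linspace(0, 100, 2001)
        f = np.zeros_like(d)
        for h, c in zip(heights, centers):
            f += h * np.exp(-((d - c) / width) ** 2)
        f += 2.0 * np.exp((d - 100) / 3.0)  # terminal rise
        return d, f

    def test_single_bump(self):
        d, f = self._bump_curve([1.2], [40])
        curve = go.detect_force_peaks((d, f), 0.1)
        assert curve.n_p == 1
        assert curve.F_max == pytest.approx(1.2, abs=0.05)

    def test_subthreshold_bump_ignored(self):
        d, f = self._bump_curve([0.05], [40])
        curve = go.detect_force_peaks((d, f), 0.1)
        assert curve.n_p == 0
        assert curve.F_max == 0.0

    def test_two_bumps(self):
        d, f = self._bump_curve([0.5, 1.0], [30, 60])
        curve = go.detect_force_peaks((d, f), 0.1)
        assert curve.n_p == 2
        assert curve.F_max == pytest.approx(1.0, abs=0.05)

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            go.detect_force_peaks((np.array([]), np.array([])), 0.1)


class TestScenario:
    def _toy_trajectory(self, dists, r0=5.0):
        """One contact (0, 4) whose distance follows `dists` over frames."""
        frames = np.zeros((len(dists), 5, 3))
        for k, dd in enumerate(dists):
            frames[k, 4, 0] = dd
        disp = 10.0 * np.arange(len(dists), dtype=float)
        cmap = desc.ContactMap(5, [(0, 4)], np.array([r0]))
        return go.PullTrajectory(frames, disp), cmap

    def test_single_break(self):
        traj, cmap = self._toy_trajectory([5.0, 6.0, 8.0, 9.0])  # >7.5 at k=2
        events = go.unfolding_scenario(traj, cmap, 1.5)
        assert events[0].d_break == pytest.approx(20.0)
        assert events[0].sep == 4

    def test_rebreak_takes_last_time(self):
        traj, cmap = self._toy_trajectory([5.0, 8.0, 6.0, 9.0, 9.5])
        events = go.unfolding_scenario(traj, cmap, 1.5)
        assert events[0].d_break == pytest.approx(30.0)

    def test_unbroken_flagged(self):
        traj, cmap = self._toy_trajectory([5.0, 6.0, 7.0])
        events = go.unfolding_scenario(traj, cmap, 1.5)
        assert events[0].d_break is None
        assert not events[0].broken

    def test_real_pull_breaks_cross_strand_contacts(self, hairpin_pull):
        _, cmap, params, _, traj = hairpin_pull
        events = go.unfolding_scenario(traj, cmap, params.break_factor)
        broken = [e for e in events if e.broken]
        assert len(broken) == len(events)  # full unfolding breaks everything
        contour = 15 * 3.8
        assert all(0 <= e.d_break <= 1.2 * contour for e in broken)


class TestUnits:
    def test_force_conversion_exact(self):
        assert go.force_to_pN(1.0) == pytest.approx(110.0)
        assert go.force_to_pN(np.array([2.1, 2.3])) == pytest.approx(
            [231.0, 253.0])

    def test_param_validation(self):
        with pytest.raises(ValueError):
            go.GoModelParams(timestep=0)
        with pytest.raises(ValueError):
            go.GoModelParams(temperature=-0.1)
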