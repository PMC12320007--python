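"""Forward model: bilinear neural dynamics and haemodynamic cascade."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from facedcm.generative_model import (
    HemodynamicParameters,
    NeuralParameters,
    SimulationOutput,
    _neural_trajectory,
    add_noise,
    bold_forward,
    integrate,
    neural_derivative,
)
from facedcm.network_model import get_model, mirror_permutation, region_index
from facedcm.paradigm import (
    RegressorSet,
    StimulusSchedule,
    build_regressors,
    generate_schedule,
)
from facedcm.synthetic_data import sample_parameters

DT = 1.45 / 16


def _linear_params():
    """Canonical A + C values, no modulation."""
    p = NeuralParameters.zeros()
    for src, tgt, v in [
        ("lV1", "lOFA", 0.3), ("rV1", "rOFA", 0.3),
        ("lV1", "lFFA", 0.3), ("rV1", "rFFA", 0.3),
        ("lOFA", "lFFA", 0.2), ("rOFA", "rFFA", 0.2),
        ("lFFA", "lOFA", 0.1), ("rFFA", "rOFA", 0.1),
        ("lOFA", "rOFA", 0.05), ("rOFA", "lOFA", 0.05),
        ("lFFA", "rFFA", 0.05), ("rFFA", "lFFA", 0.05),
    ]:
        p.a[region_index(tgt), region_index(src)] = v
    p.c[region_index("lV1"), 0] = 0.4
    p.c[region_index("rV1"), 0] = 0.4
    p.c[region_index("rV1"), 1] = 0.4
    p.c[region_index("lV1"), 2] = 0.4
    return p


class TestNeuralDerivative:
    def test_zero_state_zero_input_is_fixed_point(self):
        p = NeuralParameters.zeros()
        dz = neural_derivative(np.zeros(6), np.zeros(3), np.zeros(3), p)
        assert np.allclose(dz, 0.0)

    def test_unit_state_reads_out_effective_column(self):
        p = _linear_params()
        a_eff = p.a_eff()
        for i in range(6):
            z = np.zeros(6)
            z[i] = 1.0
            dz = neural_derivative(z, np.zeros(3), np.zeros(3), p)
            assert np.allclose(dz, a_eff[:, i])

    def test_nonfinite_input_rejected(self):
        p = NeuralParameters.zeros()
        with pytest.raises(ValueError):
            neural_derivative(np.full(6, np.nan), np.zeros(3), np.zeros(3), p)

    def test_matches_finite_difference_of_trajectory(self):
        spec = get_model("M5")
        params = sample_parameters(spec, seed=8)
        sch = generate_schedule(1, seed=2)
        reg = build_regressors(sch, n_scans=60)
        traj = _neural_trajectory(params, reg, 60)
        # pick interior points away from input switches
        for t in (40, 200, 500):
            u = reg.u[t]
            dz = neural_derivative(traj[t], u[:3], u[3:], params)
            fd = (traj[t + 1] - traj[t - 1]) / (2 * reg.dt)
            assert np.allclose(dz, fd, atol=1e-3)


class TestBoldForward:
    def test_zero_neural_gives_zero_bold(self):
        out = bold_forward(np.zeros((500, 6)))
        assert np.allclose(out, 0.0)

    def test_impulse_response_peaks_between_3_and_8_seconds(self):
        n = int(30.0 / DT)
        neural = np.zeros((n, 6))
        neural[: int(0.5 / DT)] = 1.0
        out = bold_forward(neural)
        peak_idx = np.argmax(out[:, 0])
        peak_t = peak_idx * DT
        assert 3.0 <= peak_t <= 8.0
        # single-peaked and returning toward baseline
        assert abs(out[-1, 0]) < 0.2 * out[peak_idx, 0]

    def test_weak_input_linearity(self):
        n = int(30.0 / DT)
        base = np.zeros((n, 6))
        base[: int(10.0 / DT)] = 0.01
        y1 = bold_forward(base)
        y2 = bold_forward(2 * base)
        ratio = y2[:, 0].max() / y1[:, 0].max()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_nonphysical_hemodynamics_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicParameters(transit=-1.0)
        with pytest.raises(ValueError):
            HemodynamicParameters(stiffness=1.5)
        with pytest.raises(ValueError):
            HemodynamicParameters(extraction=1.2)


class TestIntegrate:
    def test_neutral_parameters_give_flat_output(self, m5, reduced_regressors):
        out = integrate(m5, NeuralParameters.zeros(),
                        regressors=reduced_regressors)
        assert out.bold.shape == (200, 6)
        assert np.allclose(out.bold, 0.0)

    def test_linear_system_matches_matrix_exponential_oracle(
        self, m5, reduced_regressors
    ):
        """With B = 0 the neural subsystem is LTI per input pattern; the
        integrator must agree with independent expm stepping."""
        params = _linear_params()
        n_scans = 60
        traj = _neural_trajectory(params, reduced_regressors, n_scans)

        u = reduced_regressors.u[: n_scans * 16]
        a_eff = params.a_eff()
        z = np.zeros(6)
        oracle = np.zeros_like(traj)
        cache = {}
        for t in range(u.shape[0]):
            oracle[t] = z
            key = tuple(u[t])
            if key not in cache:
                e = expm(a_eff * reduced_regressors.dt)
                cu = params.c @ u[t, :3]
                d = np.linalg.solve(a_eff, (e - np.eye(6)) @ cu)
                cache[key] = (e, d)
            e, d = cache[key]
            z = e @ z + d
        rms = np.sqrt(np.mean((traj - oracle) ** 2))
        assert rms < 1e-6

    def test_full_model_matches_high_accuracy_ode_oracle(
        self, m5, reduced_regressors
    ):
        params = sample_parameters(m5, seed=3)
        hemo = HemodynamicParameters()
        n_test = 40
        y = integrate(m5, params, regressors=reduced_regressors,
                      n_scans=n_test).bold

        u_grid = reduced_regressors.u
        dt = reduced_regressors.dt
        a_eff = params.a_eff()

        def rhs(t, x):
            z, s, lf, lv, lq = x.reshape(5, 6)
            u = u_grid[min(int(t / dt), u_grid.shape[0] - 1)]
            j = a_eff + sum(u[3 + k] * params.b[k] for k in range(3))
            dz = j @ z + params.c @ u[:3]
            f, v, q = np.exp(lf), np.exp(lv), np.exp(lq)
            fv = v ** (1 / hemo.stiffness)
            ef = 1 - (1 - hemo.extraction) ** (1 / f)
            ds = z - hemo.signal_decay * s - hemo.feedback * (f - 1)
            return np.concatenate([
                dz, ds, s / f,
                (f - fv) / (hemo.transit * v),
                (f * ef / hemo.extraction - fv * q / v) / (hemo.transit * q),
            ])

        t_eval = (np.arange(n_test) + 1) * 1.45
        sol = solve_ivp(rhs, (0, t_eval[-1]), np.zeros(30), t_eval=t_eval,
                        rtol=1e-10, atol=1e-12, max_step=dt)
        lv, lq = sol.y[18:24].T, sol.y[24:30].T
        v, q = np.exp(lv), np.exp(lq)
        k1, k2, k3 = hemo.bold_k
        y_oracle = 100 * hemo.venous_volume * (
            k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v)
        )
        rms = np.sqrt(np.mean((y - y_oracle) ** 2))
        assert rms < 1e-4

    def test_grid_convergence_on_fixed_input(self, m5, reduced_regressors):
        """Halving the microtime step (same rasterised input) changes the
        sampled BOLD by far less than 1e-4 RMS."""
        params = sample_parameters(m5, seed=3)
        r16 = reduced_regressors
        r32 = RegressorSet(
            times=np.repeat(r16.times, 2),
            u=np.repeat(r16.u, 2, axis=0),
            tr=r16.tr, bins_per_scan=32, n_scans=r16.n_scans,
        )
        y16 = integrate(m5, params, regressors=r16, n_scans=100).bold
        y32 = integrate(m5, params, regressors=r32, n_scans=100).bold
        rms = np.sqrt(np.mean((y16 - y32) ** 2))
        assert rms < 1e-4

    def test_hemisphere_symmetry_under_central_stimulation(self, m5):
        blocks = []
        t = 0.0
        for cond in ("FC", "OC", "FC"):
            blocks.append((cond, t, 15.75))
            t += 15.75
            blocks.append(("baseline", t, 7.875))
            t += 7.875
        reg = build_regressors(StimulusSchedule(blocks=blocks), n_scans=80)

        p = _linear_params()
        p.c[:, 1:] = 0.0  # central input only
        mirror_pairs = [("lOFA", "rOFA"), ("lFFA", "rFFA")]
        for m in range(3):
            for a, b in mirror_pairs:
                p.b[m, region_index(b), region_index(a)] = 0.3
                p.b[m, region_index(a), region_index(b)] = 0.3
        out = integrate(m5, p, regressors=reg).bold
        perm = mirror_permutation()
        assert np.allclose(out, out[:, perm], atol=1e-10)

    def test_stable_random_couplings_stay_bounded(self, m5, reduced_regressors):
        """Whenever the drawn coupling matrix is spectrally stable, the
        integrator must stay bounded over the whole session (random
        couplings with zero self log-scaling, i.e. -0.5 Hz self-decay)."""
        rng = np.random.default_rng(0)
        mask = m5.structure.a_mask & ~np.eye(6, dtype=bool)
        tested = 0
        for _ in range(20):
            p = NeuralParameters.zeros()
            draws = np.clip(rng.normal(0, 0.15, int(mask.sum())), -0.45, 0.45)
            p.a[mask] = draws
            p.c[region_index("lV1"), 0] = 0.4
            p.c[region_index("rV1"), 0] = 0.4
            if np.max(np.linalg.eigvals(p.a_eff()).real) >= -0.05:
                continue  # weakly damped draw: boundedness not guaranteed
            tested += 1
            out = integrate(m5, p, regressors=reduced_regressors)
            assert np.all(np.isfinite(out.bold))
            assert np.abs(out.bold).max() < 50.0
        assert tested >= 10

    def test_unstable_parameters_abort_with_diagnostic(self, m5, reduced_regressors):
        p = _linear_params()
        # strong symmetric positive feedback overwhelms the self-decay
        for a, b in (("lOFA", "rOFA"), ("lFFA", "rFFA")):
            p.a[region_index(b), region_index(a)] = 0.9
            p.a[region_index(a), region_index(b)] = 0.9
        with pytest.raises(RuntimeError, match="diverged"):
            integrate(m5, p, regressors=reduced_regressors)

    def test_mask_violations_rejected(self, m1, reduced_regressors):
        p = NeuralParameters.zeros()
        p.b[0, region_index("lFFA"), region_index("lOFA")] = 0.3  # not in M1
        with pytest.raises(ValueError, match="outside the mask"):
            integrate(m1, p, regressors=reduced_regressors)

    def test_tsv_round_trip(self, tmp_path, m5, reduced_regressors):
        params = sample_parameters(m5, seed=1)
        out = integrate(m5, params, regressors=reduced_regressors, n_scans=50)
        path = tmp_path / "bold.tsv"
        out.to_tsv(path)
        clone = SimulationOutput.from_tsv(path, tr=1.45)
        assert np.allclose(clone.bold, out.bold, atol=1e-7)


class TestAddNoise:
    def _clean(self, n=200):
        return SimulationOutput(bold=np.zeros((n, 6)), tr=1.45)

    def test_zero_noise_is_identity(self, snr4_subject):
        noisy, _ = add_noise(snr4_subject.clean, noise_sd=0.0, seed=1)
        assert np.array_equal(noisy.bold, snr4_subject.clean.bold)

    def test_seed_reproducibility(self, snr4_subject):
        a, _ = add_noise(snr4_subject.clean, target_snr=1.0, seed=7)
        b, _ = add_noise(snr4_subject.clean, target_snr=1.0, seed=7)
        c, _ = add_noise(snr4_subject.clean, target_snr=1.0, seed=8)
        assert np.array_equal(a.bold, b.bold)
        assert not np.array_equal(a.bold, c.bold)

    def test_large_sample_noise_sd(self):
        noisy, meta = add_noise(self._clean(n=5000), noise_sd=0.5, seed=2)
        est = noisy.bold.std(axis=0, ddof=1)
        assert np.all(np.abs(est - 0.5) / 0.5 < 0.05)

    def test_realised_snr_recorded(self, snr4_subject):
        _, meta = add_noise(snr4_subject.clean, target_snr=2.0, seed=0)
        assert np.allclose(meta["realised_snr"], 2.0)

    def test_exactly_one_noise_spec_required(self, snr4_subject):
        with pytest.raises(ValueError):
            add_noise(snr4_subject.clean, seed=0)
        with pytest.raises(ValueError):
            add_noise(snr4_subject.clean, noise_sd=0.1, target_snr=1.0, seed=0)
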