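"""Deterministic forward model: bilinear neural dynamics + haemodynamics.

Neural states of the six regions evolve under the bilinear equation

    dz/dt = (A_eff + sum_j u_j B_j) z + C u_drive

where the diagonal of A is parameterised as unitless log-scalings a_ii with
effective self-decay ``-0.5 * exp(a_ii)`` Hz (larger a_ii = faster decay),
off-diagonal A, B and C entries are coupling rates in Hz, the u_j are the
three face modulators (CF, LF, RF) and u_drive the three driving inputs
(CS, LS, RS).

Each region's neural activity drives a four-state balloon/windkessel
haemodynamic cascade (vasodilatory signal s, normalised blood flow f,
venous volume v, deoxyhaemoglobin content q):

    ds/dt = z - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f E(f, E0)/E0 - v**(1/alpha) q / v,   E(f) = 1-(1-E0)**(1/f)

and the BOLD percent signal change is the static observation

    y = 100 V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]

with k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.  All haemodynamic constants are
collected in :class:`HemodynamicParameters`; the defaults (kappa = 0.64/s,
gamma = 0.32/s, tau = 2 s, alpha = 0.32, E0 = 0.4, V0 = 0.04) are the
standard values used throughout the fMRI effective-connectivity literature.

Integration exploits the piecewise-constant block inputs: within a stretch
of constant input the neural subsystem is linear-time-invariant, so its
microtime update is the exact discrete propagator ``expm(J dt)`` (an
exponential-Euler step, exact here; applied twice per bin at half
resolution, which also yields mid-bin states).  The haemodynamic states
are advanced by a classical RK4 step per microtime bin on log-transformed
f, v, q (guaranteeing positivity).  The inner loop is JIT-compiled and
batched over parameter vectors, which makes finite-difference Jacobians
cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import expm

from .network_model import (
    MODULATORY_INPUTS,
    N_REGIONS,
    REGIONS,
    ModelSpec,
)
from .paradigm import RegressorSet

__all__ = [
    "NeuralParameters",
    "HemodynamicParameters",
    "SimulationOutput",
    "neural_derivative",
    "bold_forward",
    "integrate",
    "integrate_batch",
    "add_noise",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class NeuralParameters:
    """Coupling parameters of the bilinear neural model.

    ``a`` is 6x6 (diagonal = unitless self log-scalings a_ii, off-diagonal =
    coupling rates in Hz), ``b`` is (3, 6, 6) ordered as (CF, LF, RF), and
    ``c`` is 6x3 over (CS, LS, RS).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls) -> "NeuralParameters":
        return cls(
            a=np.zeros((N_REGIONS, N_REGIONS)),
            b=np.zeros((len(MODULATORY_INPUTS), N_REGIONS, N_REGIONS)),
            c=np.zeros((N_REGIONS, 3)),
        )

    def a_eff(self) -> np.ndarray:
        """A with the diagonal mapped to the effective decay -0.5 exp(a_ii)."""
        a = np.array(self.a, dtype=float, copy=True)
        np.fill_diagonal(a, -0.5 * np.exp(np.diag(self.a)))
        return a

    def check_masks(self, spec: ModelSpec) -> None:
        """Raise if any nonzero entry falls outside the model's masks."""
        s = spec.structure
        off = ~np.eye(N_REGIONS, dtype=bool)
        if np.any((self.a != 0) & off & ~s.a_mask):
            raise ValueError("A has nonzero entries outside the mask")
        for k, name in enumerate(MODULATORY_INPUTS):
            if np.any((self.b[k] != 0) & ~s.b_masks[name]):
                raise ValueError(f"B[{name}] has nonzero entries outside the mask")
        if np.any((self.c != 0) & ~s.c_mask):
            raise ValueError("C has nonzero entries outside the mask")


def _per_region(value, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (N_REGIONS,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class HemodynamicParameters:
    """Balloon/windkessel constants, per region (scalars broadcast)."""

    signal_decay: np.ndarray = 0.64   # kappa, 1/s
    feedback: np.ndarray = 0.32       # gamma, 1/s
    transit: np.ndarray = 2.0         # tau, s
    stiffness: float = 0.32           # alpha (Grubb exponent)
    extraction: float = 0.4           # E0, resting O2 extraction fraction
    venous_volume: float = 0.04       # V0, resting venous volume fraction

    def __post_init__(self) -> None:
        self.signal_decay = _per_region(self.signal_decay, "signal_decay")
        self.feedback = _per_region(self.feedback, "feedback")
        self.transit = _per_region(self.transit, "transit")
        if np.any(self.signal_decay <= 0) or np.any(self.feedback <= 0):
            raise ValueError("rate constants must be strictly positive")
        if np.any(self.transit <= 0):
            raise ValueError("transit time must be strictly positive")
        if not (0 < self.stiffness < 1):
            raise ValueError("stiffness exponent must lie in (0, 1)")
        if not (0 < self.extraction < 1):
            raise ValueError("extraction fraction must lie in (0, 1)")
        if self.venous_volume <= 0:
            raise ValueError("venous volume fraction must be positive")

    @property
    def bold_k(self) -> tuple[float, float, float]:
        e0 = self.extraction
        return (7.0 * e0, 2.0, 2.0 * e0 - 0.2)


@dataclass
class SimulationOutput:
    """BOLD output of a forward simulation (percent signal change).

    ``bold`` has shape (n_scans, 6); sample ``s`` is the state at the end
    of scan ``s``.  Optional microtime trajectories are kept for
    diagnostics.
    """

    bold: np.ndarray
    tr: float
    neural: np.ndarray | None = None
    times: np.ndarray | None = None

    @property
    def n_scans(self) -> int:
        return self.bold.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.bold, columns=list(REGIONS))
        df.insert(0, "scan", np.arange(self.n_scans))
        df.to_csv(path, sep="\t", index=False, float_format="%.8f")

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float) -> "SimulationOutput":
        df = pd.read_csv(path, sep="\t")
        return cls(bold=df[list(REGIONS)].to_numpy(dtype=float), tr=tr)


# ---------------------------------------------------------------------------
# neural dynamics
# ---------------------------------------------------------------------------


def neural_derivative(
    state: np.ndarray,
    driving: np.ndarray,
    modulatory: np.ndarray,
    params: NeuralParameters,
) -> np.ndarray:
    """dz/dt of the bilinear neural model at one instant."""
    z = np.asarray(state, dtype=float)
    ud = np.asarray(driving, dtype=float)
    um = np.asarray(modulatory, dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(ud)) and np.all(np.isfinite(um))):
        raise ValueError("state and inputs must be finite")
    j = params.a_eff()
    for k in range(len(MODULATORY_INPUTS)):
        j = j + um[k] * params.b[k]
    return j @ z + params.c @ ud


def _input_patterns(regressors: RegressorSet) -> tuple[np.ndarray, np.ndarray]:
    """Unique input rows and the per-bin pattern index."""
    patterns, idx = np.unique(regressors.u, axis=0, return_inverse=True)
    return patterns, idx.astype(np.int64)


def _build_propagators(
    a_eff: np.ndarray, b: np.ndarray, c: np.ndarray, patterns: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact discrete-time affine maps z -> E z + d for each input pattern.

    Batched: ``a_eff`` (P,6,6), ``b`` (P,3,6,6), ``c`` (P,6,3); returns
    E (P,n_pat,6,6) and d (P,n_pat,6).  Uses the augmented-matrix
    exponential so constant driving input is handled exactly even when the
    coupling matrix is singular.
    """
    p = a_eff.shape[0]
    n_pat = patterns.shape[0]
    drive = patterns[:, :3]      # (n_pat, 3)
    mod = patterns[:, 3:]        # (n_pat, 3)

    # J[p, q] = a_eff[p] + sum_k mod[q, k] * b[p, k]
    j = a_eff[:, None, :, :] + np.einsum("qk,pkij->pqij", mod, b)
    cu = np.einsum("pik,qk->pqi", c, drive)

    aug = np.zeros((p, n_pat, N_REGIONS + 1, N_REGIONS + 1))
    aug[:, :, :N_REGIONS, :N_REGIONS] = j * dt
    aug[:, :, :N_REGIONS, N_REGIONS] = cu * dt
    e_aug = expm(aug.reshape(-1, N_REGIONS + 1, N_REGIONS + 1))
    e_aug = e_aug.reshape(p, n_pat, N_REGIONS + 1, N_REGIONS + 1)
    return (
        np.ascontiguousarray(e_aug[:, :, :N_REGIONS, :N_REGIONS]),
        np.ascontiguousarray(e_aug[:, :, :N_REGIONS, N_REGIONS]),
    )


@njit(cache=True, inline="always", fastmath=True)
def _hemo_rhs(z_r, s, lf, lv, lq, kappa_r, gamma_r, tau_r,
              inv_alpha, e0, one_minus_e0):  # pragma: no cover
    # saturate the log-states before exponentiating so that extreme
    # intermediate stages stay finite (the outer guard flags divergence)
    lf = min(max(lf, -4.0), 8.0)
    lv = min(max(lv, -4.0), 8.0)
    lq = min(max(lq, -4.0), 8.0)
    f = np.exp(lf)
    v = np.exp(lv)
    qd = np.exp(lq)
    fv = v ** inv_alpha
    ef = 1.0 - one_minus_e0 ** (1.0 / f)
    d_s = z_r - kappa_r * s - gamma_r * (f - 1.0)
    d_lf = s / f
    d_lv = (f - fv) / (tau_r * v)
    d_lq = (f * ef / e0 - fv * qd / v) / (tau_r * qd)
    return d_s, d_lf, d_lv, d_lq


@njit(cache=True, fastmath=True)
def _simulate_kernel(
    e_half, d_half, pat_idx, kappa, gamma, tau, alpha, e0, v0,
    dt, bins_per_scan, n_scans, bold_out,
):  # pragma: no cover - exercised via integrate()
    """Batched microtime integration; returns per-batch status (0 = ok).

    Neural states advance by two exact half-bin propagator applications
    (which also yields the mid-bin state); the haemodynamic states take a
    classical RK4 step per bin using the start / mid / end neural values.
    """
    n_batch = e_half.shape[0]
    n_steps = pat_idx.shape[0]
    nr = bold_out.shape[2]
    k1c = 7.0 * e0
    k2c = 2.0
    k3c = 2.0 * e0 - 0.2
    status = np.zeros(n_batch, dtype=np.int64)
    inv_alpha = 1.0 / alpha
    one_minus_e0 = 1.0 - e0
    half = 0.5 * dt
    sixth = dt / 6.0

    for p in range(n_batch):
        z = np.zeros(nr)
        zm = np.zeros(nr)
        zn = np.zeros(nr)
        s = np.zeros(nr)
        lf = np.zeros(nr)
        lv = np.zeros(nr)
        lq = np.zeros(nr)
        scan = 0
        ok = True
        for t in range(n_steps):
            q = pat_idx[t]
            for i in range(nr):
                acc = d_half[p, q, i]
                for jj in range(nr):
                    acc += e_half[p, q, i, jj] * z[jj]
                zm[i] = acc
            for i in range(nr):
                acc = d_half[p, q, i]
                for jj in range(nr):
                    acc += e_half[p, q, i, jj] * zm[jj]
                zn[i] = acc
            for r in range(nr):
                kap = kappa[p, r]
                gam = gamma[p, r]
                tr = tau[p, r]
                a1, b1, c1, e1 = _hemo_rhs(
                    z[r], s[r], lf[r], lv[r], lq[r], kap, gam, tr,
                    inv_alpha, e0, one_minus_e0)
                a2, b2, c2, e2 = _hemo_rhs(
                    zm[r], s[r] + half * a1, lf[r] + half * b1,
                    lv[r] + half * c1, lq[r] + half * e1, kap, gam, tr,
                    inv_alpha, e0, one_minus_e0)
                a3, b3, c3, e3 = _hemo_rhs(
                    zm[r], s[r] + half * a2, lf[r] + half * b2,
                    lv[r] + half * c2, lq[r] + half * e2, kap, gam, tr,
                    inv_alpha, e0, one_minus_e0)
                a4, b4, c4, e4 = _hemo_rhs(
                    zn[r], s[r] + dt * a3, lf[r] + dt * b3,
                    lv[r] + dt * c3, lq[r] + dt * e3, kap, gam, tr,
                    inv_alpha, e0, one_minus_e0)
                s[r] += sixth * (a1 + 2 * a2 + 2 * a3 + a4)
                lf[r] += sixth * (b1 + 2 * b2 + 2 * b3 + b4)
                lv[r] += sixth * (c1 + 2 * c2 + 2 * c3 + c4)
                lq[r] += sixth * (e1 + 2 * e2 + 2 * e3 + e4)
            for i in range(nr):
                z[i] = zn[i]
                if np.abs(z[i]) > 50.0:
                    ok = False
            for r in range(nr):
                # flow/volume/dHb floor: sustained deep inhibition drives
                # blood flow towards zero, where the log-states have no
                # lower fixed point; saturate instead of diverging
                if lf[r] < -4.0:
                    lf[r] = -4.0
                if lv[r] < -4.0:
                    lv[r] = -4.0
                if lq[r] < -4.0:
                    lq[r] = -4.0
                if (lf[r] > 8.0 or lv[r] > 8.0 or lq[r] > 8.0
                        or np.abs(s[r]) > 50.0):
                    ok = False
            if not ok:
                status[p] = 1
                break
            if (t + 1) % bins_per_scan == 0:
                for r in range(nr):
                    v = np.exp(lv[r])
                    qd = np.exp(lq[r])
                    bold_out[p, scan, r] = 100.0 * v0 * (
                        k1c * (1.0 - qd) + k2c * (1.0 - qd / v)
                        + k3c * (1.0 - v)
                    )
                scan += 1
                if scan >= n_scans:
                    break
        if status[p] == 0 and not np.all(np.isfinite(bold_out[p])):
            status[p] = 1
    return status


def integrate_batch(
    a_eff: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    kappa: np.ndarray,
    tau: np.ndarray,
    regressors: RegressorSet,
    n_scans: int,
    hemo: HemodynamicParameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many parameter vectors at once.

    Parameters are already in effective form (``a_eff`` includes the
    negative exponential diagonal).  ``kappa`` and ``tau`` are per-batch,
    per-region haemodynamic decay and transit values; the remaining
    haemodynamic constants come from ``hemo`` (defaults if None).

    Returns ``(bold, status)`` with ``bold`` of shape (P, n_scans, 6) and
    ``status`` 0 where the integration stayed bounded.
    """
    hemo = hemo or HemodynamicParameters()
    patterns, pat_idx = _input_patterns(regressors)
    n_bins_needed = n_scans * regressors.bins_per_scan
    if pat_idx.shape[0] < n_bins_needed:
        raise ValueError("regressors do not cover the requested scan window")
    pat_idx = pat_idx[:n_bins_needed]
    e_half, d_half = _build_propagators(a_eff, b, c, patterns, regressors.dt / 2.0)
    p = a_eff.shape[0]
    bold = np.zeros((p, n_scans, N_REGIONS))
    gamma = np.broadcast_to(hemo.feedback, (p, N_REGIONS)).copy()
    status = _simulate_kernel(
        e_half, d_half, pat_idx,
        np.ascontiguousarray(kappa, dtype=np.float64),
        gamma,
        np.ascontiguousarray(tau, dtype=np.float64),
        float(hemo.stiffness), float(hemo.extraction), float(hemo.venous_volume),
        regressors.dt, regressors.bins_per_scan, n_scans, bold,
    )
    return bold, status


def integrate(
    spec: ModelSpec,
    params: NeuralParameters,
    hemo: HemodynamicParameters | None = None,
    regressors: RegressorSet | None = None,
    n_scans: int | None = None,
    return_states: bool = False,
) -> SimulationOutput:
    """Forward-simulate one parameter set on the scan grid.

    BOLD is sampled once per TR (state at the end of each scan).  Unstable
    dynamics (neural magnitude beyond 1e6) abort with a diagnostic.
    """
    if regressors is None:
        raise ValueError("regressors are required")
    hemo = hemo or HemodynamicParameters()
    params.check_masks(spec)
    n_scans = n_scans or regressors.n_scans

    a_eff = params.a_eff()[None]
    bold, status = integrate_batch(
        a_eff,
        params.b[None],
        params.c[None],
        hemo.signal_decay[None],
        hemo.transit[None],
        regressors,
        n_scans,
        hemo=hemo,
    )
    if status[0] != 0:
        raise RuntimeError(
            "dynamics diverged (neural magnitude beyond 50 or haemodynamic "
            "log-state beyond 8); the effective coupling matrix is unstable "
            "or unphysiologically slow for these parameters"
        )
    out = SimulationOutput(bold=bold[0], tr=regressors.tr)
    if return_states:
        traj = _neural_trajectory(params, regressors, n_scans)
        out.neural = traj
        out.times = regressors.times[: traj.shape[0]]
    return out


def _neural_trajectory(
    params: NeuralParameters, regressors: RegressorSet, n_scans: int
) -> np.ndarray:
    """Microtime neural states (start-of-bin), via the same propagators."""
    patterns, pat_idx = _input_patterns(regressors)
    n_bins = n_scans * regressors.bins_per_scan
    pat_idx = pat_idx[:n_bins]
    e_half, d_half = _build_propagators(
        params.a_eff()[None], params.b[None], params.c[None], patterns,
        regressors.dt / 2.0,
    )
    z = np.zeros(N_REGIONS)
    traj = np.zeros((n_bins, N_REGIONS))
    for t in range(n_bins):
        traj[t] = z
        q = pat_idx[t]
        z = e_half[0, q] @ (e_half[0, q] @ z + d_half[0, q]) + d_half[0, q]
    return traj


#: Default microtime step: TR 1.45 s at 16 bins per scan.
DEFAULT_DT: float = 1.45 / 16


def bold_forward(
    neural: np.ndarray,
    hemo: HemodynamicParameters | None = None,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Haemodynamic cascade applied to a given neural trajectory.

    ``neural`` is (n_steps, 6) on the microtime grid; returns BOLD percent
    signal change of the same shape, evaluated after each Euler step.
    Zero neural input yields identically zero output (resting steady
    state).
    """
    hemo = hemo or HemodynamicParameters()
    neural = np.asarray(neural, dtype=float)
    if not np.all(np.isfinite(neural)):
        raise ValueError("neural trajectory must be finite")
    n_steps, nr = neural.shape
    k1, k2, k3 = hemo.bold_k
    kappa, gamma, tau = hemo.signal_decay, hemo.feedback, hemo.transit
    alpha, e0, v0 = hemo.stiffness, hemo.extraction, hemo.venous_volume

    def rhs(state: np.ndarray, z: np.ndarray) -> np.ndarray:
        s, lf, lv, lq = state
        f = np.exp(lf)
        v = np.exp(lv)
        q = np.exp(lq)
        fv = v ** (1.0 / alpha)
        ef = 1.0 - (1.0 - e0) ** (1.0 / f)
        return np.stack([
            z - kappa * s - gamma * (f - 1.0),
            s / f,
            (f - fv) / (tau * v),
            (f * ef / e0 - fv * q / v) / (tau * q),
        ])

    state = np.zeros((4, nr))
    out = np.zeros((n_steps, nr))
    for t in range(n_steps):
        z0 = neural[t]
        z1 = neural[t + 1] if t + 1 < n_steps else z0
        zm = 0.5 * (z0 + z1)
        k1s = rhs(state, z0)
        k2s = rhs(state + 0.5 * dt * k1s, zm)
        k3s = rhs(state + 0.5 * dt * k2s, zm)
        k4s = rhs(state + dt * k3s, z1)
        state = state + dt / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
        state[1:] = np.maximum(state[1:], -4.0)  # flow floor, see kernel
        v = np.exp(state[2])
        q = np.exp(state[3])
        out[t] = 100.0 * v0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
    return out


def add_noise(
    clean: SimulationOutput,
    noise_sd: float | None = None,
    target_snr: float | None = None,
    seed: int = 0,
) -> tuple[SimulationOutput, dict]:
    """Add i.i.d. Gaussian observation noise per region and scan.

    Exactly one of ``noise_sd`` (a single SD in signal units, shared by all
    regions) or ``target_snr`` (per-region SD chosen as that region's
    clean-signal SD divided by the target) must be given; ``noise_sd = 0``
    returns the series unchanged.  The realised SNR per region is recorded
    in the returned metadata.
    """
    if (noise_sd is None) == (target_snr is None):
        raise ValueError("give exactly one of noise_sd or target_snr")
    signal_sd = clean.bold.std(axis=0, ddof=0)
    if target_snr is not None:
        if target_snr <= 0:
            raise ValueError("target SNR must be positive")
        sd = signal_sd / target_snr
    else:
        if noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        sd = np.full(N_REGIONS, float(noise_sd))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.bold.shape) * sd
    noisy = SimulationOutput(bold=clean.bold + noise, tr=clean.tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        realised = np.where(sd > 0, signal_sd / sd, np.inf)
    meta = {
        "noise_sd": sd.tolist(),
        "signal_sd": signal_sd.tolist(),
        "realised_snr": realised.tolist(),
        "seed": int(seed),
    }
    return noisy, meta
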