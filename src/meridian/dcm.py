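"""Bilinear DCM forward model with balloon-Windkessel hemodynamics.

The neural state equation is the classic bilinear form

    dz/dt = (A + sum_j u_j B^j) z + C u

over the six attention-network nodes, with four driving-input streams
(invalid/valid targets of the horizontal and vertical runs).  Each node's
neural activity z drives a vasodilatory signal s, blood inflow f, venous
volume v and deoxyhemoglobin content q; the BOLD signal is the standard
static observation

    y = V0 * (k1 (1 - q) + k2 (1 - q / v) + k3 (1 - v)).

Volume, inflow and deoxyhemoglobin are integrated in log space so they stay
positive.  Integration is fixed-step RK4 on a microtime grid of
``BINS_PER_TR`` bins per TR; driving inputs are one-bin-wide impulses of
unit area placed at target onsets.  A numba-compiled kernel is used when
numba is importable; a pure-numpy path produces identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import BINS_PER_TR, N_INPUTS, NODES, RUNS, stream_index

N_NODES = len(NODES)

try:  # pragma: no cover - exercised implicitly through simulate_bold
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


# --------------------------------------------------------------------------
# Model containers
# --------------------------------------------------------------------------


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel parameters (per node or scalar, SI units).

    kappa : vasodilatory signal decay rate (1/s)
    gamma : flow autoregulation rate (1/s)
    tau   : venous transit time (s)
    alpha : vessel stiffness (Grubb) exponent
    rho   : resting oxygen extraction fraction
    v0    : resting venous blood volume fraction
    k1, k2, k3 : observation coefficients; defaults follow the standard
        parameterization k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    v0: float = 0.04
    k1: float | None = None
    k2: float = 2.0
    k3: float | None = None

    def __post_init__(self) -> None:
        if self.k1 is None:
            self.k1 = 7.0 * self.rho
        if self.k3 is None:
            self.k3 = 2.0 * self.rho - 0.2
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "v0"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"hemodynamic parameter {name!r} must be positive")

    def as_arrays(self, n_nodes: int = N_NODES) -> tuple[np.ndarray, ...]:
        """Broadcast (kappa, gamma, tau, alpha, rho) to per-node arrays."""
        return tuple(
            np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n_nodes,)).copy()
            for name in ("kappa", "gamma", "tau", "alpha", "rho")
        )


@dataclass
class DCMModel:
    """A bilinear DCM over the six attention-network nodes.

    a : (6, 6) fixed coupling in Hz (row = target node).
    b : (4, 6, 6) input-specific modulation; streams 2 and 4 (valid trials)
        are structurally zero, so only b[0] (invalid-horizontal) and b[2]
        (invalid-vertical) may carry entries.
    c : (6, 4) driving-input weights.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.a.shape != (N_NODES, N_NODES):
            raise ValueError(f"A must be {N_NODES}x{N_NODES}, got {self.a.shape}")
        if self.b.shape != (N_INPUTS, N_NODES, N_NODES):
            raise ValueError(f"B must be {N_INPUTS}x{N_NODES}x{N_NODES}, got {self.b.shape}")
        if self.c.shape != (N_NODES, N_INPUTS):
            raise ValueError(f"C must be {N_NODES}x{N_INPUTS}, got {self.c.shape}")
        for j in (1, 3):
            if np.any(self.b[j] != 0.0):
                raise ValueError(
                    f"B^{j + 1} modulates valid trials and must be structurally zero"
                )

    # -- stability ---------------------------------------------------------

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the fixed coupling A (the u = 0 Jacobian)."""
        return np.linalg.eigvals(self.a)

    def assert_stable(self) -> None:
        ev = self.eigenvalues()
        worst = ev[np.argmax(ev.real)]
        if worst.real >= 0:
            raise ValueError(
                f"unstable A matrix: eigenvalue {worst:.4g} has non-negative real part"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        hemo = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self.hemo).items()
        }
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "hemo": hemo,
            "nodes": list(NODES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMModel":
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            c=np.asarray(d["c"], dtype=float),
            hemo=HemodynamicParams(**d.get("hemo", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DCMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class InputSet:
    """Driving-input impulse trains on the microtime grid of both runs.

    u : (T, 4) array over the concatenated two-run grid; nonzero entries are
        one-bin impulses of height ``1 / dt`` (unit area).
    run_slices : (start, stop) bin ranges of each run; integration restarts
        from rest at each run start.
    """

    u: np.ndarray
    dt: float
    tr: float
    bins_per_tr: int
    run_slices: tuple[tuple[int, int], ...]
    volumes_per_run: tuple[int, ...]

    def copy(self) -> "InputSet":
        return InputSet(
            u=self.u.copy(),
            dt=self.dt,
            tr=self.tr,
            bins_per_tr=self.bins_per_tr,
            run_slices=self.run_slices,
            volumes_per_run=self.volumes_per_run,
        )

    @property
    def n_impulses(self) -> int:
        return int(np.count_nonzero(self.u))

    def impulse_table(self) -> np.ndarray:
        """(n_impulses, 2) array of (bin, stream) pairs, sorted by bin."""
        bins, streams = np.nonzero(self.u)
        order = np.argsort(bins, kind="stable")
        return np.stack([bins[order], streams[order]], axis=1)


def build_inputs(
    events,
    tr: float,
    volumes_per_run: Sequence[int],
    bins_per_tr: int = BINS_PER_TR,
    run_order: Sequence[str] = RUNS,
) -> InputSet:
    """Build the four impulse streams from a two-run event table.

    ``events`` must carry columns ``run``, ``cueing`` and ``onset`` (target
    onset in seconds from the start of that run).  Stream assignment follows
    the u1..u4 convention of :data:`meridian.constants.INPUT_STREAMS`.
    """
    dt = tr / bins_per_tr
    volumes_per_run = tuple(int(v) for v in volumes_per_run)
    run_lengths = [v * bins_per_tr for v in volumes_per_run]
    total = int(np.sum(run_lengths))
    u = np.zeros((total, N_INPUTS))
    starts = np.concatenate([[0], np.cumsum(run_lengths)])
    run_slices = tuple(
        (int(starts[i]), int(starts[i + 1])) for i in range(len(volumes_per_run))
    )
    for i, run in enumerate(run_order):
        sub = events[events["run"] == run]
        if len(sub) == 0:
            continue
        bins = np.rint(sub["onset"].to_numpy() / dt).astype(int)
        bad = bins >= run_lengths[i]
        if np.any(bad):
            raise ValueError(
                f"target onsets beyond the end of the {run} run: "
                f"{sub['onset'].to_numpy()[bad]}"
            )
        streams = [stream_index(c, run) for c in sub["cueing"]]
        u[starts[i] + bins, streams] = 1.0 / dt
    return InputSet(
        u=u,
        dt=dt,
        tr=tr,
        bins_per_tr=bins_per_tr,
        run_slices=run_slices,
        volumes_per_run=volumes_per_run,
    )


# --------------------------------------------------------------------------
# Neural dynamics
# --------------------------------------------------------------------------


def neural_derivative(z: np.ndarray, u: np.ndarray, model: DCMModel) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B^j) z + C u."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (N_NODES,):
        raise ValueError(f"z must have shape ({N_NODES},), got {z.shape}")
    if u.shape != (N_INPUTS,):
        raise ValueError(f"u must have shape ({N_INPUTS},), got {u.shape}")
    a_eff = model.a + np.tensordot(u, model.b, axes=(0, 0))
    return a_eff @ z + model.c @ u


def integrate_neural(model: DCMModel, inputs: InputSet) -> np.ndarray:
    """RK4 integration of the neural states alone on the microtime grid.

    Returns the (T, 6) trajectory of states at each bin start; the state is
    reset to zero at the start of each run.  Inputs are treated as constant
    within each bin.
    """
    model.assert_stable()
    u = inputs.u
    dt = inputs.dt
    traj = np.zeros((u.shape[0], N_NODES))
    b_active = [j for j in range(N_INPUTS) if np.any(model.b[j])]

    def deriv(z, ut):
        a_eff = model.a
        if b_active and np.any(ut):
            a_eff = a_eff + np.tensordot(ut, model.b, axes=(0, 0))
        return a_eff @ z + model.c @ ut

    for start, stop in inputs.run_slices:
        z = np.zeros(N_NODES)
        for t in range(start, stop):
            traj[t] = z
            ut = u[t]
            k1 = deriv(z, ut)
            k2 = deriv(z + 0.5 * dt * k1, ut)
            k3 = deriv(z + 0.5 * dt * k2, ut)
            k4 = deriv(z + dt * k3, ut)
            z = z + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return traj


def hemodynamic_observe(
    z_traj: np.ndarray, params: HemodynamicParams, dt: float
) -> np.ndarray:
    """Propagate a neural trajectory through the balloon model.

    The neural drive is taken as constant within each bin (zero-order hold).
    Returns the (T, n) BOLD signal at bin starts.
    """
    z_traj = np.asarray(z_traj, dtype=float)
    T, n = z_traj.shape
    kappa, gamma, tau, alpha, rho = params.as_arrays(n)
    v0, k1c, k2c, k3c = params.v0, params.k1, params.k2, params.k3
    # states: s, log f, log v, log q
    y = np.zeros((4, n))
    bold = np.zeros((T, n))

    def deriv(y, z):
        s, lf, lv, lq = y
        f, v, q = np.exp(lf), np.exp(lv), np.exp(lq)
        fv = v ** (1.0 / alpha)
        e_frac = 1.0 - (1.0 - rho) ** (1.0 / f)
        ds = z - kappa * s - gamma * (f - 1.0)
        dlf = s / f
        dlv = (f - fv) / (tau * v)
        dlq = (f * e_frac / rho - fv * q / v) / (tau * q)
        return np.stack([ds, dlf, dlv, dlq])

    for t in range(T):
        v, q = np.exp(y[2]), np.exp(y[3])
        bold[t] = v0 * (k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v))
        z = z_traj[t]
        k1 = deriv(y, z)
        k2 = deriv(y + 0.5 * dt * k1, z)
        k3 = deriv(y + 0.5 * dt * k2, z)
        k4 = deriv(y + dt * k3, z)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return bold


# --------------------------------------------------------------------------
# Joint (neural + hemodynamic) batched integrator
# --------------------------------------------------------------------------

# State layout per batch member: (5, n) rows = z, s, log f, log v, log q.


def _rk4_numpy(A, B, C, u, kappa, gamma, tau, alpha, rho, v0, k1c, k2c, k3c, dt, sample_bins):
    nb = A.shape[0]
    T = u.shape[0]
    nu = u.shape[2]
    n = A.shape[1]
    inv_alpha = 1.0 / alpha  # (nb, n)
    one_m_rho = 1.0 - rho

    def deriv(y, ut):
        # y: (nb, 5, n); ut: (4, nu)
        z = y[:, 0]
        s = y[:, 1]
        f = np.exp(y[:, 2])
        v = np.exp(y[:, 3])
        q = np.exp(y[:, 4])
        if nu == 1:
            dz = np.einsum("bij,bj->bi", A, z) + C @ ut[:, 0]
            for j in range(4):
                if ut[j, 0] != 0.0:
                    dz += ut[j, 0] * np.einsum("bij,bj->bi", B[:, j], z)
        else:
            dz = np.einsum("bij,bj->bi", A, z) + np.einsum("bij,jb->bi", C, ut)
            for j in range(4):
                if np.any(ut[j]):
                    dz += ut[j][:, None] * np.einsum("bij,bj->bi", B[:, j], z)
        fv = v**inv_alpha
        e_frac = 1.0 - one_m_rho ** (1.0 / f)
        ds = z - kappa * s - gamma * (f - 1.0)
        dlf = s / f
        dlv = (f - fv) / (tau * v)
        dlq = (f * e_frac / rho - fv * q / v) / (tau * q)
        return np.stack([dz, ds, dlf, dlv, dlq], axis=1)

    y = np.zeros((nb, 5, n))
    out = np.zeros((nb, len(sample_bins), n))
    sample_map = {int(b): i for i, b in enumerate(sample_bins)}
    for t in range(T):
        if t in sample_map:
            v = np.exp(y[:, 3])
            q = np.exp(y[:, 4])
            out[:, sample_map[t]] = v0 * (
                k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v)
            )
        ut = u[t]
        k1 = deriv(y, ut)
        k2 = deriv(y + 0.5 * dt * k1, ut)
        k3 = deriv(y + 0.5 * dt * k2, ut)
        k4 = deriv(y + dt * k3, ut)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _deriv_jit(y, ut, A, B, C, kappa, gamma, tau, alpha, rho, out):  # pragma: no cover
        nb, _, n = y.shape
        nu = ut.shape[1]
        for b in range(nb):
            iu = b if nu > 1 else 0
            u_active = (
                ut[0, iu] != 0.0 or ut[1, iu] != 0.0 or ut[2, iu] != 0.0 or ut[3, iu] != 0.0
            )
            for i in range(n):
                z_i = 0.0
                if u_active:
                    for j in range(n):
                        aij = A[b, i, j]
                        for m in range(4):
                            if ut[m, iu] != 0.0:
                                aij += ut[m, iu] * B[b, m, i, j]
                        z_i += aij * y[b, 0, j]
                    for m in range(4):
                        z_i += C[b, i, m] * ut[m, iu]
                else:
                    for j in range(n):
                        z_i += A[b, i, j] * y[b, 0, j]
                z = y[b, 0, i]
                s = y[b, 1, i]
                f = np.exp(y[b, 2, i])
                v = np.exp(y[b, 3, i])
                q = np.exp(y[b, 4, i])
                fv = v ** (1.0 / alpha[b, i])
                e_frac = 1.0 - (1.0 - rho[b, i]) ** (1.0 / f)
                out[b, 0, i] = z_i
                out[b, 1, i] = z - kappa[b, i] * s - gamma[b, i] * (f - 1.0)
                out[b, 2, i] = s / f
                out[b, 3, i] = (f - fv) / (tau[b, i] * v)
                out[b, 4, i] = (
                    f * e_frac / rho[b, i] - fv * q / v
                ) / (tau[b, i] * q)

    @numba.njit(cache=True, fastmath=False)
    def _rk4_jit(
        A, B, C, u, kappa, gamma, tau, alpha, rho, v0, k1c, k2c, k3c, dt, sample_bins
    ):  # pragma: no cover
        nb = A.shape[0]
        n = A.shape[1]
        T = u.shape[0]
        ns = sample_bins.shape[0]
        y = np.zeros((nb, 5, n))
        out = np.zeros((nb, ns, n))
        k1 = np.zeros((nb, 5, n))
        k2 = np.zeros((nb, 5, n))
        k3 = np.zeros((nb, 5, n))
        k4 = np.zeros((nb, 5, n))
        tmp = np.zeros((nb, 5, n))
        si = 0
        for t in range(T):
            if si < ns and t == sample_bins[si]:
                for b in range(nb):
                    for i in range(n):
                        v = np.exp(y[b, 3, i])
                        q = np.exp(y[b, 4, i])
                        out[b, si, i] = v0 * (
                            k1c * (1.0 - q) + k2c * (1.0 - q / v) + k3c * (1.0 - v)
                        )
                si += 1
            ut = u[t]
            _deriv_jit(y, ut, A, B, C, kappa, gamma, tau, alpha, rho, k1)
            for b in range(nb):
                for r in range(5):
                    for i in range(n):
                        tmp[b, r, i] = y[b, r, i] + 0.5 * dt * k1[b, r, i]
            _deriv_jit(tmp, ut, A, B, C, kappa, gamma, tau, alpha, rho, k2)
            for b in range(nb):
                for r in range(5):
                    for i in range(n):
                        tmp[b, r, i] = y[b, r, i] + 0.5 * dt * k2[b, r, i]
            _deriv_jit(tmp, ut, A, B, C, kappa, gamma, tau, alpha, rho, k3)
            for b in range(nb):
                for r in range(5):
                    for i in range(n):
                        tmp[b, r, i] = y[b, r, i] + dt * k3[b, r, i]
            _deriv_jit(tmp, ut, A, B, C, kappa, gamma, tau, alpha, rho, k4)
            for b in range(nb):
                for r in range(5):
                    for i in range(n):
                        y[b, r, i] += (
                            dt
                            / 6.0
                            * (
                                k1[b, r, i]
                                + 2.0 * k2[b, r, i]
                                + 2.0 * k3[b, r, i]
                                + k4[b, r, i]
                            )
                        )
        return out


def simulate_bold_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    hemo_arrays: tuple[np.ndarray, ...],
    inputs: InputSet,
    sampling_offset: int = 18,
    hemo_obs: tuple[float, float, float, float] | None = None,
    u_batch: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate BOLD for a batch of models (or a batch of input streams).

    A : (nb, 6, 6); B : (nb, 4, 6, 6); C : (nb, 6, 4).
    hemo_arrays : (kappa, gamma, tau, alpha, rho), each (nb, 6).
    u_batch : optional (T, 4, nb) per-batch inputs; defaults to the shared
        streams in ``inputs``.
    Returns BOLD of shape (nb, total_volumes, 6), with the run time series
    concatenated along the volume axis.
    """
    nb = A.shape[0]
    if not (0 <= sampling_offset < inputs.bins_per_tr):
        raise ValueError("sampling_offset must lie within one TR")
    kappa, gamma, tau, alpha, rho = (np.ascontiguousarray(h, dtype=float) for h in hemo_arrays)
    v0, k1c, k2c, k3c = hemo_obs if hemo_obs is not None else (
        HemodynamicParams().v0,
        HemodynamicParams().k1,
        HemodynamicParams().k2,
        HemodynamicParams().k3,
    )
    outs = []
    for (start, stop), nvol in zip(inputs.run_slices, inputs.volumes_per_run):
        if u_batch is not None:
            useg = np.ascontiguousarray(u_batch[start:stop])
        else:
            useg = np.ascontiguousarray(inputs.u[start:stop, :, None])
        sample_bins = (
            np.arange(nvol, dtype=np.int64) * inputs.bins_per_tr + sampling_offset
        )
        args = (
            np.ascontiguousarray(A, dtype=float),
            np.ascontiguousarray(B, dtype=float),
            np.ascontiguousarray(C, dtype=float),
            useg,
            kappa,
            gamma,
            tau,
            alpha,
            rho,
            float(v0),
            float(k1c),
            float(k2c),
            float(k3c),
            float(inputs.dt),
            sample_bins,
        )
        if _HAVE_NUMBA:
            outs.append(_rk4_jit(*args))
        else:
            outs.append(_rk4_numpy(*args))
    return np.concatenate(outs, axis=1)


def simulate_bold(
    model: DCMModel,
    inputs: InputSet,
    sampling_offset: int = 18,
) -> np.ndarray:
    """Simulate the noiseless BOLD signal of one model.

    Returns a (total_volumes, 6) array on the TR grid, both runs
    concatenated; each run starts from hemodynamic rest.
    """
    model.assert_stable()
    kappa, gamma, tau, alpha, rho = model.hemo.as_arrays()
    hemo_arrays = tuple(h[None, :] for h in (kappa, gamma, tau, alpha, rho))
    out = simulate_bold_batch(
        model.a[None],
        model.b[None],
        model.c[None],
        hemo_arrays,
        inputs,
        sampling_offset=sampling_offset,
        hemo_obs=(model.hemo.v0, model.hemo.k1, model.hemo.k2, model.hemo.k3),
    )
    return out[0]
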