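"""Forward model: bilinear neural dynamics, balloon hemodynamics, BOLD output.

Neural states ``z`` (one per region) evolve under the bilinear state equation

    dz/dt = (A_eff + u2 * B) z + C u

where ``A_eff`` is the intrinsic coupling matrix with a fixed inhibitory
self-decay ``-sigma_self`` on its diagonal, ``B`` is the contextual
modulation of coupling and ``C`` maps the two driving inputs (any-trial
onset ``u1`` and the chosen-vs-specified context ``u2``) into the network.

Each region's neural activity drives a balloon model — vasodilatory signal
``s``, blood inflow ``f``, venous volume ``v`` and deoxyhemoglobin content
``q`` — whose output is the BOLD percent signal change

    y = 100 * V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)),

with k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.  ``f``, ``v`` and ``q`` are
integrated in log space so they stay positive.  Integration is a fixed-step
explicit 4th-order Runge-Kutta scheme on a microtime grid (default 0.1 s)
with inputs held piecewise-constant over each step; a step-halving check is
part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_space import REGIONS, ModelSpec

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class SimulationError(RuntimeError):
    """Raised when the forward integration diverges."""


# --------------------------------------------------------------------------
# designs and inputs
# --------------------------------------------------------------------------

CONDITIONS = ("specified", "chosen", "null")


@dataclass(frozen=True)
class StimulusDesign:
    """Event design: trial onsets, durations and condition labels.

    Null trials are perceptually identical to the interstimulus interval and
    produce no input deflection.
    """

    onsets: np.ndarray  # seconds
    durations: np.ndarray  # seconds
    conditions: tuple[str, ...]
    soa: float = 2.5
    tr: float = 2.0
    n_volumes: int = 150

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if onsets.ndim != 1 or durations.shape != onsets.shape:
            raise ValueError("onsets and durations must be 1-d and equal length")
        if len(self.conditions) != onsets.size:
            raise ValueError("one condition label per trial required")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def total_time(self) -> float:
        return self.n_volumes * self.tr

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "duration_s": self.durations,
                "condition": list(self.conditions),
            }
        )


@dataclass(frozen=True)
class InputSet:
    """Driving inputs sampled on the microtime grid."""

    u1: np.ndarray
    u2: np.ndarray
    dt_micro: float

    @property
    def u(self) -> np.ndarray:
        return np.column_stack([self.u1, self.u2])


def build_design(
    n_per_condition: int,
    soa: float = 2.5,
    seed: int = 0,
    *,
    duration: float = 1.0,
    tr: float = 2.0,
    n_volumes: int | None = None,
) -> StimulusDesign:
    """Randomly intermix equal numbers of specified, chosen and null trials.

    Trials are laid out at a fixed stimulus onset asynchrony; the condition
    order is a seeded permutation.  ``n_volumes`` defaults to the number of
    volumes spanning the whole trial train at the given TR.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    n_trials = 3 * n_per_condition
    rng = np.random.default_rng(seed)
    conditions = np.repeat(np.array(CONDITIONS), n_per_condition)
    rng.shuffle(conditions)
    onsets = np.arange(n_trials) * soa
    if n_volumes is None:
        n_volumes = int(np.ceil(n_trials * soa / tr))
    return StimulusDesign(
        onsets=onsets,
        durations=np.full(n_trials, duration),
        conditions=tuple(conditions),
        soa=soa,
        tr=tr,
        n_volumes=n_volumes,
    )


def build_inputs(
    design: StimulusDesign,
    dt_micro: float = 0.1,
    *,
    center_u2: bool = False,
    u2_span: str = "trial",
) -> InputSet:
    """Box-car driving inputs on the microtime grid.

    ``u1`` is 1 during any non-null trial (the 1-s go cue).  ``u2`` codes
    the chosen-vs-specified context.  The context is a cognitive state
    rather than a transient stimulus, so by default (``u2_span="trial"``)
    it stays on for the whole trial cycle (one SOA) of a chosen trial;
    ``u2_span="cue"`` restricts it to the cue window like ``u1``.  With
    ``center_u2`` chosen trials are coded +1/2 and specified trials -1/2.
    """
    if dt_micro <= 0:
        raise ValueError("dt_micro must be positive")
    ratio = design.tr / dt_micro
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt_micro must divide the TR")
    if u2_span not in ("trial", "cue"):
        raise ValueError("u2_span must be 'trial' or 'cue'")
    n_micro = int(round(design.total_time / dt_micro))
    t = np.arange(n_micro) * dt_micro
    u1 = np.zeros(n_micro)
    u2 = np.zeros(n_micro)
    for onset, dur, cond in zip(design.onsets, design.durations, design.conditions):
        if cond == "null":
            continue
        on = (t >= onset - 1e-12) & (t < onset + dur - 1e-12)
        u1[on] = 1.0
        u2_dur = design.soa if u2_span == "trial" else dur
        on2 = (t >= onset - 1e-12) & (t < onset + u2_dur - 1e-12)
        if cond == "chosen":
            u2[on2] = 0.5 if center_u2 else 1.0
        elif center_u2:
            u2[on2] = -0.5
    return InputSet(u1=u1, u2=u2, dt_micro=dt_micro)


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model parameters (canonical defaults; all configurable)."""

    kappa: float = 0.64  # vasodilatory signal decay, 1/s
    gamma: float = 0.32  # flow autoregulation, 1/s
    tau: float = 2.0  # venous transit time, s
    alpha: float = 0.32  # vessel stiffness exponent
    E0: float = 0.32  # resting oxygen extraction fraction
    V0: float = 0.04  # resting venous volume fraction

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "E0", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1 and 0 < self.E0 < 1):
            raise ValueError("alpha and E0 must lie in (0, 1)")


@dataclass(frozen=True)
class ConnectivityParams:
    """Connectivity rates (Hz) on the support of a model's masks.

    ``A`` holds off-diagonal intrinsic couplings; the effective intrinsic
    matrix has a fixed ``-sigma_self`` self-decay on the diagonal.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    sigma_self: float = 0.5

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if A.shape != (4, 4) or B.shape != (4, 4) or C.shape != (4, 2):
            raise ValueError("A, B must be 4x4 and C 4x2")
        if self.sigma_self <= 0:
            raise ValueError("sigma_self must be positive")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def effective_A(self) -> np.ndarray:
        return self.A - self.sigma_self * np.eye(4)

    def check_masks(self, model: ModelSpec) -> None:
        if np.any(self.A[~model.a_mask.astype(bool)] != 0):
            raise ValueError("A has entries outside the model's a_mask")
        if np.any(self.B[~model.b_mask.astype(bool)] != 0):
            raise ValueError("B has entries outside the model's b_mask")
        if np.any(self.C[~model.c_mask.astype(bool)] != 0):
            raise ValueError("C has entries outside the model's c_mask")


@dataclass(frozen=True)
class RegionTimeSeries:
    """Sampled BOLD signal (percent signal change), one column per region."""

    y: np.ndarray  # (n_volumes, 4)
    tr: float
    regions: tuple[str, ...] = field(default=REGIONS)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape[1] != len(self.regions):
            raise ValueError("y must be (n_volumes, n_regions)")
        if not np.all(np.isfinite(y)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "y", y)

    @property
    def n_volumes(self) -> int:
        return self.y.shape[0]

    def to_frame(self):
        import pandas as pd

        t = np.arange(self.n_volumes) * self.tr
        df = pd.DataFrame(self.y, columns=list(self.regions))
        df.insert(0, "time_s", t)
        return df


def neural_derivative(
    z: np.ndarray, u: np.ndarray, params: ConnectivityParams
) -> np.ndarray:
    """dz/dt = (A_eff + u2 B) z + C u, in Hz."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite state or input")
    A_eff = params.effective_A + u[1] * params.B
    return A_eff @ z + params.C @ u


# --------------------------------------------------------------------------
# integrators
# --------------------------------------------------------------------------

_BOLD_K2 = 2.0


def _deriv_numpy(state, Aeff, Bm, Cm, kappa, gamma, tau, alpha, E0, u1, u2):
    """Time derivative of the stacked state (B, 5, R) for a batch."""
    z, s, lf, lv, lq = (state[:, i, :] for i in range(5))
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    Aeff_u = Aeff + u2 * Bm
    dz = np.einsum("bij,bj->bi", Aeff_u, z) + Cm[:, :, 0] * u1 + Cm[:, :, 1] * u2
    ds = z - kappa * s - gamma * (f - 1.0)
    dlf = s / f
    vinva = v ** (1.0 / alpha)
    dlv = (f - vinva) / (tau * v)
    E_f = 1.0 - (1.0 - E0) ** (1.0 / f)
    dlq = (f * E_f / (E0 * q) - vinva / v) / tau
    return np.stack([dz, ds, dlf, dlv, dlq], axis=1)


def _integrate_numpy(Aeff, Bm, Cm, kappa, gamma, tau, alpha, E0, V0, u, dt, sample_idx):
    """Reference RK4 integrator, vectorised over a batch of parameter sets."""
    nb = Aeff.shape[0]
    n_micro = u.shape[0]
    state = np.zeros((nb, 5, 4))
    kappa = kappa[:, None]
    tau = tau[:, None]
    y = np.empty((nb, sample_idx.size, 4))
    sample_map = {int(ix): k for k, ix in enumerate(sample_idx)}
    k1c = 7.0 * E0
    k3c = 2.0 * E0 - 0.2

    def bold(st):
        v = np.exp(st[:, 3, :])
        q = np.exp(st[:, 4, :])
        return 100.0 * V0 * (k1c * (1.0 - q) + _BOLD_K2 * (1.0 - q / v) + k3c * (1.0 - v))

    if 0 in sample_map:
        y[:, sample_map[0], :] = bold(state)
    for n in range(n_micro):
        u1 = u[n, 0]
        u2 = u[n, 1]
        args = (Aeff, Bm, Cm, kappa, gamma, tau, alpha, E0, u1, u2)
        k1 = _deriv_numpy(state, *args)
        k2 = _deriv_numpy(state + 0.5 * dt * k1, *args)
        k3 = _deriv_numpy(state + 0.5 * dt * k2, *args)
        k4 = _deriv_numpy(state + dt * k3, *args)
        state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (n + 1) in sample_map:
            y[:, sample_map[n + 1], :] = bold(state)
    return y


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _deriv_nb(state, Aeff, Bm, Cm, kappa, gamma, tau, alpha, E0, u1, u2, out):
        # state, out: (5, 4) for one batch element
        for i in range(4):
            acc = Cm[i, 0] * u1 + Cm[i, 1] * u2
            for j in range(4):
                acc += (Aeff[i, j] + u2 * Bm[i, j]) * state[0, j]
            out[0, i] = acc
        for i in range(4):
            f = np.exp(state[2, i])
            v = np.exp(state[3, i])
            q = np.exp(state[4, i])
            out[1, i] = state[0, i] - kappa * state[1, i] - gamma * (f - 1.0)
            out[2, i] = state[1, i] / f
            vinva = v ** (1.0 / alpha)
            out[3, i] = (f - vinva) / (tau * v)
            E_f = 1.0 - (1.0 - E0) ** (1.0 / f)
            out[4, i] = (f * E_f / (E0 * q) - vinva / v) / tau

    @numba.njit(cache=False)
    def _integrate_nb(Aeff, Bm, Cm, kappa, gamma, tau, alpha, E0, V0, u, dt, sample_idx):
        nb_ = Aeff.shape[0]
        n_micro = u.shape[0]
        n_samp = sample_idx.size
        y = np.empty((nb_, n_samp, 4))
        k1c = 7.0 * E0
        k3c = 2.0 * E0 - 0.2
        for b in range(nb_):
            state = np.zeros((5, 4))
            tmp = np.empty((5, 4))
            k1 = np.empty((5, 4))
            k2 = np.empty((5, 4))
            k3 = np.empty((5, 4))
            k4 = np.empty((5, 4))
            ptr = 0
            if ptr < n_samp and sample_idx[ptr] == 0:
                for i in range(4):
                    y[b, ptr, i] = 0.0
                ptr += 1
            for n in range(n_micro):
                u1 = u[n, 0]
                u2 = u[n, 1]
                _deriv_nb(state, Aeff[b], Bm[b], Cm[b], kappa[b], gamma, tau[b], alpha, E0, u1, u2, k1)
                for i in range(5):
                    for j in range(4):
                        tmp[i, j] = state[i, j] + 0.5 * dt * k1[i, j]
                _deriv_nb(tmp, Aeff[b], Bm[b], Cm[b], kappa[b], gamma, tau[b], alpha, E0, u1, u2, k2)
                for i in range(5):
                    for j in range(4):
                        tmp[i, j] = state[i, j] + 0.5 * dt * k2[i, j]
                _deriv_nb(tmp, Aeff[b], Bm[b], Cm[b], kappa[b], gamma, tau[b], alpha, E0, u1, u2, k3)
                for i in range(5):
                    for j in range(4):
                        tmp[i, j] = state[i, j] + dt * k3[i, j]
                _deriv_nb(tmp, Aeff[b], Bm[b], Cm[b], kappa[b], gamma, tau[b], alpha, E0, u1, u2, k4)
                for i in range(5):
                    for j in range(4):
                        state[i, j] += (dt / 6.0) * (
                            k1[i, j] + 2.0 * k2[i, j] + 2.0 * k3[i, j] + k4[i, j]
                        )
                if ptr < n_samp and sample_idx[ptr] == n + 1:
                    for i in range(4):
                        v = np.exp(state[3, i])
                        q = np.exp(state[4, i])
                        y[b, ptr, i] = 100.0 * V0 * (
                            k1c * (1.0 - q) + _BOLD_K2 * (1.0 - q / v) + k3c * (1.0 - v)
                        )
                    ptr += 1
        return y


def integrate_bold(
    Aeff: np.ndarray,
    Bm: np.ndarray,
    Cm: np.ndarray,
    kappa: np.ndarray,
    tau: np.ndarray,
    u: np.ndarray,
    dt: float,
    sample_idx: np.ndarray,
    hemo: HemoParams,
    *,
    engine: str = "auto",
) -> np.ndarray:
    """Integrate a batch of parameter sets; returns BOLD (batch, T, 4).

    ``Aeff`` must already contain the self-decay on its diagonal.  ``kappa``
    and ``tau`` are per-batch-element values (the other balloon parameters
    are shared).  ``sample_idx`` gives microtime indices at which the BOLD
    observation is read out.
    """
    Aeff = np.ascontiguousarray(Aeff, dtype=float)
    Bm = np.ascontiguousarray(Bm, dtype=float)
    Cm = np.ascontiguousarray(Cm, dtype=float)
    kappa = np.ascontiguousarray(kappa, dtype=float)
    tau = np.ascontiguousarray(tau, dtype=float)
    u = np.ascontiguousarray(u, dtype=float)
    sample_idx = np.ascontiguousarray(sample_idx, dtype=np.int64)
    if engine == "auto":
        engine = "numba" if _HAVE_NUMBA else "numpy"
    try:
        if engine == "numba":
            y = _integrate_nb(
                Aeff, Bm, Cm, kappa, hemo.gamma, tau, hemo.alpha, hemo.E0, hemo.V0,
                u, dt, sample_idx,
            )
        elif engine == "numpy":
            with np.errstate(all="ignore"):
                y = _integrate_numpy(
                    Aeff, Bm, Cm, kappa, hemo.gamma, tau, hemo.alpha, hemo.E0, hemo.V0,
                    u, dt, sample_idx,
                )
        else:
            raise ValueError(f"unknown engine {engine!r}")
    except (ZeroDivisionError, FloatingPointError, OverflowError) as err:
        raise SimulationError("forward integration diverged (state overflow)") from err
    if not np.all(np.isfinite(y)):
        bad = np.where(~np.all(np.isfinite(y), axis=(1, 2)))[0]
        raise SimulationError(
            f"forward integration diverged for batch elements {bad.tolist()}"
        )
    return y


def sample_indices(design: StimulusDesign, dt_micro: float) -> np.ndarray:
    """Microtime indices of volume acquisitions (one per TR, starting at 0)."""
    per_tr = int(round(design.tr / dt_micro))
    return np.arange(design.n_volumes, dtype=np.int64) * per_tr


def simulate_bold(
    model: ModelSpec,
    params: ConnectivityParams,
    design: StimulusDesign,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    *,
    hemo: HemoParams = HemoParams(),
    dt_micro: float = 0.1,
    center_u2: bool = False,
    u2_span: str = "trial",
    engine: str = "auto",
) -> RegionTimeSeries:
    """Simulate one session's noisy BOLD time series for a model.

    Deterministic given the seed; with ``noise_sd = 0`` the output is the
    noiseless model prediction.
    """
    params.check_masks(model)
    inputs = build_inputs(design, dt_micro, center_u2=center_u2, u2_span=u2_span)
    idx = sample_indices(design, dt_micro)
    try:
        y = integrate_bold(
            params.effective_A[None],
            params.B[None],
            params.C[None],
            np.array([hemo.kappa]),
            np.array([hemo.tau]),
            inputs.u,
            dt_micro,
            idx,
            hemo,
            engine=engine,
        )[0]
    except SimulationError as err:
        raise SimulationError(
            f"unstable dynamics for model {model.model_id}: "
            f"A={params.A.tolist()}, B={params.B.tolist()}, C={params.C.tolist()}"
        ) from err
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return RegionTimeSeries(y=y, tr=design.tr)


def predicted_bold(
    model: ModelSpec,
    params: ConnectivityParams,
    design: StimulusDesign,
    **kwargs,
) -> RegionTimeSeries:
    """Noiseless model prediction (convenience wrapper)."""
    return simulate_bold(model, params, design, noise_sd=0.0, **kwargs)
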