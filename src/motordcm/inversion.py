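"""Variational-Laplace model inversion for one (session, model) pair.

The free parameters are the masked A/B/C connectivity rates plus log-scaling
factors on the balloon parameters kappa and tau; observation noise is
handled by one log-precision hyperparameter per region, updated by an EM
step.  The posterior over parameters is a Gaussian found by Gauss-Newton
ascent on the negative free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL(q(theta) || p(theta)),

a lower bound on the log model evidence.  ``accuracy`` is the expected
log-likelihood under the Gaussian posterior q and ``complexity`` is the
Kullback-Leibler divergence of the posterior from the prior, so F penalises
parameters according to both their prior and posterior dependencies.

Gradients of the forward model are taken by central finite differences of
the integrator, vectorised over a single batched call.  A constant and a
linear drift are projected out of both data and predictions before the
likelihood is evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .generative import (
    HemoParams,
    RegionTimeSeries,
    StimulusDesign,
    build_inputs,
    integrate_bold,
    sample_indices,
)
from .model_space import ModelSpec

__all__ = [
    "Priors",
    "Posterior",
    "ModelEvidence",
    "InversionOptions",
    "param_names",
    "build_priors",
    "make_forward",
    "variational_laplace",
    "invert",
    "free_energy_curve",
    "posterior_correlation",
]


@dataclass(frozen=True)
class Priors:
    """Gaussian prior over the free-parameter vector."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        p = mean.size
        if cov.shape != (p, p):
            raise ValueError("prior covariance shape mismatch")
        if len(self.names) != p:
            raise ValueError("one name per parameter required")
        # positive definiteness
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("prior covariance must be positive definite") from err
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def n_params(self) -> int:
        return self.mean.size


@dataclass
class Posterior:
    """Gaussian posterior: means, covariance, convergence diagnostics."""

    names: tuple[str, ...]
    Ep: np.ndarray
    Cp: np.ndarray
    n_iter: int
    converged: bool
    F_trace: np.ndarray
    log_precision: np.ndarray

    @property
    def Ep_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.Ep)}


@dataclass(frozen=True)
class ModelEvidence:
    """Free-energy bound and its accuracy/complexity decomposition (nats)."""

    F: float
    accuracy: float
    complexity: float


@dataclass(frozen=True)
class InversionOptions:
    dt_micro: float = 0.1
    max_iter: int = 64
    tol: float = 1e-2  # nats; stop when an accepted step improves F by less
    fd_step: float = 1e-4
    hemo: HemoParams = field(default_factory=HemoParams)
    sigma_self: float = 0.5
    center_u2: bool = False
    u2_span: str = "trial"
    confounds: str = "linear"  # "linear" (constant + drift) or "none"
    update_noise: bool = True
    init_log_precision: float | None = None
    a_var: float = 1.0 / 16.0
    b_var: float = 1.0 / 16.0
    c_var: float = 1.0 / 32.0
    hemo_var: float = 1.0 / 64.0


HEMO_PARAM_NAMES = ("hemo.log_kappa", "hemo.log_tau")


def param_names(model: ModelSpec) -> tuple[str, ...]:
    """Free-parameter names, in canonical packing order.

    Masked A entries first (row-major over the mask), then B, then C, then
    the hemodynamic log-scalings.  Connection names read source->target.
    """
    names: list[str] = []
    regions = model.regions
    for i, j in zip(*np.nonzero(model.a_mask)):
        names.append(f"A.{regions[j]}->{regions[i]}")
    for i, j in zip(*np.nonzero(model.b_mask)):
        names.append(f"B.{regions[j]}->{regions[i]}")
    for i, j in zip(*np.nonzero(model.c_mask)):
        names.append(f"C.{regions[i]}.u{j + 1}")
    names.extend(HEMO_PARAM_NAMES)
    return tuple(names)


def connectivity_names(model: ModelSpec) -> tuple[str, ...]:
    """The A/B/C subset of :func:`param_names` (no hemodynamic scalings)."""
    return tuple(n for n in param_names(model) if not n.startswith("hemo."))


def build_priors(model: ModelSpec, opts: InversionOptions = InversionOptions()) -> Priors:
    """Zero-mean shrinkage priors over masked connectivity + hemo scalings."""
    names = param_names(model)
    variances = []
    for n in names:
        if n.startswith("A."):
            variances.append(opts.a_var)
        elif n.startswith("B."):
            variances.append(opts.b_var)
        elif n.startswith("C."):
            variances.append(opts.c_var)
        else:
            variances.append(opts.hemo_var)
    v = np.array(variances)
    return Priors(names=names, mean=np.zeros(v.size), cov=np.diag(v))


def unpack_theta(
    model: ModelSpec, theta: np.ndarray, sigma_self: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map a batch of parameter vectors to (A_eff, B, C, hemo_scalings).

    ``theta`` is (batch, P); returns matrices (batch, 4, 4)/(batch, 4, 2)
    and the hemo log-scalings (batch, 2).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    nb = theta.shape[0]
    ai, aj = np.nonzero(model.a_mask)
    bi, bj = np.nonzero(model.b_mask)
    ci, cj = np.nonzero(model.c_mask)
    na, nbil, nc = ai.size, bi.size, ci.size
    if theta.shape[1] != na + nbil + nc + 2:
        raise ValueError("parameter vector length does not match the model")
    A = np.zeros((nb, 4, 4))
    B = np.zeros((nb, 4, 4))
    C = np.zeros((nb, 4, 2))
    A[:, ai, aj] = theta[:, :na]
    B[:, bi, bj] = theta[:, na : na + nbil]
    C[:, ci, cj] = theta[:, na + nbil : na + nbil + nc]
    A[:, np.arange(4), np.arange(4)] = -sigma_self
    return A, B, C, theta[:, -2:]


def make_forward(
    model: ModelSpec,
    design: StimulusDesign,
    opts: InversionOptions = InversionOptions(),
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched forward map theta (B, P) -> predicted BOLD (B, T, 4)."""
    inputs = build_inputs(design, opts.dt_micro, center_u2=opts.center_u2,
                          u2_span=opts.u2_span)
    idx = sample_indices(design, opts.dt_micro)
    u = inputs.u
    hemo = opts.hemo

    def forward(theta: np.ndarray) -> np.ndarray:
        Aeff, B, C, hscale = unpack_theta(model, theta, opts.sigma_self)
        kappa = hemo.kappa * np.exp(hscale[:, 0])
        tau = hemo.tau * np.exp(hscale[:, 1])
        return integrate_bold(Aeff, B, C, kappa, tau, u, opts.dt_micro, idx, hemo)

    return forward


def _confound_projector(n: int, kind: str) -> tuple[np.ndarray | None, int]:
    if kind == "none":
        return None, 0
    if kind == "linear":
        t = np.arange(n, dtype=float)
        X0 = np.column_stack([np.ones(n), t - t.mean()])
        R = np.eye(n) - X0 @ np.linalg.pinv(X0)
        return R, X0.shape[1]
    raise ValueError(f"unknown confound option {kind!r}")


_LAM_MIN, _LAM_MAX = 1e-8, 1e10


def _evaluate(
    forward: Callable,
    mu: np.ndarray,
    y: np.ndarray,
    priors: Priors,
    R: np.ndarray | None,
    n_eff: float,
    lam: np.ndarray,
    fd_step: float,
    update_noise: bool,
) -> dict:
    """Free energy, gradients and curvature at posterior mode ``mu``.

    One batched forward call evaluates the prediction and all central
    finite-difference perturbations together.
    """
    p = mu.size
    n_chan = y.shape[1]
    steps = fd_step * np.ones(p)
    batch = np.vstack([mu[None], mu[None] + np.diag(steps), mu[None] - np.diag(steps)])
    preds = forward(batch)  # (2P+1, T, R)
    g = preds[0]
    J = (preds[1 : 1 + p] - preds[1 + p :]) / (2.0 * steps[:, None, None])
    J = np.moveaxis(J, 0, -1)  # (T, R, P)
    if R is not None:
        g = R @ g
        J = np.einsum("ts,srp->trp", R, J)
    e = y - g  # y already projected by caller
    Pi0 = np.linalg.inv(priors.cov)
    JtJ = np.einsum("trp,trq->rpq", J, J)  # per-channel J'J
    Jte = np.einsum("trp,tr->rp", J, e)
    ete = np.einsum("tr,tr->r", e, e)

    lam = lam.copy()
    for _ in range(16 if update_noise else 1):
        H = Pi0 + np.einsum("r,rpq->pq", lam, JtJ)
        Sigma = np.linalg.inv(H)
        if not update_noise:
            break
        tr_r = np.einsum("rpq,qp->r", JtJ, Sigma)
        lam_new = np.clip(n_eff / (ete + tr_r), _LAM_MIN, _LAM_MAX)
        if np.allclose(lam_new, lam, rtol=1e-6):
            lam = lam_new
            H = Pi0 + np.einsum("r,rpq->pq", lam, JtJ)
            Sigma = np.linalg.inv(H)
            break
        lam = lam_new
    H = Pi0 + np.einsum("r,rpq->pq", lam, JtJ)
    Sigma = np.linalg.inv(H)
    Sigma = 0.5 * (Sigma + Sigma.T)

    tr_r = np.einsum("rpq,qp->r", JtJ, Sigma)
    accuracy = float(
        np.sum(-0.5 * lam * (ete + tr_r) + 0.5 * n_eff * (np.log(lam) - np.log(2 * np.pi)))
    )
    d = mu - priors.mean
    sign0, logdet0 = np.linalg.slogdet(priors.cov)
    sign1, logdet1 = np.linalg.slogdet(Sigma)
    complexity = 0.5 * float(
        d @ Pi0 @ d + np.trace(Pi0 @ Sigma) - p + logdet0 - logdet1
    )
    F = accuracy - complexity
    grad = np.einsum("r,rp->p", lam, Jte) - Pi0 @ d
    return {
        "g": g,
        "e": e,
        "J": J,
        "lam": lam,
        "H": H,
        "Sigma": Sigma,
        "F": F,
        "accuracy": accuracy,
        "complexity": complexity,
        "grad": grad,
    }


def variational_laplace(
    forward: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    priors: Priors,
    *,
    max_iter: int = 64,
    tol: float = 1e-2,
    fd_step: float = 1e-4,
    confounds: str = "none",
    update_noise: bool = True,
    init_log_precision: float | None = None,
) -> tuple[Posterior, ModelEvidence]:
    """Gauss-Newton / EM ascent on the free energy for a generic forward map.

    ``forward`` maps a (batch, P) parameter array to predictions
    (batch, T, R); ``y`` is the (T, R) data.  Levenberg-style damping is
    applied to the curvature and increased by decades on rejected moves.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    T, n_chan = y.shape
    Rproj, n_conf = _confound_projector(T, confounds)
    n_eff = float(T - n_conf)
    y_p = Rproj @ y if Rproj is not None else y

    if init_log_precision is None:
        var0 = np.maximum(y_p.var(axis=0), 1e-12)
        lam = np.clip(1.0 / var0, _LAM_MIN, _LAM_MAX)
    else:
        lam = np.full(n_chan, np.exp(init_log_precision))

    mu = priors.mean.copy()
    state = _evaluate(forward, mu, y_p, priors, Rproj, n_eff, lam, fd_step, update_noise)
    trace = [state["F"]]
    damping = 1e-6
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H = state["H"]
        Hd = H + damping * np.diag(np.diag(H))
        try:
            step = np.linalg.solve(Hd, state["grad"])
        except np.linalg.LinAlgError:
            warnings.warn("singular curvature; regularising", RuntimeWarning)
            Hd = Hd + 1e-6 * np.eye(H.shape[0])
            step = np.linalg.solve(Hd, state["grad"])
        mu_new = mu + step
        try:
            state_new = _evaluate(
                forward, mu_new, y_p, priors, Rproj, n_eff, state["lam"], fd_step, update_noise
            )
        except Exception:
            state_new = None
        if state_new is not None and state_new["F"] >= state["F"] - 1e-9:
            dF = state_new["F"] - state["F"]
            mu = mu_new
            state = state_new
            trace.append(state["F"])
            damping = max(damping / 10.0, 1e-8)
            if abs(dF) < tol:
                converged = True
                break
        else:
            trace.append(state["F"])  # rejected step: F unchanged
            damping *= 10.0
            if damping > 1e8:
                break
    if not converged:
        warnings.warn("inversion did not converge; returning last iterate", RuntimeWarning)

    post = Posterior(
        names=priors.names,
        Ep=mu,
        Cp=state["Sigma"],
        n_iter=n_iter,
        converged=converged,
        F_trace=np.asarray(trace),
        log_precision=np.log(state["lam"]),
    )
    ev = ModelEvidence(
        F=float(state["F"]),
        accuracy=float(state["accuracy"]),
        complexity=float(state["complexity"]),
    )
    return post, ev


def invert(
    model: ModelSpec,
    data: RegionTimeSeries,
    design: StimulusDesign,
    priors: Priors | None = None,
    opts: InversionOptions = InversionOptions(),
) -> tuple[Posterior, ModelEvidence]:
    """Invert one model on one session's region time series."""
    if data.n_volumes != design.n_volumes:
        raise ValueError("data and design disagree on the number of volumes")
    if abs(data.tr - design.tr) > 1e-9:
        raise ValueError("data and design disagree on the TR")
    if priors is None:
        priors = build_priors(model, opts)
    forward = make_forward(model, design, opts)
    return variational_laplace(
        forward,
        data.y,
        priors,
        max_iter=opts.max_iter,
        tol=opts.tol,
        fd_step=opts.fd_step,
        confounds=opts.confounds,
        update_noise=opts.update_noise,
        init_log_precision=opts.init_log_precision,
    )


def free_energy_curve(posterior: Posterior) -> np.ndarray:
    """Per-iteration free-energy values (accepted iterations never decrease)."""
    return np.asarray(posterior.F_trace, dtype=float)


def posterior_correlation(
    Cp: np.ndarray,
    names: Sequence[str] | None = None,
    *,
    subset: str = "connectivity",
) -> np.ndarray:
    """Normalise a posterior covariance to a correlation matrix.

    With parameter ``names`` given, the matrix is first restricted to the
    connectivity (A/B/C) parameters, mirroring the normalised-Cp summaries
    used to assess parameter identifiability.  Zero-variance parameters
    yield NaN entries and a warning.
    """
    Cp = np.asarray(Cp, dtype=float)
    if names is not None:
        names = list(names)
        if len(names) != Cp.shape[0]:
            raise ValueError("one name per row of Cp required")
        if subset == "connectivity":
            keep = [i for i, n in enumerate(names) if not n.startswith("hemo.")]
            Cp = Cp[np.ix_(keep, keep)]
    sd = np.sqrt(np.diag(Cp))
    if np.any(sd == 0):
        warnings.warn("zero posterior variance: undefined correlation entries", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = Cp / np.outer(sd, sd)
    finite = np.isfinite(corr)
    corr[finite] = np.clip(corr[finite], -1.0, 1.0)
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return corr
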