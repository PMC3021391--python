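"""Group-level Bayesian model selection over free-energy evidence tables.

Two complementary procedures:

* fixed effects (FFX): log evidences are summed over sessions for each
  model (the group Bayes factor on the log scale); posterior model
  probabilities follow by softmax under a uniform model prior.  This
  assumes every session's data arose from the same model.
* random effects (RFX): a hierarchical model in which each session's
  generating model is a latent categorical variable whose probabilities
  carry a Dirichlet prior.  Fitted by the standard variational update
  loop; reported as Dirichlet parameters, expected posterior model
  probabilities and exceedance probabilities (the belief that a model is
  more likely than any other), the latter by Monte-Carlo sampling of the
  fitted Dirichlet.

RFX is robust to outlying subjects whose extreme single-subject evidence
would otherwise dominate the summed (FFX) log evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, softmax

__all__ = [
    "EvidenceTable",
    "FfxResult",
    "RfxResult",
    "fixed_effects",
    "bayes_factor",
    "random_effects",
    "rfx_gibbs",
    "selection_report",
]

_META_COLS = ("session_id", "subject_id", "group", "session")


@dataclass
class EvidenceTable:
    """Sessions x models matrix of free-energy log evidences (nats).

    ``meta`` carries one row per session: session_id, subject_id, group
    label (e.g. young / OC / PD) and session label (e.g. A / B / on / off).
    """

    meta: pd.DataFrame
    F: pd.DataFrame  # index aligned with meta, columns = model ids

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.F):
            raise ValueError("meta and F must have the same number of rows")
        missing = [c for c in _META_COLS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta lacks columns: {missing}")
        if self.F.isna().any().any():
            raise ValueError("evidence table has missing cells")

    @property
    def model_ids(self) -> list[str]:
        return list(self.F.columns)

    def subset(
        self,
        models: list[str] | None = None,
        group: str | None = None,
        session: str | None = None,
    ) -> "EvidenceTable":
        keep = pd.Series(True, index=self.meta.index)
        if group is not None:
            keep &= self.meta["group"] == group
        if session is not None:
            keep &= self.meta["session"] == session
        F = self.F.loc[keep]
        if models is not None:
            missing = [m for m in models if m not in F.columns]
            if missing:
                raise KeyError(f"models not in table: {missing}")
            F = F[models]
        return EvidenceTable(meta=self.meta.loc[keep].reset_index(drop=True),
                             F=F.reset_index(drop=True))

    def to_csv(self, path) -> None:
        pd.concat([self.meta[list(_META_COLS)], self.F], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EvidenceTable":
        df = pd.read_csv(path)
        meta = df[list(_META_COLS)]
        F = df.drop(columns=list(_META_COLS))
        return cls(meta=meta, F=F)


@dataclass(frozen=True)
class FfxResult:
    model_ids: tuple[str, ...]
    summed_F: np.ndarray
    delta_F: np.ndarray  # relative to best (best = 0)
    posterior_prob: np.ndarray
    ranking: tuple[str, ...]  # best first

    @property
    def best(self) -> str:
        return self.ranking[0]


@dataclass(frozen=True)
class RfxResult:
    model_ids: tuple[str, ...]
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    exceedance_mc_se: np.ndarray
    n_mc: int
    seed: int
    converged: bool
    n_iter: int

    @property
    def ranking(self) -> tuple[str, ...]:
        order = np.argsort(-self.expected_prob)
        return tuple(self.model_ids[i] for i in order)

    @property
    def best(self) -> str:
        return self.ranking[0]


def fixed_effects(table: EvidenceTable, models: list[str] | None = None) -> FfxResult:
    """Summed log evidence per model and softmax posterior probabilities."""
    sub = table.subset(models=models)
    if sub.F.shape[1] < 2:
        raise ValueError("fixed-effects comparison needs at least two models")
    if len(sub.F) < 1:
        raise ValueError("fixed-effects comparison needs at least one session")
    summed = sub.F.to_numpy().sum(axis=0)
    delta = summed - summed.max()
    prob = softmax(delta)
    order = np.argsort(-summed)
    ids = tuple(sub.model_ids)
    return FfxResult(
        model_ids=ids,
        summed_F=summed,
        delta_F=delta,
        posterior_prob=prob,
        ranking=tuple(ids[i] for i in order),
    )


#: Bayes-factor evidence categories: (lower bound, upper bound, label).
BF_CATEGORIES = (
    (3.0, 20.0, "positive"),
    (20.0, 150.0, "strong"),
    (150.0, np.inf, "very strong"),
)


def bayes_factor(F_a: float, F_b: float) -> tuple[float, str]:
    """Bayes factor of model a over model b and its conventional category.

    BF = exp(F_a - F_b); BF 3-20 is positive, 20-150 strong, >150 very
    strong evidence (log-evidence bands 1.1-3, 3-5, >5).
    """
    if not (np.isfinite(F_a) and np.isfinite(F_b)):
        raise ValueError("log evidences must be finite")
    bf = float(np.exp(F_a - F_b))
    for lo, hi, label in BF_CATEGORIES:
        if lo <= bf < hi:
            return bf, label
    return bf, "none"


def random_effects(
    table: EvidenceTable,
    prior_alpha: float = 1.0,
    n_mc: int = 100_000,
    seed: int = 0,
    models: list[str] | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    per_subject: bool = False,
) -> RfxResult:
    """Hierarchical (random-effects) Bayesian model selection.

    Variational updates: each session's model responsibilities are the
    softmax of its log evidences plus the Dirichlet digamma terms; the
    Dirichlet counts are the prior alpha plus summed responsibilities,
    iterated to convergence.  Exceedance probabilities are estimated from
    ``n_mc`` Monte-Carlo draws of the fitted Dirichlet.

    With ``per_subject`` the rows are first averaged within subject so each
    subject contributes one row regardless of session count.
    """
    if n_mc < 1_000:
        raise ValueError("n_mc must be at least 1000")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    sub = table.subset(models=models)
    F = sub.F.to_numpy()
    if per_subject:
        F = pd.DataFrame(F).groupby(sub.meta["subject_id"].to_numpy()).mean().to_numpy()
    n, k = F.shape
    if n < 2:
        raise ValueError("random-effects comparison needs at least two sessions")
    if k < 2:
        raise ValueError("random-effects comparison needs at least two models")

    alpha0 = np.full(k, float(prior_alpha))
    alpha = alpha0.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))
        g = softmax(logu, axis=1)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=k)
    xp = wins / n_mc
    xp_se = np.sqrt(xp * (1 - xp) / n_mc)
    return RfxResult(
        model_ids=tuple(sub.model_ids),
        alpha=alpha,
        expected_prob=expected,
        exceedance_prob=xp,
        exceedance_mc_se=xp_se,
        n_mc=int(n_mc),
        seed=int(seed),
        converged=converged,
        n_iter=n_iter,
    )


def rfx_gibbs(
    F: np.ndarray,
    prior_alpha: float = 1.0,
    n_samples: int = 20_000,
    burn_in: int = 2_000,
    seed: int = 0,
) -> np.ndarray:
    """Gibbs-sampling estimate of the RFX expected model probabilities.

    Independent reference implementation used to cross-check the
    variational solution: alternately samples model assignments given the
    probability vector and the Dirichlet given the assignment counts.
    Returns the posterior mean of the model probability vector.
    """
    F = np.asarray(F, dtype=float)
    n, k = F.shape
    rng = np.random.default_rng(seed)
    r = np.full(k, 1.0 / k)
    total = np.zeros(k)
    kept = 0
    for it in range(n_samples + burn_in):
        logp = F + np.log(r)
        p = softmax(logp, axis=1)
        cum = np.cumsum(p, axis=1)
        unif = rng.random((n, 1))
        assign = (unif > cum).sum(axis=1)
        counts = np.bincount(assign, minlength=k)
        r = rng.dirichlet(prior_alpha + counts)
        if it >= burn_in:
            total += r
            kept += 1
    return total / kept


def selection_report(ffx: FfxResult, rfx: RfxResult) -> dict:
    """Tabulate FFX and RFX rankings and flag rank disagreements."""
    if tuple(sorted(ffx.model_ids)) != tuple(sorted(rfx.model_ids)):
        raise ValueError("FFX and RFX results cover different model sets")
    if len(ffx.model_ids) == 0:
        raise ValueError("empty model subset")
    flags = []
    for rank, (a, b) in enumerate(zip(ffx.ranking, rfx.ranking), start=1):
        if a != b:
            flags.append(
                {
                    "rank": rank,
                    "ffx": a,
                    "rfx": b,
                }
            )
    return {
        "models": list(ffx.model_ids),
        "ffx": {
            "summed_F": {m: float(v) for m, v in zip(ffx.model_ids, ffx.summed_F)},
            "delta_F": {m: float(v) for m, v in zip(ffx.model_ids, ffx.delta_F)},
            "posterior_prob": {
                m: float(v) for m, v in zip(ffx.model_ids, ffx.posterior_prob)
            },
            "ranking": list(ffx.ranking),
        },
        "rfx": {
            "alpha": {m: float(v) for m, v in zip(rfx.model_ids, rfx.alpha)},
            "expected_prob": {
                m: float(v) for m, v in zip(rfx.model_ids, rfx.expected_prob)
            },
            "exceedance_prob": {
                m: float(v) for m, v in zip(rfx.model_ids, rfx.exceedance_prob)
            },
            "ranking": list(rfx.ranking),
        },
        "agree": not flags,
        "rank_disagreements": flags,
    }
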