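"""Parameter-level reliability battery.

Given per-subject, per-session posterior parameter estimates for a chosen
model, this module provides the statistics used to assess whether
connectivity parameters replicate across sessions:

* cross-session Pearson / Spearman correlations per parameter;
* a chi-squared test of sign preservation across sessions;
* a split-plot repeated-measures ANOVA (group between subjects; session
  and connection within subjects);
* group summaries of normalised posterior covariance (i.e. posterior
  correlation) matrices, with element-wise one-sample t-tests and
  Bonferroni correction, and the Spearman agreement of mean matrices
  between sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParamPanel",
    "SignTestResult",
    "round_half_up",
    "cross_session_correlation",
    "sign_consistency_test",
    "parameter_anova",
    "posterior_corr_group_summary",
    "matrix_session_agreement",
    "b_over_a_ratio",
    "ks_normality",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (so 2.25 -> 2.3 at one decimal)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ParamPanel:
    """Long-format posterior-mean estimates: subject x session x parameter."""

    data: pd.DataFrame  # columns: subject, group, session, parameter, value

    REQUIRED = ("subject", "group", "session", "parameter", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel lacks columns: {missing}")

    @property
    def parameters(self) -> list[str]:
        return sorted(self.data["parameter"].unique())

    @property
    def sessions(self) -> list[str]:
        return sorted(self.data["session"].unique())

    def pivot(self, parameter: str) -> pd.DataFrame:
        """Subjects x sessions table for one parameter."""
        sub = self.data[self.data["parameter"] == parameter]
        if sub.empty:
            raise KeyError(f"parameter {parameter!r} not in panel")
        return sub.pivot_table(index="subject", columns="session", values="value")

    def to_csv(self, path) -> None:
        self.data[list(self.REQUIRED)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParamPanel":
        return cls(pd.read_csv(path))


def cross_session_correlation(
    panel: ParamPanel,
    parameter: str,
    method: str = "pearson",
    sessions: tuple[str, str] | None = None,
) -> tuple[float, float]:
    """Correlation of one parameter's estimates across two sessions.

    Pearson returns (r^2, p); Spearman returns (rho, p).
    """
    wide = panel.pivot(parameter)
    if sessions is None:
        if wide.shape[1] != 2:
            raise ValueError("panel must contain exactly two sessions (or pass them)")
        sessions = tuple(wide.columns)
    a = wide[sessions[0]].to_numpy(dtype=float)
    b = wide[sessions[1]].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 paired subjects")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant vector: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
        return float(r**2), float(p)
    if method == "spearman":
        rho, p = stats.spearmanr(a, b)
        return float(rho), float(p)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SignTestResult:
    n_same: int
    n_total: int
    chi_sq: float
    df: int
    p: float


def sign_consistency_test(n_same: int, n_total: int) -> SignTestResult:
    """Chi-squared test of sign preservation against a random-sign null.

    Under the null, half the subjects are expected to keep the sign of a
    parameter across sessions; the statistic is
    ``2 (n_same - n/2)^2 / (n/2)`` on 1 degree of freedom.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_same <= n_total):
        raise ValueError("n_same must lie in [0, n_total]")
    expected = n_total / 2.0
    chi = 2.0 * (n_same - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi, df=1))
    return SignTestResult(n_same=int(n_same), n_total=int(n_total),
                          chi_sq=float(chi), df=1, p=p)


# --------------------------------------------------------------------------
# split-plot ANOVA
# --------------------------------------------------------------------------


def _gg_epsilon(diffs: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from within-subject difference scores."""
    # diffs: subjects x levels of the within factor (cell scores)
    k = diffs.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(diffs, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def parameter_anova(
    panel: ParamPanel,
    *,
    correction: str = "none",
) -> pd.DataFrame:
    """Split-plot ANOVA: group (between) x session x parameter (within).

    The panel must be balanced: every subject observed at every session for
    every parameter.  Returns a table of F statistics, degrees of freedom
    and p values for all main effects and interactions, with within-subject
    error strata (session x subject(group), etc.).  ``correction`` may be
    ``"gg"`` for Greenhouse-Geisser adjusted p values.

    Connections/parameters play the role of the within-subject "connection"
    factor; with a single parameter the connection terms are omitted.
    """
    df = panel.data
    subjects = sorted(df["subject"].unique())
    sessions = sorted(df["session"].unique())
    params = sorted(df["parameter"].unique())
    groups = df.groupby("subject")["group"].first()
    n, s, c = len(subjects), len(sessions), len(params)

    cube = np.full((n, s, c), np.nan)
    sub_ix = {v: i for i, v in enumerate(subjects)}
    ses_ix = {v: i for i, v in enumerate(sessions)}
    par_ix = {v: i for i, v in enumerate(params)}
    for row in df.itertuples():
        cube[sub_ix[row.subject], ses_ix[row.session], par_ix[row.parameter]] = row.value
    if np.isnan(cube).any():
        raise ValueError("unbalanced panel: missing subject/session/parameter cells")

    glabels = np.array([groups[subj] for subj in subjects])
    return _split_plot_anova(cube, glabels, correction=correction,
                             within_names=("session", "connection"))


def _split_plot_anova(
    cube: np.ndarray,
    group_labels: np.ndarray,
    *,
    correction: str = "none",
    within_names: tuple[str, str] = ("session", "connection"),
) -> pd.DataFrame:
    """Univariate split-plot decomposition for one between + two within factors.

    Uses subject-weighted (sequential) sums of squares, which coincide with
    the classical formulas for balanced group sizes and remain the standard
    aov decomposition for unequal group sizes.
    """
    n, s, c = cube.shape
    wn1, wn2 = within_names
    glevels = sorted(set(group_labels))
    g = len(glevels)
    gmask = {lv: group_labels == lv for lv in glevels}
    ng = {lv: int(gmask[lv].sum()) for lv in glevels}
    if min(ng.values()) < 2:
        raise ValueError("each group needs at least two subjects")

    grand = cube.mean()
    subj_mean = cube.mean(axis=(1, 2))  # (n,)
    grp_mean = {lv: cube[gmask[lv]].mean() for lv in glevels}
    ses_mean = cube.mean(axis=(0, 2))  # (s,)
    par_mean = cube.mean(axis=(0, 1))  # (c,)
    gs_mean = {lv: cube[gmask[lv]].mean(axis=(0, 2)) for lv in glevels}  # (s,)
    gc_mean = {lv: cube[gmask[lv]].mean(axis=(0, 1)) for lv in glevels}  # (c,)
    sc_mean = cube.mean(axis=0)  # (s, c)
    gsc_mean = {lv: cube[gmask[lv]].mean(axis=0) for lv in glevels}  # (s, c)
    subj_ses = cube.mean(axis=2)  # (n, s)
    subj_par = cube.mean(axis=1)  # (n, c)

    # between-subject stratum
    ss_g = s * c * sum(ng[lv] * (grp_mean[lv] - grand) ** 2 for lv in glevels)
    ss_subj = s * c * sum(
        ((subj_mean[gmask[lv]] - grp_mean[lv]) ** 2).sum() for lv in glevels
    )
    df_g, df_subj = g - 1, n - g

    # session stratum
    ss_s = n * c * ((ses_mean - grand) ** 2).sum()
    ss_gs = c * sum(
        ng[lv] * ((gs_mean[lv] - grp_mean[lv] - ses_mean + grand) ** 2).sum()
        for lv in glevels
    )
    ss_s_err = c * sum(
        (
            (
                subj_ses[gmask[lv]]
                - subj_mean[gmask[lv], None]
                - gs_mean[lv][None, :]
                + grp_mean[lv]
            )
            ** 2
        ).sum()
        for lv in glevels
    )
    df_s, df_gs, df_s_err = s - 1, (g - 1) * (s - 1), (n - g) * (s - 1)

    # connection stratum
    ss_c = n * s * ((par_mean - grand) ** 2).sum()
    ss_gc = s * sum(
        ng[lv] * ((gc_mean[lv] - grp_mean[lv] - par_mean + grand) ** 2).sum()
        for lv in glevels
    )
    ss_c_err = s * sum(
        (
            (
                subj_par[gmask[lv]]
                - subj_mean[gmask[lv], None]
                - gc_mean[lv][None, :]
                + grp_mean[lv]
            )
            ** 2
        ).sum()
        for lv in glevels
    )
    df_c, df_gc, df_c_err = c - 1, (g - 1) * (c - 1), (n - g) * (c - 1)

    # session x connection stratum
    ss_sc = n * ((sc_mean - ses_mean[:, None] - par_mean[None, :] + grand) ** 2).sum()
    ss_gsc = sum(
        ng[lv]
        * (
            (
                gsc_mean[lv]
                - gs_mean[lv][:, None]
                - gc_mean[lv][None, :]
                + grp_mean[lv]
                - (sc_mean - ses_mean[:, None] - par_mean[None, :] + grand)
            )
            ** 2
        ).sum()
        for lv in glevels
    )
    ss_sc_err = 0.0
    for lv in glevels:
        sub = cube[gmask[lv]]
        resid = (
            sub
            - subj_ses[gmask[lv]][:, :, None]
            - subj_par[gmask[lv]][:, None, :]
            - gsc_mean[lv][None, :, :]
            + gs_mean[lv][None, :, None]
            + gc_mean[lv][None, None, :]
            + subj_mean[gmask[lv]][:, None, None]
            - grp_mean[lv]
        )
        ss_sc_err += (resid**2).sum()
    df_sc = (s - 1) * (c - 1)
    df_gsc = (g - 1) * (s - 1) * (c - 1)
    df_sc_err = (n - g) * (s - 1) * (c - 1)

    rows = []

    def add(effect, ss, dfn, ss_err, dfe, eps=1.0):
        if dfn == 0 or dfe == 0:
            return
        msn = ss / dfn
        mse = ss_err / dfe
        F = msn / mse if mse > 0 else np.inf if msn > 0 else 0.0
        p = float(stats.f.sf(F, dfn * eps, dfe * eps)) if np.isfinite(F) else 0.0
        rows.append(
            {"effect": effect, "SS": ss, "df1": dfn, "df2": dfe, "F": F,
             "eps": eps, "p": p}
        )

    add("group", ss_g, df_g, ss_subj, df_subj)

    eps_s = eps_c = eps_sc = 1.0
    if correction == "gg":
        eps_s = _gg_epsilon(subj_ses)
        eps_c = _gg_epsilon(subj_par)
        eps_sc = _gg_epsilon(cube.reshape(n, s * c))
    if s > 1:
        add(wn1, ss_s, df_s, ss_s_err, df_s_err, eps_s)
        add(f"group:{wn1}", ss_gs, df_gs, ss_s_err, df_s_err, eps_s)
    if c > 1:
        add(wn2, ss_c, df_c, ss_c_err, df_c_err, eps_c)
        add(f"group:{wn2}", ss_gc, df_gc, ss_c_err, df_c_err, eps_c)
    if s > 1 and c > 1:
        add(f"{wn1}:{wn2}", ss_sc, df_sc, ss_sc_err, df_sc_err, eps_sc)
        add(f"group:{wn1}:{wn2}", ss_gsc, df_gsc, ss_sc_err, df_sc_err, eps_sc)
    return pd.DataFrame(rows).set_index("effect")


# --------------------------------------------------------------------------
# posterior-correlation summaries
# --------------------------------------------------------------------------


def _unique_offdiag(k: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(k, 1)
    return iu


def posterior_corr_group_summary(
    matrices: list[np.ndarray] | np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Group summary of per-subject posterior correlation matrices.

    Returns the element-wise mean matrix, the map of one-sample t
    statistics over the unique off-diagonal elements, a Bonferroni
    significance mask at ``alpha / n_unique``, and the fraction of unique
    off-diagonal elements with negative mean.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("need a stack of square matrices of equal shape")
    n, k, _ = mats.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = mats.mean(axis=0)
    iu = _unique_offdiag(k)
    n_unique = iu[0].size
    vals = mats[:, iu[0], iu[1]]  # (n, n_unique)
    t, p = stats.ttest_1samp(vals, 0.0, axis=0)
    threshold = alpha / n_unique
    t_map = np.zeros((k, k))
    p_map = np.ones((k, k))
    sig = np.zeros((k, k), dtype=bool)
    t_map[iu] = t
    t_map.T[iu] = t
    p_map[iu] = p
    p_map.T[iu] = p
    sig[iu] = p < threshold
    sig.T[iu] = p < threshold
    frac_neg = float((mean[iu] < 0).mean())
    return {
        "mean": mean,
        "t": t_map,
        "p": p_map,
        "bonferroni_mask": sig,
        "bonferroni_threshold": threshold,
        "n_unique": int(n_unique),
        "fraction_negative": frac_neg,
    }


def matrix_session_agreement(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Spearman rho between two matrices' unique off-diagonal elements."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    iu = _unique_offdiag(a.shape[0])
    rho, _ = stats.spearmanr(a[iu], b[iu])
    return float(rho)


def b_over_a_ratio(b: float, a: float, *, tol: float = 1e-6) -> float:
    """Ratio of a bilinear term to its intrinsic coupling (NaN if |A| < tol)."""
    if abs(a) < tol:
        return float("nan")
    return float(b / a)


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov z and p against N(sample mean, sample sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    d, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    z = d * np.sqrt(x.size)
    return float(z), float(p)
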