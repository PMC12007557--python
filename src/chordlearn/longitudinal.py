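"""Longitudinal model comparison, interaction tests, FDR, and reliability.

Outcomes measured over 7 test sessions (coded 0..6) are modelled with
random-intercept linear mixed models. Five candidate session-trend shapes
are compared by BIC:

* ``linear``: a single linear term.
* ``asymptotic``: rises inverse-quadratically until the middle of the
  training period and is constant afterwards.
* ``inverse_quadratic``: an inverse-quadratic rise over the full period.
* ``quadratic``: linear + quadratic terms.
* ``cubic``: linear + quadratic + cubic terms.

BIC = k ln(n) - 2 ln(L) with n the row count and k the number of estimated
parameters (fixed effects + random-intercept variance + residual
variance). Models compared by BIC are fit by maximum likelihood, since
REML likelihoods are not comparable across fixed-effect structures; REML
remains the default for coefficient inference. Random slopes are omitted:
with 7 sessions per subject they frequently produce singular fits without
changing the fixed-effect estimates of interest.

Reliability across timepoints is the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1),
computed from the classical mean-squares decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

SESSION_MODELS = (
    "linear",
    "asymptotic",
    "inverse_quadratic",
    "quadratic",
    "cubic",
)


def session_basis(
    model_id: str, sessions: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Centered basis columns for one session-trend model.

    With sessions t in 0..6 and midpoint m = 3:

    * linear: ``t``
    * asymptotic: ``1 - ((t - m) / m)^2`` for t <= m, then constant 1 —
      an inverse-quadratic rise that saturates at mid-training
    * inverse_quadratic: ``1 - ((t - T) / T)^2`` with T the final session —
      the same concave rise stretched over the whole period
    * quadratic: ``t, t^2``;  cubic: ``t, t^2, t^3``

    All columns are mean-centered over the given sessions.
    """
    if sessions is None:
        sessions = np.arange(7)
    t = np.asarray(sessions, dtype=float)
    if model_id == "linear":
        cols, names = [t], ["s_lin"]
    elif model_id == "asymptotic":
        m = t.max() / 2.0
        f = np.where(t <= m, 1.0 - ((t - m) / m) ** 2, 1.0)
        cols, names = [f], ["s_asym"]
    elif model_id == "inverse_quadratic":
        T = t.max()
        cols, names = [1.0 - ((t - T) / T) ** 2], ["s_invq"]
    elif model_id == "quadratic":
        cols, names = [t, t**2], ["s_lin", "s_quad"]
    elif model_id == "cubic":
        cols, names = [t, t**2, t**3], ["s_lin", "s_quad", "s_cub"]
    else:
        raise ValueError(
            f"unknown model {model_id!r}; expected one of {SESSION_MODELS}"
        )
    basis = np.column_stack([c - c.mean() for c in cols])
    return basis, names


@dataclass
class LMMFit:
    """A fitted random-intercept mixed model."""

    model_id: str | None
    result: object  # statsmodels MixedLMResults
    formula: str
    reml: bool

    @property
    def converged(self) -> bool:
        return bool(getattr(self.result, "converged", False))

    @property
    def singular(self) -> bool:
        # random-intercept variance collapsed to ~0
        re_var = float(np.asarray(self.result.cov_re).ravel()[0])
        return re_var < 1e-8 * max(self.result.scale, 1e-300)

    @property
    def n_params(self) -> int:
        # fixed effects + random-intercept variance + residual variance
        return len(self.result.fe_params) + self.result.k_re2 + 1

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    def bic(self) -> float:
        if self.reml:
            raise ValueError("BIC requires a maximum-likelihood fit")
        n = self.result.nobs
        return float(self.n_params * np.log(n) - 2.0 * self.llf)

    def coef(self) -> pd.Series:
        return self.result.fe_params

    def wald_pvalue(self, term: str) -> float:
        """Wald test p-value for one fixed-effect term."""
        return float(self.result.pvalues[term])


def attach_session_basis(
    table: pd.DataFrame, model_id: str, session_col: str = "session"
) -> tuple[pd.DataFrame, list[str]]:
    """Add the model's centered session-basis columns to a long table."""
    sessions = np.sort(table[session_col].unique())
    basis, names = session_basis(model_id, sessions)
    lookup = pd.DataFrame(basis, columns=names, index=sessions)
    out = table.copy()
    for name in names:
        out[name] = lookup.loc[out[session_col], name].to_numpy()
    return out, names


def fit_lmm(
    table: pd.DataFrame,
    fixed: str,
    group_col: str = "subject",
    reml: bool = True,
    model_id: str | None = None,
) -> LMMFit:
    """Fit a random-intercept mixed model with the given fixed-effect
    formula (e.g. ``"outcome ~ group * practice + s_lin"``).

    Singular fits (random-intercept variance at zero) are reported via
    :attr:`LMMFit.singular`, never hidden.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(fixed, table, groups=table[group_col])
        try:
            result = model.fit(reml=reml, method="bfgs")
            if not np.isfinite(result.llf):
                raise np.linalg.LinAlgError("non-finite likelihood")
        except np.linalg.LinAlgError:
            result = model.fit(reml=reml, method="powell")
    return LMMFit(model_id=model_id, result=result, formula=fixed, reml=reml)


@dataclass
class BICComparison:
    winner: str
    bic: dict[str, float]
    excluded: list[str]


def compare_models_bic(
    table: pd.DataFrame,
    model_ids=SESSION_MODELS,
    outcome: str = "outcome",
    extra_terms: str = "",
) -> BICComparison:
    """Fit one mixed model per session-trend shape and pick the lowest BIC.

    All models are fit by maximum likelihood on identical rows; ties are
    broken toward the model with fewer parameters (then listing order).
    Non-converged fits are excluded with a warning.
    """
    bics: dict[str, float] = {}
    ks: dict[str, int] = {}
    excluded: list[str] = []
    for mid in model_ids:
        augmented, names = attach_session_basis(table, mid)
        formula = f"{outcome} ~ {' + '.join(names)}"
        if extra_terms:
            formula += f" + {extra_terms}"
        fit = fit_lmm(augmented, formula, reml=False, model_id=mid)
        if not fit.converged:
            warnings.warn(
                f"model {mid!r} did not converge; excluded from comparison",
                stacklevel=2,
            )
            excluded.append(mid)
            continue
        bics[mid] = fit.bic()
        ks[mid] = fit.n_params
    if not bics:
        raise RuntimeError("no model converged")
    winner = min(bics, key=lambda m: (bics[m], ks[m], model_ids.index(m)))
    return BICComparison(winner=winner, bic=bics, excluded=excluded)


def fdr_adjust(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejected mask, adjusted p-values); adjusted values are
    monotone in the input ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


@dataclass
class ICCResult:
    """ICC(2,1) with its variance components.

    ``var_rows`` is between-subject variance, ``var_cols`` between-timepoint
    variance, ``var_error`` residual; ICC <= 1 always, and can be negative
    when subjects agree less than chance.
    """

    icc: float
    var_rows: float
    var_cols: float
    var_error: float


def icc_agreement(matrix: np.ndarray) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    ``matrix`` is subjects x timepoints with no missing cells. From the
    two-way ANOVA mean squares (MSR rows, MSC columns, MSE error):

        ICC(2,1) = (MSR - MSE) /
                   (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects and k timepoints.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(
        icc=float(icc),
        var_rows=float(max((msr - mse) / k, 0.0)),
        var_cols=float(max((msc - mse) / n, 0.0)),
        var_error=float(mse),
    )
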