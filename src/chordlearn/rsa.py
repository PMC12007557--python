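"""Second-moment decomposition, crossnobis dissimilarity, and decoding.

Given prewhitened trial x voxel patterns from one scanner session, three
multivariate summaries are computed:

**Pattern-variability decomposition.** The trial x trial second-moment
matrix ``G`` of scaled inner products, G[t1, t2] = <V_t1, V_t2> / P with P
the voxel count, is expressed as a nonnegative linear combination of eight
binary component matrices: a global intercept (H0), a same-run component
(HR), class components for trained/untrained trials (HCT/HCU), same
sequence-type components within each class (HST/HSU), and diagonal
trial-noise indicators per class (HT/HU). The coefficients alpha are fit by
non-negative least squares over all matrix entries; the coefficients of the
diagonal components index trial-by-trial pattern variability, summarised on
the log scale as the variability index s = log(alpha).

**Crossnobis dissimilarity.** The squared cross-validated Mahalanobis
distance between sequence types a and b,

    CN(a, b) = sum_{i != j} <d_i, d_j> / (R (R - 1) P),

with d_i the difference of run-mean patterns in run i and R the run count.
Cross-validating over independent runs removes the noise bias of the plain
squared distance, so CN is unbiased and may legitimately be negative;
values are never clipped.

**Pairwise decoding.** Leave-one-run-out accuracy of a linear SVM
discriminating two sequence types, with the regularisation parameter C
selected by nested (inner leave-one-run-out) cross-validation on the
training runs.

All three operate on correct trials from eligible runs only: a run
qualifies when each tested sequence type has at least ``min_correct`` (3)
correct trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import SVC

from .patterns import TrialBetas

COMPONENT_NAMES = ("H0", "HR", "HCT", "HCU", "HST", "HSU", "HT", "HU")

#: default decoder regularisation grid: log-spaced, 5 points per decade
DEFAULT_C_GRID = tuple(np.logspace(-2, 1, 16))


def eligible_run_filter(
    betas: TrialBetas, min_correct: int = 3
) -> TrialBetas:
    """Keep correct trials from runs where every tested sequence type has
    at least ``min_correct`` correct trials.

    Shared pre-filter for all session-level pattern summaries.
    """
    meta = betas.meta
    correct = (
        meta["correct"].to_numpy(bool)
        if "correct" in meta
        else np.ones(len(meta), bool)
    )
    types = sorted(meta["seq_type"].unique())
    keep_runs = []
    for run, g in meta[correct].groupby("run"):
        counts = g["seq_type"].value_counts()
        if all(counts.get(t, 0) >= min_correct for t in types):
            keep_runs.append(run)
    mask = correct & meta["run"].isin(keep_runs).to_numpy()
    return betas.select(mask)


@dataclass
class SecondMomentMatrix:
    """Trial x trial matrix of scaled inner products with its metadata."""

    G: np.ndarray
    n_voxels: int
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        self.G = (G + G.T) / 2.0


def compute_G(betas: TrialBetas) -> SecondMomentMatrix:
    """Scaled inner products of activation patterns: G = V V' / P.

    Callers apply :func:`eligible_run_filter` first; this function only
    computes the matrix.
    """
    if betas.n_trials == 0:
        raise ValueError("no trials")
    V = betas.patterns
    return SecondMomentMatrix(
        G=V @ V.T / betas.n_voxels,
        n_voxels=betas.n_voxels,
        meta=betas.meta.copy(),
    )


@dataclass
class ComponentBasis:
    """The eight binary indicator-product matrices of the decomposition."""

    matrices: dict[str, np.ndarray]
    meta: pd.DataFrame

    def stacked(self) -> np.ndarray:
        """Column-stack of vec(H_i) in canonical component order."""
        return np.column_stack(
            [self.matrices[k].ravel() for k in COMPONENT_NAMES]
        )


def build_component_basis(meta: pd.DataFrame) -> ComponentBasis:
    """Construct H0..HU from trial metadata (run, seq_type, trained).

    * H0: all ones (global intercept).
    * HR: 1 for same-run trial pairs.
    * HCT/HCU: 1 for pairs where both trials are trained/untrained.
    * HST/HSU: 1 for same sequence-type pairs within the trained/untrained
      class (within-run pairs included; the same-run contribution is the
      separate additive HR term).
    * HT/HU: diagonal indicators of trained/untrained trials.
    """
    for col in ("run", "seq_type", "trained"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column '{col}'")
    run = meta["run"].to_numpy()
    seq = meta["seq_type"].to_numpy()
    trained = meta["trained"].to_numpy(bool)
    n = len(meta)
    same_run = (run[:, None] == run[None, :]).astype(float)
    same_seq = (seq[:, None] == seq[None, :]).astype(float)
    t_pair = np.outer(trained, trained).astype(float)
    u_pair = np.outer(~trained, ~trained).astype(float)
    matrices = {
        "H0": np.ones((n, n)),
        "HR": same_run,
        "HCT": t_pair,
        "HCU": u_pair,
        "HST": same_seq * t_pair,
        "HSU": same_seq * u_pair,
        "HT": np.diag(trained.astype(float)),
        "HU": np.diag((~trained).astype(float)),
    }
    return ComponentBasis(matrices=matrices, meta=meta.reset_index(drop=True))


@dataclass
class ComponentCoefficients:
    """Nonnegative component weights with the NNLS residual norm."""

    alpha: dict[str, float]
    residual_norm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha[k] for k in COMPONENT_NAMES])


def estimate_components(
    G: SecondMomentMatrix, basis: ComponentBasis
) -> ComponentCoefficients:
    """Non-negative least squares fit of G to the component basis.

    Minimises ||vec(G) - sum_i alpha_i vec(H_i)||^2 subject to alpha >= 0,
    vectorising the full symmetric matrix including the diagonal (each
    off-diagonal entry thus counts twice). Warns when the basis columns are
    linearly dependent on this design (coefficients not identifiable).
    """
    A = basis.stacked()
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn(
            "component matrices are linearly dependent on this design; "
            "coefficients are not uniquely identified",
            stacklevel=2,
        )
    coef, rnorm = nnls(A, G.G.ravel())
    return ComponentCoefficients(
        alpha=dict(zip(COMPONENT_NAMES, map(float, coef))),
        residual_norm=float(rnorm),
    )


@dataclass
class VariabilityIndex:
    """s = log(alpha) for one diagonal component; undefined when the NNLS
    clamped the coefficient to (numerical) zero."""

    value: float
    defined: bool
    component: str


def variability_index(
    coefficients: ComponentCoefficients, eps: float = 1e-12
) -> dict[str, VariabilityIndex]:
    """Log trial-variability coefficients for each class.

    Returns ``{"trained": s_T, "untrained": s_U}`` where s = log(alpha) of
    the corresponding diagonal component; coefficients at or below ``eps``
    yield a flagged-undefined result (NaN), never a silent number.
    """
    out = {}
    for label, comp in (("trained", "HT"), ("untrained", "HU")):
        a = coefficients.alpha[comp]
        if a <= eps:
            out[label] = VariabilityIndex(float("nan"), False, comp)
        else:
            out[label] = VariabilityIndex(float(np.log(a)), True, comp)
    return out


def run_average_betas(betas: TrialBetas) -> pd.DataFrame:
    """Mean pattern per (sequence type, run).

    Returns a DataFrame indexed by (seq_type, run) whose ``pattern`` column
    holds the mean voxel vectors. Raises if a type is missing from any run
    present after filtering (apply :func:`eligible_run_filter` first).
    """
    meta = betas.meta
    types = sorted(meta["seq_type"].unique())
    runs = sorted(meta["run"].unique())
    rows = []
    for t in types:
        for r in runs:
            mask = (meta["seq_type"] == t) & (meta["run"] == r)
            if not mask.any():
                raise ValueError(f"type {t!r} absent from run {r!r}")
            rows.append(
                {
                    "seq_type": t,
                    "run": r,
                    "pattern": betas.patterns[mask.to_numpy()].mean(axis=0),
                }
            )
    return pd.DataFrame(rows).set_index(["seq_type", "run"])


@dataclass
class CrossnobisResult:
    a: object
    b: object
    value: float
    category: str
    runs_used: int


def pair_category(a_trained: bool, b_trained: bool) -> str:
    if a_trained and b_trained:
        return "trained-trained"
    if not a_trained and not b_trained:
        return "untrained-untrained"
    return "trained-untrained"


def crossnobis(
    means: pd.DataFrame,
    a,
    b,
    n_voxels: int,
    trained_types: set | frozenset = frozenset(),
) -> CrossnobisResult:
    """Cross-validated squared Mahalanobis distance between types a and b.

    ``means`` is the output of :func:`run_average_betas` on prewhitened
    patterns. Sums <d_i, d_j> over ordered run pairs i != j, where d_i is
    the within-run difference of type means, normalised by
    R (R - 1) P. Unbiased: can be negative, never clipped.
    """
    runs = sorted(
        set(means.loc[a].index) & set(means.loc[b].index)
    )
    R = len(runs)
    if R < 2:
        raise ValueError("need at least 2 runs containing both types")
    D = np.stack(
        [means.loc[(a, r), "pattern"] - means.loc[(b, r), "pattern"]
         for r in runs]
    )
    total = D.sum(axis=0)
    # sum over ordered pairs i != j of <d_i, d_j>
    cross = float(total @ total - np.einsum("ij,ij->", D, D))
    value = cross / (R * (R - 1) * n_voxels)
    return CrossnobisResult(
        a=a,
        b=b,
        value=value,
        category=pair_category(a in trained_types, b in trained_types),
        runs_used=R,
    )


def pairwise_decode(
    betas: TrialBetas,
    a,
    b,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> float:
    """Leave-one-run-out linear-SVM accuracy for the type pair (a, b).

    Outer folds are runs; within each training fold the SVM regularisation
    parameter C is chosen by inner leave-one-run-out cross-validation over
    ``c_grid`` (ties broken toward the smallest C), then a model with the
    selected C is trained on all training runs and scored on the held-out
    run. Deterministic given the inputs.
    """
    meta = betas.meta
    mask = meta["seq_type"].isin([a, b]).to_numpy()
    X = betas.patterns[mask]
    y = (meta.loc[mask, "seq_type"] == b).to_numpy(int)
    run = meta.loc[mask, "run"].to_numpy()
    runs = np.unique(run)
    if len(runs) < 3:
        raise ValueError("need >= 3 runs for nested cross-validation")
    accs = []
    for test_run in runs:
        tr = run != test_run
        if len(np.unique(y[~tr])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"a class is absent from fold {test_run!r}")
        best_c = _select_c(X[tr], y[tr], run[tr], c_grid, seed)
        clf = SVC(kernel="linear", C=best_c, random_state=seed)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[~tr]) == y[~tr])))
    return float(np.mean(accs))


def _select_c(X, y, run, c_grid, seed) -> float:
    inner_runs = np.unique(run)
    scores = np.zeros(len(c_grid))
    for val_run in inner_runs:
        tr = run != val_run
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"a class is absent from inner fold {val_run!r}")
        for ci, c in enumerate(c_grid):
            clf = SVC(kernel="linear", C=c, random_state=seed)
            clf.fit(X[tr], y[tr])
            scores[ci] += np.mean(clf.predict(X[~tr]) == y[~tr])
    return float(c_grid[int(np.argmax(scores))])  # argmax: first max = smallest C


def aggregate_pair_categories(
    results: list[CrossnobisResult] | pd.DataFrame,
) -> pd.Series:
    """Mean metric per pair category (trained-trained, untrained-untrained,
    trained-untrained). Empty categories are absent from the output (the
    caller can check)."""
    if isinstance(results, list):
        results = pd.DataFrame(
            [{"category": r.category, "value": r.value} for r in results]
        )
    if results.empty:
        raise ValueError("no pair results to aggregate")
    return results.groupby("category")["value"].mean()


def session_pattern_summary(
    betas: TrialBetas,
    trained_types: frozenset,
    min_correct: int = 3,
    decode: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end session summary: filter runs, fit the eight-component
    decomposition, and compute crossnobis (and optionally decoding) for
    every type pair; returns a tidy long-format frame."""
    kept = eligible_run_filter(betas, min_correct=min_correct)
    G = compute_G(kept)
    basis = build_component_basis(kept.meta)
    coefs = estimate_components(G, basis)
    s = variability_index(coefs)
    rows = [
        {"metric": f"alpha_{k}", "category": "", "value": v}
        for k, v in coefs.alpha.items()
    ]
    rows += [
        {"metric": f"s_{label}", "category": "", "value": vi.value}
        for label, vi in s.items()
    ]
    means = run_average_betas(kept)
    types = sorted(kept.meta["seq_type"].unique())
    cn = [
        crossnobis(means, a, b, kept.n_voxels, trained_types)
        for i, a in enumerate(types)
        for b in types[i + 1:]
    ]
    for cat, val in aggregate_pair_categories(cn).items():
        rows.append({"metric": "crossnobis", "category": cat, "value": val})
    if decode:
        acc = [
            CrossnobisResult(
                a, b,
                pairwise_decode(kept, a, b, seed=seed),
                pair_category(a in trained_types, b in trained_types),
                0,
            )
            for i, a in enumerate(types)
            for b in types[i + 1:]
        ]
        for cat, val in aggregate_pair_categories(acc).items():
            rows.append({"metric": "accuracy", "category": cat, "value": val})
    return pd.DataFrame(rows)
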