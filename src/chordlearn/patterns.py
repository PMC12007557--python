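"""Trial-wise activation-pattern estimation and multivariate prewhitening.

Each functional run is modelled voxelwise with an ordinary-least-squares
GLM containing one regressor per trial (an impulse at trial onset convolved
with a canonical double-gamma hemodynamic response function), plus optional
nuisance columns (constant, polynomial drift, supplied motion series and
their derivatives). The trial coefficients form the trial x voxel pattern
matrix; GLM residuals feed a shrinkage estimate of the spatial noise
covariance, whose inverse symmetric square root prewhitens the patterns so
voxel noise is approximately spherical.

Temporal autocorrelation is not modelled (plain OLS); this is a documented
simplification. Low-frequency drift can alternatively be removed up front
with a discrete-cosine high-pass filter (90 s cutoff by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import tukey_upper_fence


@dataclass
class TrialBetas:
    """Trial x voxel pattern matrix with per-trial metadata.

    ``meta`` has one row per pattern row; expected columns include run,
    sequence_id (or seq_type), trained, correct, session as available.
    """

    patterns: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (trials x voxels)")
        if len(self.meta) != self.patterns.shape[0]:
            raise ValueError("metadata rows must match pattern rows")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain non-finite entries")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def select(self, mask) -> "TrialBetas":
        mask = np.asarray(mask)
        return TrialBetas(self.patterns[mask], self.meta.loc[mask])

    def write(self, prefix) -> None:
        """Write as a matrix TSV + metadata TSV pair."""
        np.savetxt(f"{prefix}_patterns.tsv", self.patterns, delimiter="\t")
        self.meta.to_csv(f"{prefix}_meta.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "TrialBetas":
        return cls(
            np.loadtxt(f"{prefix}_patterns.tsv", delimiter="\t", ndmin=2),
            pd.read_csv(f"{prefix}_meta.tsv", sep="\t"),
        )


@dataclass
class NoiseCovariance:
    """Voxel x voxel noise covariance with its shrinkage weight."""

    matrix: np.ndarray
    shrinkage: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.matrix = (m + m.T) / 2.0


def double_gamma_hrf(
    dt: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities (shape = delay, scale = 1 s: response
    peaking near 5 s, undershoot near 15 s, undershoot 1/6 of the peak),
    sampled every ``dt`` seconds over ``duration`` and peak-normalised to 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, duration, dt)
    h = stats.gamma.pdf(t, peak_delay) - ratio * stats.gamma.pdf(
        t, undershoot_delay
    )
    return h / h.max()


def trial_design_matrix(
    onsets: np.ndarray,
    n_volumes: int,
    tr: float,
    hrf: np.ndarray | None = None,
    oversample: int = 12,
) -> np.ndarray:
    """One HRF-convolved impulse-response column per trial onset.

    Impulses are placed on a grid oversampled ``oversample``-fold relative
    to the TR, convolved with the HRF sampled on that grid, and read out at
    volume acquisition times. Shared by the BOLD simulator and the GLM so
    the noiseless round trip is exact.
    """
    onsets = np.asarray(onsets, dtype=float)
    dt = tr / oversample
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    n_fine = n_volumes * oversample + len(hrf)
    X = np.zeros((n_volumes, len(onsets)))
    for j, onset in enumerate(onsets):
        if onset < 0 or onset >= n_volumes * tr:
            raise ValueError(f"onset {onset} outside the run")
        fine = np.zeros(n_fine)
        fine[int(round(onset / dt))] = 1.0
        conv = np.convolve(fine, hrf)[: n_volumes * oversample]
        X[:, j] = conv[::oversample]
    return X


def fit_trial_glm(
    data: np.ndarray,
    onsets: np.ndarray,
    tr: float,
    meta: pd.DataFrame | None = None,
    nuisance: np.ndarray | None = None,
    hrf: np.ndarray | None = None,
    add_constant: bool = True,
    drift_order: int = 0,
    motion: np.ndarray | None = None,
    motion_derivatives: bool = True,
) -> tuple[TrialBetas, np.ndarray]:
    """OLS GLM with one regressor per trial; returns betas and residuals.

    ``data`` is volumes x voxels. Nuisance columns (constant, Legendre
    drift polynomials, motion series and optionally their first
    differences, plus any supplied ``nuisance`` block) are appended after
    the trial columns and their coefficients discarded. Raises on a
    rank-deficient design.
    """
    data = np.asarray(data, dtype=float)
    n_vol = data.shape[0]
    X_trial = trial_design_matrix(onsets, n_vol, tr, hrf=hrf)
    blocks = [X_trial]
    if add_constant:
        blocks.append(np.ones((n_vol, 1)))
    if drift_order > 0:
        t = np.linspace(-1, 1, n_vol)
        blocks.append(np.polynomial.legendre.legvander(t, drift_order)[:, 1:])
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_vol:
            motion = motion.T
        blocks.append(motion)
        if motion_derivatives:
            blocks.append(np.diff(motion, axis=0, prepend=motion[:1]))
    if nuisance is not None:
        blocks.append(np.atleast_2d(nuisance))
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coefs, *_ = np.linalg.lstsq(X, data, rcond=None)
    residuals = data - X @ coefs
    n_trials = X_trial.shape[1]
    if meta is None:
        meta = pd.DataFrame({"trial": np.arange(n_trials), "onset": onsets})
    return TrialBetas(coefs[:n_trials], meta), residuals


def highpass_filter(
    timeseries: np.ndarray, tr: float, cutoff: float = 90.0
) -> np.ndarray:
    """Remove drifts slower than ``cutoff`` seconds by projecting out a
    discrete-cosine basis (plus the mean).

    The basis contains DCT-II components with period longer than the
    cutoff, i.e. k = 1 .. floor(2 * N * TR / cutoff).
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * TR")
    Y = np.asarray(timeseries, dtype=float)
    squeeze = Y.ndim == 1
    Y = np.atleast_2d(Y.T).T if squeeze else Y
    n = Y.shape[0]
    n_basis = int(np.floor(2.0 * n * tr / cutoff))
    t = (np.arange(n) + 0.5) / n
    cols = [np.ones(n)]
    cols += [np.cos(np.pi * k * t) for k in range(1, n_basis + 1)]
    B = np.column_stack(cols)
    Q, _ = np.linalg.qr(B)
    out = Y - Q @ (Q.T @ Y)
    return out[:, 0] if squeeze else out


def shrinkage_covariance(
    residuals: np.ndarray, shrinkage: float | None = None
) -> NoiseCovariance:
    """Shrink the sample residual covariance toward its diagonal.

    Returns ``(1 - lam) * S + lam * diag(S)``. When ``shrinkage`` is not
    supplied, lam is the analytic plug-in weight for the diagonal target
    (ratio of the summed sampling variances of the off-diagonal entries to
    their summed squares), clipped to [0, 1]. Positive definite whenever
    every voxel has nonzero variance and lam > 0.
    """
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    if n < 2:
        raise ValueError("need at least 2 residual time points")
    if np.allclose(R, 0):
        raise ValueError("residuals are identically zero")
    Xc = R - R.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    if shrinkage is None:
        # plug-in estimate of sum of Var(s_ij) over off-diagonal entries
        W = np.einsum("ki,kj->ij", Xc**2, Xc**2) - n * (Xc.T @ Xc / n) ** 2
        var_s = W * n / (n - 1) ** 3
        off = ~np.eye(p, dtype=bool)
        denom = np.sum(S[off] ** 2)
        shrinkage = 1.0 if denom == 0 else float(
            np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0)
        )
    out = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    return NoiseCovariance(out, float(shrinkage))


def _inv_sqrt(cov: NoiseCovariance, floor_scale: float = 1e-10) -> np.ndarray:
    m = cov.matrix
    evals, evecs = np.linalg.eigh(m)
    floor = floor_scale * np.trace(m) / m.shape[0]
    if evals.min() < -1e-8 * np.trace(m) / m.shape[0]:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    evals = np.maximum(evals, floor)
    return (evecs / np.sqrt(evals)) @ evecs.T


def prewhiten(betas: TrialBetas, cov: NoiseCovariance) -> TrialBetas:
    """Multiply each pattern by the symmetric inverse square root of the
    noise covariance (multivariate spatial prewhitening)."""
    W = _inv_sqrt(cov)
    if W.shape[0] != betas.n_voxels:
        raise ValueError("covariance dimension does not match voxel count")
    return TrialBetas(betas.patterns @ W, betas.meta.copy())


def exclude_high_motion_runs(fd_per_run, k: float = 1.5) -> np.ndarray:
    """Flag runs whose framewise-displacement summary exceeds the Tukey
    upper fence (Q3 + 1.5 IQR) of the run distribution. True = exclude."""
    fd = np.asarray(fd_per_run, dtype=float)
    return fd > tukey_upper_fence(fd, k=k)
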