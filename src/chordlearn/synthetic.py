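"""Synthetic data with known ground truth for every analysis stage.

Four generators:

* key-press logs with chord structure, an exponential learning curve for
  movement time, and injected chord-substitution errors;
* trial x voxel pattern sets whose *expected* second-moment matrix equals
  a prescribed nonnegative combination of the eight component matrices —
  each alpha maps to the standard deviation sqrt(alpha) of a shared
  standard-normal voxel vector, so E[V V' / P] = sum_i alpha_i H_i exactly
  and the decomposition has an analytic recovery oracle;
* BOLD-like run time series that are the exact forward model of the trial
  GLM (HRF-convolved impulses times amplitudes plus white noise);
* long-format longitudinal outcome tables with session-basis fixed
  effects, subject random intercepts, and Gaussian residuals.

Default sizes mirror the study design: 5 runs x 4 sequence types x 8
trials per type per run; 400 volumes per run at TR 1.2 s; 7 test sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import KeyPressLog
from .longitudinal import session_basis
from .patterns import TrialBetas, double_gamma_hrf, trial_design_matrix
from .rsa import COMPONENT_NAMES
from .task_design import FINGERS, Chord, Sequence, SessionDesign, enumerate_chords


@dataclass
class SubjectParams:
    """Generative parameters for one simulated subject.

    Movement time on correct trials follows ``a + b * exp(-c * k)`` with
    ``k`` the practice-session index (seconds): asymptote ``a``, initial
    gain ``b``, learning rate ``c`` per session. Errors occur independently
    per trial with probability ``error_prob`` (a random chord substituted);
    key-press times within a chord jitter with SD ``jitter_sd`` seconds.
    """

    group: str = "intervention"
    config_label: str = "A"
    mt_asymptote: float = 2.0
    mt_gain: float = 2.5
    mt_rate: float = 0.15
    error_prob: float = 0.1
    jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.mt_asymptote <= 0 or self.mt_gain < 0 or self.mt_rate < 0:
            raise ValueError("learning-curve parameters out of range")
        if not 0 <= self.error_prob < 1:
            raise ValueError("error probability must be in [0, 1)")

    def expected_mt(self, practice_index: int) -> float:
        return self.mt_asymptote + self.mt_gain * np.exp(
            -self.mt_rate * practice_index
        )


STOPPING_RULES = {"unpaced": 20, "paced": 5}


def simulate_behavior_session(
    params: SubjectParams,
    sequences: list[Sequence],
    phase: str,
    practice_index: int,
    rng: np.random.Generator,
    beat: float = 0.7,
    max_trials_per_sequence: int | None = None,
) -> list[KeyPressLog]:
    """Simulate one practice session of key-press logs.

    For each sequence, trials are generated until the phase's criterion
    count of correct trials is reached (20 correct in the unpaced phase, 5
    in the paced home phase). Correct trials space chord mean times evenly
    over the subject's learning-curve MT (in the paced phase, over the
    prescribed beat spacing); incorrect trials substitute one random wrong
    chord. Press times within a trial are strictly increasing.
    """
    if phase not in STOPPING_RULES:
        raise ValueError(f"phase must be one of {set(STOPPING_RULES)}")
    criterion = STOPPING_RULES[phase]
    if max_trials_per_sequence is None:
        max_trials_per_sequence = max(50 * criterion, 200)
    chord_pool = sorted(enumerate_chords())
    logs: list[KeyPressLog] = []
    trial_id = 0
    for seq_id, seq in enumerate(sequences):
        n_correct = 0
        n_attempts = 0
        while n_correct < criterion:
            if n_attempts >= max_trials_per_sequence:
                raise RuntimeError(
                    f"sequence {seq_id} did not reach {criterion} correct "
                    f"trials in {max_trials_per_sequence} attempts"
                )
            is_error = rng.random() < params.error_prob
            chords = list(seq.chords)
            if is_error:
                pos = int(rng.integers(len(chords)))
                wrong = [c for c in chord_pool if c != chords[pos]]
                chords[pos] = wrong[int(rng.integers(len(wrong)))]
            if phase == "paced":
                gap = beat
            else:
                mt = params.expected_mt(practice_index)
                gap = mt / (len(chords) - 1)
            presses = _press_times(chords, gap, params.jitter_sd, rng)
            logs.append(
                KeyPressLog(
                    trial_id=trial_id,
                    sequence_id=seq_id,
                    presses=presses,
                    phase=phase,
                )
            )
            trial_id += 1
            n_attempts += 1
            if not is_error:
                n_correct += 1
    return logs


def _press_times(chords, gap, jitter_sd, rng):
    presses = []
    start = 0.5  # cue-to-first-chord latency, seconds
    for k, chord in enumerate(chords):
        center = start + k * gap
        for key in sorted(chord.keys, key=FINGERS.index):
            t = center + jitter_sd * rng.standard_normal()
            presses.append((key, max(t, 0.0)))
    presses.sort(key=lambda p: p[1])
    # enforce strictly increasing times at float resolution
    out = []
    last = -np.inf
    for key, t in presses:
        t = t if t > last else np.nextafter(last, np.inf)
        out.append((key, float(t)))
        last = t
    return out


# ---------------------------------------------------------------------------
# Multivoxel patterns with known component structure
# ---------------------------------------------------------------------------


def make_pattern_metadata(
    n_runs: int = 5,
    n_trained_types: int = 2,
    n_untrained_types: int = 2,
    trials_per_type_per_run: int = 8,
) -> pd.DataFrame:
    """Trial metadata for the default session layout: 5 runs x (2 trained +
    2 untrained types) x 8 trials = 160 rows, all marked correct."""
    rows = []
    types = [(f"T{i}", True) for i in range(n_trained_types)] + [
        (f"U{i}", False) for i in range(n_untrained_types)
    ]
    for run in range(n_runs):
        for seq_type, trained in types:
            for _ in range(trials_per_type_per_run):
                rows.append(
                    {
                        "run": run,
                        "seq_type": seq_type,
                        "trained": trained,
                        "correct": True,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PatternGenSpec:
    """Specification for one synthetic pattern dataset.

    ``alpha`` holds the eight nonnegative component weights in canonical
    order (H0, HR, HCT, HCU, HST, HSU, HT, HU); ``meta`` the trial layout
    (see :func:`make_pattern_metadata`), or a SessionDesign via
    :meth:`from_design`.
    """

    alpha: dict[str, float]
    n_voxels: int = 200
    meta: pd.DataFrame = field(default_factory=make_pattern_metadata)
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(COMPONENT_NAMES) - set(self.alpha)
        if missing:
            raise ValueError(f"alpha lacks components {missing}")
        if any(v < 0 for v in self.alpha.values()):
            raise ValueError("alpha coefficients must be nonnegative")
        if self.n_voxels < 1:
            raise ValueError("need at least 1 voxel")

    @classmethod
    def from_design(
        cls, design: SessionDesign, alpha, n_voxels=200, seed=None
    ) -> "PatternGenSpec":
        ev = design.to_events_frame()
        meta = pd.DataFrame(
            {
                "run": ev["run"],
                "seq_type": ev["sequence_id"].astype(str),
                "trained": ev["trial_type"] == "trained",
                "correct": True,
            }
        )
        return cls(alpha=alpha, n_voxels=n_voxels, meta=meta, seed=seed)


def simulate_pattern_dataset(
    spec: PatternGenSpec, rng: np.random.Generator | None = None
) -> TrialBetas:
    """Draw trial patterns whose expected second-moment matrix is
    ``sum_i alpha_i H_i``.

    Each component contributes ``sqrt(alpha) * v`` with ``v`` a shared
    i.i.d. standard-normal voxel vector: one global vector, one per run,
    one per class (trained/untrained), one per sequence type, and an
    independent per-trial noise vector whose scale is the class's diagonal
    coefficient. Because the shared vectors are independent with identity
    covariance, E[V V' / P] = sum_i alpha_i H_i exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    meta = spec.meta.reset_index(drop=True)
    P = spec.n_voxels
    a = spec.alpha
    draw = lambda: rng.standard_normal(P)

    v_global = draw()
    v_run = {r: draw() for r in meta["run"].unique()}
    v_class = {True: draw(), False: draw()}
    v_type = {t: draw() for t in meta["seq_type"].unique()}

    X = np.zeros((len(meta), P))
    for i, row in meta.iterrows():
        trained = bool(row["trained"])
        x = np.sqrt(a["H0"]) * v_global + np.sqrt(a["HR"]) * v_run[row["run"]]
        if trained:
            x = (
                x
                + np.sqrt(a["HCT"]) * v_class[True]
                + np.sqrt(a["HST"]) * v_type[row["seq_type"]]
                + np.sqrt(a["HT"]) * draw()
            )
        else:
            x = (
                x
                + np.sqrt(a["HCU"]) * v_class[False]
                + np.sqrt(a["HSU"]) * v_type[row["seq_type"]]
                + np.sqrt(a["HU"]) * draw()
            )
        X[i] = x
    return TrialBetas(X, meta)


# ---------------------------------------------------------------------------
# BOLD-like run time series
# ---------------------------------------------------------------------------


@dataclass
class BOLDRun:
    """Simulated run time series (volumes x voxels) with its event table."""

    data: np.ndarray
    tr: float
    events: pd.DataFrame

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


def simulate_bold_run(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    n_voxels: int = 50,
    tr: float = 1.2,
    n_volumes: int = 400,
    noise_sd: float = 1.0,
    hrf: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    events: pd.DataFrame | None = None,
) -> BOLDRun:
    """Forward model of the trial GLM: X @ A + white noise.

    ``amplitudes`` is trials x voxels (a 1-D vector is broadcast across
    voxels). With ``noise_sd = 0`` the output equals the design matrix
    times the amplitudes exactly, so the GLM round trip is the identity.
    """
    if hrf is None:
        hrf = double_gamma_hrf(tr / 12)
    rng = rng or np.random.default_rng()
    onsets = np.asarray(onsets, dtype=float)
    if np.any(onsets >= n_volumes * tr):
        raise ValueError("trial onset beyond run duration")
    A = np.asarray(amplitudes, dtype=float)
    if A.ndim == 1:
        A = np.tile(A[:, None], (1, n_voxels))
    X = trial_design_matrix(onsets, n_volumes, tr, hrf=hrf)
    data = X @ A + noise_sd * rng.standard_normal((n_volumes, A.shape[1]))
    if events is None:
        events = pd.DataFrame({"onset": onsets, "trial": np.arange(len(onsets))})
    return BOLDRun(data=data, tr=tr, events=events)


# ---------------------------------------------------------------------------
# Longitudinal outcome tables
# ---------------------------------------------------------------------------


#: Reference effect sizes for the session-trend recovery simulations: one
#: coefficient vector per model, sized so the trend is comparable to the
#: subject-level noise (random-intercept SD 0.5, residual SD 0.5) — i.e.
#: clearly present but not overwhelming, as in behavioral learning curves.
DEFAULT_TREND_COEFFICIENTS = {
    "linear": (0.5,),
    "asymptotic": (2.0,),
    "inverse_quadratic": (2.0,),
    "quadratic": (0.5, -0.08),
    "cubic": (0.5, -0.15, 0.02),
}


def simulate_longitudinal_table(
    model_id: str,
    coefficients,
    n_subjects: int = 60,
    n_sessions: int = 7,
    random_intercept_sd: float = 0.5,
    residual_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    with_groups: bool = False,
    group_coef: float = 0.0,
    practice_coef: float = 0.0,
    interaction_coef: float = 0.0,
) -> pd.DataFrame:
    """Long-format outcomes under a chosen session-trend model.

    The outcome is ``basis @ coefficients`` (centered session basis of
    ``model_id``) plus a subject random intercept and Gaussian residuals.
    With ``with_groups`` the table also carries a two-level group factor
    (half the subjects each) and a trained/untrained practice factor (two
    rows per subject x session), with optional main and interaction
    effects, to exercise the group x practice interaction test.
    """
    rng = rng or np.random.default_rng()
    sessions = np.arange(n_sessions)
    basis, _ = session_basis(model_id, sessions)
    coefficients = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if basis.shape[1] != coefficients.size:
        raise ValueError(
            f"model {model_id!r} needs {basis.shape[1]} coefficients"
        )
    trend = basis @ coefficients
    intercepts = random_intercept_sd * rng.standard_normal(n_subjects)
    rows = []
    for subj in range(n_subjects):
        group = 1 if (with_groups and subj >= n_subjects // 2) else 0
        practices = (0, 1) if with_groups else (np.nan,)
        for s in sessions:
            for prac in practices:
                mu = trend[s] + intercepts[subj]
                if with_groups:
                    mu += (
                        group_coef * group
                        + practice_coef * prac
                        + interaction_coef * group * prac
                    )
                rows.append(
                    {
                        "subject": subj,
                        "session": int(s),
                        "group": group,
                        "practice": prac,
                        "outcome": mu + residual_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)
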