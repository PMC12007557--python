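"""Scoring of raw key-press logs into behavioral outcomes.

A trial's raw record is a list of timed key presses. Scoring proceeds:

1. presses are clustered into 5 chords at the 4 largest inter-press gaps,
   regardless of accuracy;
2. each performed chord's key set must equal the target chord's key set,
   in order, for the trial to count as correct;
3. in the paced phase the movement time (MT) must additionally lie within
   +-10% of the prescribed 4 x 0.7 s = 2.8 s;
4. session summaries (median/SD of MT, inter-press-interval consistency)
   are computed from correct trials after discarding the first 10 presented
   trials of each sequence, and disproportionately error-prone
   subject x sequence x session cells are excluded by a Tukey upper fence.

MT is defined as the difference between the mean press times of the last
and first chords, consistent with the 4-interval structure of a 5-chord
trial; whether the original task measured MT from cue onset instead is not
recorded in the trial metadata, so the definition used is flagged in the
``mt_definition`` module attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_design import FINGERS, Sequence

#: MT endpoint convention used throughout this module (see module docstring)
mt_definition = "last_chord_mean_time_minus_first_chord_mean_time"


@dataclass
class KeyPressLog:
    """Raw timed key presses for one trial. Presses are sorted by time on
    construction; times must be nonnegative."""

    trial_id: int
    sequence_id: int
    presses: list[tuple[str, float]]
    phase: str = "unpaced"

    def __post_init__(self) -> None:
        if any(t < 0 for _, t in self.presses):
            raise ValueError("press times must be nonnegative")
        if any(k not in FINGERS for k, _ in self.presses):
            bad = {k for k, _ in self.presses} - set(FINGERS)
            raise ValueError(f"unknown keys {bad}; expected {FINGERS}")
        self.presses = sorted(self.presses, key=lambda p: p[1])


@dataclass
class ChordedTrial:
    """A trial clustered into chords with accuracy/timing verdicts."""

    trial_id: int
    sequence_id: int
    chords: list[list[tuple[str, float]]]
    mean_times: list[float]
    verdict: str = "unscored"  # correct | wrong | too_fast | too_slow | missed
    phase: str = "unpaced"
    meta: dict = field(default_factory=dict)

    @property
    def correct(self) -> bool:
        return self.verdict == "correct"

    @property
    def key_sets(self) -> list[frozenset[str]]:
        return [frozenset(k for k, _ in chord) for chord in self.chords]


def cluster_presses(log: KeyPressLog, n_chords: int = 5) -> ChordedTrial:
    """Cluster presses into ``n_chords`` groups at the largest time gaps.

    The split points are the ``n_chords - 1`` largest inter-press gaps,
    ties broken toward the earliest gap. Trials with fewer presses than
    chords cannot be clustered and get verdict ``missed``.
    """
    times = np.array([t for _, t in log.presses])
    if len(times) < n_chords:
        return ChordedTrial(
            log.trial_id,
            log.sequence_id,
            chords=[list(log.presses)] if log.presses else [],
            mean_times=[float(times.mean())] if len(times) else [],
            verdict="missed",
            phase=log.phase,
        )
    gaps = np.diff(times)
    # stable argsort on -gap keeps earlier gaps first among ties
    cut_after = np.sort(np.argsort(-gaps, kind="stable")[: n_chords - 1])
    bounds = [0, *(cut_after + 1), len(times)]
    chords = [
        list(log.presses[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    mean_times = [float(np.mean([t for _, t in c])) for c in chords]
    return ChordedTrial(
        log.trial_id,
        log.sequence_id,
        chords=chords,
        mean_times=mean_times,
        phase=log.phase,
    )


def score_accuracy(trial: ChordedTrial, target: Sequence) -> ChordedTrial:
    """Mark the trial correct iff every performed chord's key set equals the
    target's nth chord key set, in order. Missed trials stay missed."""
    if trial.verdict == "missed":
        return trial
    ok = len(trial.chords) == len(target.chords) and all(
        performed == chord.keys
        for performed, chord in zip(trial.key_sets, target.chords)
    )
    trial.verdict = "correct" if ok else "wrong"
    return trial


def score_paced(
    trial: ChordedTrial,
    beat: float = 0.7,
    n_chords: int = 5,
    tolerance: float = 0.10,
) -> ChordedTrial:
    """Apply the tempo criterion to a key-correct trial.

    The prescribed MT is ``(n_chords - 1) * beat`` (2.8 s at the default
    0.7 s beat); a trial is too slow (fast) when its MT is more than 10%
    longer (shorter) than prescribed.
    """
    if trial.verdict != "correct":
        return trial
    prescribed = (n_chords - 1) * beat
    mt = movement_time(trial)
    if mt > (1 + tolerance) * prescribed:
        trial.verdict = "too_slow"
    elif mt < (1 - tolerance) * prescribed:
        trial.verdict = "too_fast"
    return trial


def movement_time(trial: ChordedTrial) -> float:
    """MT: last chord mean time minus first chord mean time, seconds."""
    if len(trial.mean_times) < 2:
        raise ValueError("movement time undefined for < 2 chords")
    return trial.mean_times[-1] - trial.mean_times[0]


def compute_ipis(trial: ChordedTrial) -> np.ndarray:
    """The 4 inter-press intervals: differences between mean times of
    consecutive chords of a 5-chord trial."""
    if len(trial.mean_times) != 5:
        raise ValueError(f"expected 5 chords, got {len(trial.mean_times)}")
    ipis = np.diff(trial.mean_times)
    if np.any(ipis <= 0):
        raise ValueError("chord mean times must be strictly increasing")
    return ipis


@dataclass
class IPIConsistency:
    """Mean across-trial correlation of IPI vectors at one lag."""

    lag: int
    mean_correlation: float  # nan when no valid pair
    n_pairs: int
    n_skipped_zero_variance: int

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


def ipi_consistency(
    trials: list[ChordedTrial], lag: int = 1
) -> IPIConsistency:
    """Execution consistency: Pearson correlation between the 4-IPI vectors
    of trials ``t`` and ``t + lag`` (positions in the given list), averaged
    over all pairs. Pairs where either vector has zero variance are skipped
    and counted. Callers pass correct trials of one sequence, already past
    the first-10 discard.
    """
    if not 1 <= lag:
        raise ValueError("lag must be >= 1")
    vecs = [compute_ipis(t) for t in trials]
    corrs = []
    skipped = 0
    for i in range(len(vecs) - lag):
        a, b = vecs[i], vecs[i + lag]
        tol = 1e-12 * max(np.abs(a).max(), np.abs(b).max(), 1.0)
        if np.std(a) <= tol or np.std(b) <= tol:
            skipped += 1
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return IPIConsistency(
        lag=lag,
        mean_correlation=float(np.mean(corrs)) if corrs else float("nan"),
        n_pairs=len(corrs),
        n_skipped_zero_variance=skipped,
    )


def tukey_upper_fence(values, k: float = 1.5) -> float:
    """Q3 + k * IQR with quartiles by linear interpolation (type 7)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for a Tukey fence")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 + k * (q3 - q1))


def exclude_outlier_sequences(
    error_counts: pd.DataFrame, k: float = 1.5
) -> pd.Series:
    """Flag subject x sequence x session cells with disproportionate errors.

    ``error_counts`` has columns subject, session, sequence_id, errors (one
    row per cell). Separately for each session x sequence, a cell is
    excluded when its error count exceeds the Tukey upper fence of that
    cell's distribution across subjects. Returns a boolean Series aligned
    with the input index (True = exclude).
    """
    required = {"subject", "session", "sequence_id", "errors"}
    if missing := required - set(error_counts.columns):
        raise ValueError(f"missing columns: {missing}")
    fences = error_counts.groupby(["session", "sequence_id"])[
        "errors"
    ].transform(lambda s: tukey_upper_fence(s.to_numpy(), k=k))
    return (error_counts["errors"] > fences).rename("excluded")


@dataclass
class MTStats:
    median_mt: float
    sd_mt: float
    error_count: int
    n_used: int

    @property
    def defined(self) -> bool:
        return self.n_used >= 1


def session_mt_stats(
    trials: list[ChordedTrial],
    discard_first: int = 10,
    discard_counts_incorrect: bool = True,
) -> MTStats:
    """Median and SD of MT for one sequence in one session.

    The first ``discard_first`` trials are dropped before MT statistics
    (performance is unstable early in a session); by default the discard
    counts trials in presentation order regardless of accuracy, with
    ``discard_counts_incorrect=False`` it drops the first 10 *correct*
    trials instead. Errors are counted over all trials pre-discard. The MT
    statistics use correct trials only; with no correct trial remaining the
    result is flagged undefined (NaN values, ``defined`` False).
    """
    error_count = sum(not t.correct for t in trials)
    if discard_counts_incorrect:
        kept = trials[discard_first:]
    else:
        n_corr = 0
        kept = []
        for t in trials:
            if n_corr >= discard_first:
                kept.append(t)
            if t.correct:
                n_corr += 1
    mts = [movement_time(t) for t in kept if t.correct]
    if not mts:
        return MTStats(float("nan"), float("nan"), error_count, 0)
    return MTStats(
        median_mt=float(np.median(mts)),
        sd_mt=float(np.std(mts, ddof=1)) if len(mts) > 1 else 0.0,
        error_count=error_count,
        n_used=len(mts),
    )


def read_keypress_csv(path) -> list[KeyPressLog]:
    """Read a key-press CSV (trial, sequence_id, key, time[, phase]) into
    per-trial logs."""
    df = pd.read_csv(path)
    logs = []
    for (trial, seq), g in df.groupby(["trial", "sequence_id"], sort=True):
        phase = g["phase"].iloc[0] if "phase" in g else "unpaced"
        logs.append(
            KeyPressLog(
                trial_id=int(trial),
                sequence_id=int(seq),
                presses=list(zip(g["key"], g["time"].astype(float))),
                phase=str(phase),
            )
        )
    return logs


def write_keypress_csv(logs: list[KeyPressLog], path) -> None:
    rows = [
        {
            "trial": log.trial_id,
            "sequence_id": log.sequence_id,
            "key": key,
            "time": time,
            "phase": log.phase,
        }
        for log in logs
        for key, time in log.presses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
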