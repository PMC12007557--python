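"""Chord enumeration, sequence generation, and scanner-session design.

The task unit is a *chord*: a simultaneous combination of 1-4 finger presses
on a four-key button box, written as four binary flags in fixed finger order
(pinky, ring, middle, index). Trials present *sequences* of 5 chords; the
design constraints are combinatorial:

* two chords (1101 and 1011) are excluded as too difficult, leaving 13;
* consecutive chords within a sequence differ in exactly 3 fingers
  (Hamming distance 3) and no chord repeats within a sequence;
* trained and untrained sequence sets share no ordered chord transition,
  share as few chords as possible, and match per-finger press frequency
  as well as possible (lexicographic objective, in that order);
* a scanner session presents 4 sequences x 8 trials x 5 runs = 160 trials,
  never two consecutive trials of the same sequence, with a truncated
  exponential inter-trial interval (mean 7.4 s on [6.0, 9.2] s) and a 6 s
  hand-stretch pause after every 8 trials.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

FINGERS = ("pinky", "ring", "middle", "index")

#: chords excluded from the task (pinky-ring-middle-index order)
EXCLUDED_MASKS = ((1, 1, 0, 1), (1, 0, 1, 1))


@dataclass(frozen=True, order=True)
class Chord:
    """A simultaneous finger-press combination.

    ``mask`` holds four binary flags in pinky, ring, middle, index order.
    """

    mask: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.mask) != 4 or any(m not in (0, 1) for m in self.mask):
            raise ValueError(f"mask must be 4 binary flags, got {self.mask}")
        if sum(self.mask) == 0:
            raise ValueError("chord must use at least one finger")

    @classmethod
    def from_string(cls, s: str) -> "Chord":
        return cls(tuple(int(c) for c in s))  # type: ignore[arg-type]

    @property
    def keys(self) -> frozenset[str]:
        """Finger names pressed in this chord."""
        return frozenset(f for f, m in zip(FINGERS, self.mask) if m)

    def __str__(self) -> str:
        return "".join(str(m) for m in self.mask)


@dataclass(frozen=True, order=True)
class Sequence:
    """An ordered series of 5 chords executed as one trial."""

    chords: tuple[Chord, ...]
    label: str = field(default="", compare=False)

    @property
    def transitions(self) -> tuple[tuple[Chord, Chord], ...]:
        """Ordered consecutive chord pairs (execution order matters)."""
        return tuple(zip(self.chords[:-1], self.chords[1:]))

    def finger_counts(self) -> np.ndarray:
        """Total presses per finger across the sequence."""
        return np.sum([c.mask for c in self.chords], axis=0)

    def __str__(self) -> str:
        return "-".join(str(c) for c in self.chords)


def hamming_distance(a: Chord, b: Chord) -> int:
    """Number of fingers whose press flag differs between two chords."""
    return sum(x != y for x, y in zip(a.mask, b.mask))


def enumerate_chords(excluded: tuple = EXCLUDED_MASKS) -> set[Chord]:
    """All usable chords: every nonempty 4-finger combination minus the
    excluded masks. With the default exclusions this yields 13 chords."""
    out = set()
    for mask in itertools.product((0, 1), repeat=4):
        if sum(mask) == 0 or mask in excluded:
            continue
        out.add(Chord(mask))
    return out


def generate_sequences(
    chords: set[Chord],
    length: int = 5,
    distance: int = 3,
    seed: int | None = None,
) -> list[Sequence]:
    """Exhaustively enumerate all valid sequences over ``chords``.

    A valid sequence has ``length`` distinct chords with Hamming distance
    exactly ``distance`` between each consecutive pair. The search is a
    depth-first enumeration over the transition graph, so it is exhaustive
    and deterministic; ``seed``, when given, only shuffles the output order.

    Returns an empty list if the constraints are unsatisfiable.
    """
    pool = sorted(chords)
    neighbors = {
        c: [d for d in pool if hamming_distance(c, d) == distance] for c in pool
    }
    out: list[Sequence] = []

    def extend(path: list[Chord]) -> None:
        if len(path) == length:
            out.append(Sequence(tuple(path)))
            return
        for nxt in neighbors[path[-1]]:
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    for start in pool:
        extend([start])
    if seed is not None:
        random.Random(seed).shuffle(out)
    return out


@dataclass(frozen=True)
class Configuration:
    """A trained/untrained partition of sequences (set A or B)."""

    trained: tuple[Sequence, ...]
    untrained: tuple[Sequence, ...]
    label: str = "A"

    def __post_init__(self) -> None:
        shared = _transition_set(self.trained) & _transition_set(self.untrained)
        if shared:
            raise ValueError(f"trained/untrained share transitions: {shared}")


def _transition_set(seqs) -> set[tuple[Chord, Chord]]:
    return set(itertools.chain.from_iterable(s.transitions for s in seqs))


def _chord_set(seqs) -> set[Chord]:
    return set(itertools.chain.from_iterable(s.chords for s in seqs))


def partition_objective(
    trained, untrained
) -> tuple[int, float]:
    """Lexicographic objective for a candidate partition.

    First key: number of chords shared between the trained and untrained
    chord sets (minimised). Second key: L1 distance between the per-finger
    press frequency distributions of the two sets, each normalised to sum
    to 1 (minimised).
    """
    shared = len(_chord_set(trained) & _chord_set(untrained))
    ft = np.sum([s.finger_counts() for s in trained], axis=0).astype(float)
    fu = np.sum([s.finger_counts() for s in untrained], axis=0).astype(float)
    ft /= ft.sum()
    fu /= fu.sum()
    return shared, float(np.abs(ft - fu).sum())


def partition_configurations(
    sequences: list[Sequence],
    seed: int = 0,
    n_trained: int = 3,
    n_untrained: int = 6,
    label: str = "A",
    exhaustive_cap: int = 20_000,
    n_restarts: int = 500,
) -> Configuration:
    """Split a sequence pool into trained/untrained sets.

    Hard constraint: no ordered chord transition appears in both sets.
    Among feasible partitions the objective minimised is lexicographic:
    chord overlap first, then finger-frequency mismatch (see
    :func:`partition_objective`).

    When the number of candidate trained subsets is at most
    ``exhaustive_cap`` the search over trained subsets is exhaustive;
    otherwise ``n_restarts`` seeded random trained subsets are tried. For
    each trained candidate, the untrained complement pool (sequences
    transition-disjoint from the trained set) is searched exhaustively when
    small, otherwise greedily by incremental objective. Deterministic given
    ``seed``.
    """
    pool = sorted(set(sequences))
    rng = random.Random(seed)
    n = len(pool)
    n_combos = _ncr(n, n_trained)
    if n_combos <= exhaustive_cap:
        trained_candidates = itertools.combinations(pool, n_trained)
    else:
        trained_candidates = (
            tuple(sorted(rng.sample(pool, n_trained))) for _ in range(n_restarts)
        )

    best: tuple | None = None
    best_obj = None
    for trained in trained_candidates:
        t_trans = _transition_set(trained)
        avail = [
            s
            for s in pool
            if s not in trained and not (set(s.transitions) & t_trans)
        ]
        if len(avail) < n_untrained:
            continue
        untrained = _pick_untrained(
            trained, avail, n_untrained, exhaustive_cap, rng
        )
        obj = partition_objective(trained, untrained)
        if best_obj is None or obj < best_obj:
            best_obj, best = obj, (trained, untrained)
    if best is None:
        raise ValueError(
            "no transition-disjoint partition exists in the given pool"
        )
    trained, untrained = best
    return Configuration(tuple(trained), tuple(untrained), label=label)


def _pick_untrained(trained, avail, k, cap, rng):
    if _ncr(len(avail), k) <= cap:
        return min(
            itertools.combinations(avail, k),
            key=lambda u: partition_objective(trained, u),
        )
    # greedy: grow the set by the sequence with the best incremental objective
    chosen: list[Sequence] = []
    remaining = list(avail)
    while len(chosen) < k:
        nxt = min(
            remaining,
            key=lambda s: partition_objective(trained, chosen + [s]),
        )
        chosen.append(nxt)
        remaining.remove(nxt)
    return tuple(chosen)


def _ncr(n: int, r: int) -> int:
    import math

    return math.comb(n, r) if n >= r else 0


# ---------------------------------------------------------------------------
# Inter-trial interval sampler
# ---------------------------------------------------------------------------


class TruncExpITI:
    """Truncated-exponential inter-trial-interval sampler.

    The rate is calibrated by numeric root-finding so that the mean of the
    exponential truncated to ``[lower, upper]`` equals ``target_mean``
    (defaults: mean 7.4 s on [6.0, 9.2] s). Raises if the target mean is
    outside the achievable open interval (lower, (lower+upper)/2).
    """

    def __init__(
        self,
        lower: float = 6.0,
        upper: float = 9.2,
        target_mean: float = 7.4,
    ) -> None:
        if not lower < target_mean < (lower + upper) / 2.0:
            raise ValueError(
                f"target mean {target_mean} not achievable on "
                f"[{lower}, {upper}] by a truncated exponential"
            )
        self.lower, self.upper, self.target_mean = lower, upper, target_mean
        self.rate = optimize.brentq(
            lambda lam: self.truncated_mean(lam) - target_mean, 1e-9, 50.0
        )
        self._dist = stats.truncexpon(
            b=(upper - lower) * self.rate, loc=lower, scale=1.0 / self.rate
        )

    def truncated_mean(self, rate: float) -> float:
        """Closed-form mean of Exp(rate) truncated to [lower, upper]."""
        a, b = self.lower, self.upper
        ea, eb = np.exp(-rate * a), np.exp(-rate * b)
        return 1.0 / rate + (a * ea - b * eb) / (ea - eb)

    def truncated_mean_quadrature(self, rate: float) -> float:
        """Quadrature check of the truncated mean (independent of the
        closed form used for calibration)."""
        a, b = self.lower, self.upper
        z = np.exp(-rate * a) - np.exp(-rate * b)
        val, _ = integrate.quad(lambda x: x * rate * np.exp(-rate * x), a, b)
        return val / z

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw ITI(s) in seconds; every draw lies in [lower, upper]."""
        return self._dist.rvs(size=size, random_state=rng)


def sample_iti(rng: np.random.Generator, size: int | None = None):
    """Draw from the default calibrated ITI distribution (7.4 s mean,
    truncated to [6.0, 9.2] s)."""
    return _default_iti().sample(rng, size=size)


_ITI_CACHE: dict[tuple, TruncExpITI] = {}


def _default_iti() -> TruncExpITI:
    key = (6.0, 9.2, 7.4)
    if key not in _ITI_CACHE:
        _ITI_CACHE[key] = TruncExpITI(*key)
    return _ITI_CACHE[key]


# ---------------------------------------------------------------------------
# Session design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSlot:
    run: int
    sequence_id: int
    trained: bool
    onset: float
    iti: float
    duration: float


@dataclass
class SessionDesign:
    """A full scanner-session trial schedule.

    ``trials`` is ordered by run then onset. ``sequence_ids`` maps the
    integer ids used in the schedule to the :class:`Sequence` objects tested
    this session (2 trained + 2 untrained under defaults).
    """

    runs: int
    trials: list[TrialSlot]
    beat: float
    sequence_ids: dict[int, Sequence]
    trained_ids: frozenset[int]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def prescribed_mt(self) -> float:
        """Movement time prescribed by the pacing beat: 4 intervals/trial."""
        return 4 * self.beat

    def run_trials(self, run: int) -> list[TrialSlot]:
        return [t for t in self.trials if t.run == run]

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type,
        sequence_id, run)."""
        return pd.DataFrame(
            {
                "onset": [t.onset for t in self.trials],
                "duration": [t.duration for t in self.trials],
                "trial_type": [
                    "trained" if t.trained else "untrained" for t in self.trials
                ],
                "sequence_id": [t.sequence_id for t in self.trials],
                "run": [t.run for t in self.trials],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "runs": self.runs,
                "beat": self.beat,
                "sequences": {
                    str(k): str(v) for k, v in self.sequence_ids.items()
                },
                "trained_ids": sorted(self.trained_ids),
                "trials": [vars(t) for t in self.trials],
            },
            indent=1,
        )


def untrained_pair_for_session(session: int, n_untrained: int = 6):
    """Deterministic cycling of untrained-sequence pairs across sessions.

    With 6 untrained sequences there are 3 disjoint pairs; sessions 0/3/6
    test pair 0, sessions 1/4 pair 1, sessions 2/5 pair 2.
    """
    n_pairs = n_untrained // 2
    p = session % n_pairs
    return (2 * p, 2 * p + 1)


def build_session_design(
    config: Configuration,
    n_tested_trained: int = 2,
    n_tested_untrained: int = 2,
    runs: int = 5,
    trials_per_seq_per_run: int = 8,
    seed: int = 0,
    session: int = 0,
    beat: float = 0.7,
    trial_duration: float = 6.6,
    stretch_every: int = 8,
    stretch_duration: float = 6.0,
    iti: TruncExpITI | None = None,
    max_retries: int = 1000,
) -> SessionDesign:
    """Schedule one scanner session.

    Under the defaults: 4 tested sequences x 8 trials x 5 runs = 160 trials.
    Within each run trial order is a seeded shuffle re-drawn (with an
    incremented seed) until no two consecutive trials share a sequence id.
    The trial window is 6.6 s (1 s fixation + 3 preparation beats + 5
    execution beats at 0.7 s); a 6 s stretch pause follows every 8 trials.

    Which 2 of the 3 trained sequences are tested is a seeded draw (the
    A1/A2 subgrouping); the untrained pair follows the deterministic
    across-session cycling of :func:`untrained_pair_for_session`.
    """
    rng = np.random.default_rng(seed)
    iti = iti or _default_iti()

    tr_idx = sorted(
        rng.choice(len(config.trained), size=n_tested_trained, replace=False)
    )
    un_start = untrained_pair_for_session(session, len(config.untrained))
    un_idx = [i % len(config.untrained) for i in un_start][:n_tested_untrained]
    tested = [config.trained[i] for i in tr_idx] + [
        config.untrained[i] for i in un_idx
    ]
    sequence_ids = {i: s for i, s in enumerate(tested)}
    trained_ids = frozenset(range(len(tr_idx)))

    trials: list[TrialSlot] = []
    for run in range(runs):
        order = _run_order(
            len(tested), trials_per_seq_per_run, rng, max_retries
        )
        t = 0.0
        for k, sid in enumerate(order):
            gap = float(iti.sample(rng))
            trials.append(
                TrialSlot(
                    run=run,
                    sequence_id=sid,
                    trained=sid in trained_ids,
                    onset=t,
                    iti=gap,
                    duration=trial_duration,
                )
            )
            t += trial_duration + gap
            if stretch_every and (k + 1) % stretch_every == 0:
                t += stretch_duration
    return SessionDesign(
        runs=runs,
        trials=trials,
        beat=beat,
        sequence_ids=sequence_ids,
        trained_ids=trained_ids,
    )


def _run_order(n_seq, reps, rng, max_retries):
    """Random order of n_seq ids x reps with no adjacent repeats.

    Seeded greedy: each slot draws uniformly among ids with remaining
    trials, excluding the previous id, except that an id whose remaining
    count saturates the remaining slots (2r - 1 >= slots left) is forced.
    Restarts on the rare dead end.
    """
    for _ in range(max_retries):
        remaining = np.full(n_seq, reps)
        order: list[int] = []
        prev = -1
        ok = True
        for slot in range(n_seq * reps):
            left = n_seq * reps - slot
            allowed = [i for i in range(n_seq) if remaining[i] > 0 and i != prev]
            if not allowed:
                ok = False
                break
            forced = [i for i in allowed if 2 * remaining[i] - 1 >= left]
            pick = int(rng.choice(forced if forced else allowed))
            order.append(pick)
            remaining[pick] -= 1
            prev = pick
        if ok:
            return order
    raise RuntimeError(
        f"could not schedule a run without adjacent repeats in "
        f"{max_retries} attempts"
    )
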