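"""Trial sequences for behavioral sessions and event-related scanning runs.

Scanner runs are *history balanced* one trial back: across the run, every
ordered pair of conditions (including self-succession) occurs equally often
as a (previous, current) transition, so that each trial is equally likely to
be preceded by any condition.  The sequence is realised as a randomized
Eulerian circuit on the complete transition digraph with self-loops: with
``n`` conditions repeated ``r`` times each there are ``n*r`` transitions; a
prepended initial trial balances the history of the second trial, giving
``n*r + 1`` trials in total.  Exact balance requires ``n | r``; otherwise a
best-balanced sequence (ordered-pair counts differing by at most one) is
produced and flagged.

Behavioral sessions follow the training/test conventions: pre-training test
of 240 trials over 15 signal levels (16 per level, 8 radial + 8 concentric),
training runs of 256 trials over 15 levels, post-training test of 240 trials
over 16 levels.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RunDesign", "build_run", "build_behavioral_session", "build_letter_stream",
    "PRE_TEST_LEVELS", "POST_TEST_LEVELS", "TRAINING_LEVELS",
    "SCAN_LEVELS_YOUNG", "SCAN_LEVELS_OLDER", "scan_conditions",
]

PRE_TEST_LEVELS = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 60, 70, 85, 100)
TRAINING_LEVELS = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75)
POST_TEST_LEVELS = (0, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75)
SCAN_LEVELS_YOUNG = (0, 25, 35, 50, 70, 85, 100)
SCAN_LEVELS_OLDER = (0, 30, 50, 70, 100)


def scan_conditions(group: str) -> list[str]:
    """Scanner condition labels for a group: one per signal level plus fixation."""
    levels = {"young": SCAN_LEVELS_YOUNG, "older": SCAN_LEVELS_OLDER}.get(group)
    if levels is None:
        raise ValueError(f"unknown group {group!r}")
    return [f"s{lev}" for lev in levels] + ["fixation"]


@dataclass
class RunDesign:
    """One event-related run: ordered condition labels plus timing constants."""

    conditions: tuple
    trials: list                       # ordered condition labels, incl. initial
    trials_per_condition: int
    lead_fixation_s: float = 9.0
    tail_fixation_s: float = 9.0
    trial_duration_s: float = 3.0
    tr_s: float = 1.5
    exactly_balanced: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def initial_trial(self) -> str:
        return self.trials[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        return (self.lead_fixation_s + self.n_trials * self.trial_duration_s
                + self.tail_fixation_s)

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    def onsets(self) -> np.ndarray:
        """Trial onset times in seconds from run start."""
        return self.lead_fixation_s + self.trial_duration_s * np.arange(self.n_trials)

    def transition_counts(self) -> dict:
        counts = {(a, b): 0 for a in self.conditions for b in self.conditions}
        for prev, cur in zip(self.trials[:-1], self.trials[1:]):
            counts[(prev, cur)] += 1
        return counts

    def to_events(self) -> pd.DataFrame:
        """BIDS-events-style table: onset, duration, condition (+metadata)."""
        df = pd.DataFrame({
            "onset": self.onsets(),
            "duration": self.trial_duration_s,
            "condition": self.trials,
        })
        for k, v in self.meta.items():
            if isinstance(v, (list, np.ndarray)) and len(v) == len(df):
                df[k] = v
        return df


def _eulerian_circuit(n: int, edges_per_pair: np.ndarray,
                      rng: np.random.Generator) -> list[int]:
    """Random Eulerian circuit on a digraph given an (n, n) edge-multiplicity
    matrix with equal in/out degree per node.  Hierholzer with shuffled
    outgoing edges."""
    adj = []
    for a in range(n):
        out = np.repeat(np.arange(n), edges_per_pair[a])
        rng.shuffle(out)
        adj.append(list(out))
    start = int(rng.integers(n))
    stack, circuit = [start], []
    ptr = [0] * n
    while stack:
        v = stack[-1]
        if ptr[v] < len(adj[v]):
            stack.append(adj[v][ptr[v]])
            ptr[v] += 1
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def build_run(conditions, reps: int = 16, seed: int | None = None,
              **timing) -> RunDesign:
    """Build a history-balanced run of ``len(conditions) * reps + 1`` trials.

    Each condition occurs exactly ``reps`` times after the initial trial.
    Ordered-pair transition counts are all equal to ``reps / n`` when ``n``
    divides ``reps``; otherwise extra transitions are spread so that counts
    differ by at most one (``exactly_balanced`` is then False and the run is
    flagged in the log).
    """
    conditions = tuple(conditions)
    n = len(conditions)
    if n < 2:
        raise ValueError("need at least 2 conditions")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    k, extra = divmod(reps, n)
    mult = np.full((n, n), k, dtype=int)
    if extra:
        # add `extra` permutation layers (circulant shifts): each layer adds
        # one edge per node in and out, and distinct shifts never stack on a
        # pair, keeping max - min at 1
        shifts = np.arange(n) if k > 0 else np.arange(1, n)
        rng.shuffle(shifts)
        chosen = list(shifts[:extra])
        if k == 0 and not any(np.gcd(int(s), n) == 1 for s in chosen):
            # guarantee strong connectivity when there is no uniform layer
            coprime = [s for s in shifts if np.gcd(int(s), n) == 1]
            chosen[0] = coprime[0]
        offset = int(rng.integers(n))  # decouple shift pattern from labels
        for s in chosen:
            for a in range(n):
                mult[(a + offset) % n, (a + offset + s) % n] += 1
        logger.info(
            "exact one-back balance infeasible (reps=%d, n=%d): "
            "transition counts %d/%d", reps, n, k, k + 1)
    circuit = _eulerian_circuit(n, mult, rng)
    assert len(circuit) == n * reps + 1
    trials = [conditions[i] for i in circuit]
    return RunDesign(conditions=conditions, trials=trials,
                     trials_per_condition=reps,
                     exactly_balanced=(extra == 0), **timing)


def _alternating_split(counts, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split per-level counts into (radial, concentric) with equal totals.

    Even counts split evenly; odd counts alternate which category gets the
    extra trial, in randomized order, so the session totals balance.
    """
    out = [None] * len(counts)
    odd_idx = [i for i, c in enumerate(counts) if c % 2]
    if len(odd_idx) % 2:
        raise ValueError("odd number of odd-count levels cannot balance")
    flip = rng.permutation(len(odd_idx)) % 2
    for j, i in enumerate(odd_idx):
        c = counts[i]
        r = c // 2 + int(flip[j])
        out[i] = (r, c - r)
    for i, c in enumerate(counts):
        if out[i] is None:
            out[i] = (c // 2, c // 2)
    return out


def build_behavioral_session(kind: str, group: str = "young",
                             seed: int | None = None) -> pd.DataFrame:
    """Trial table for a lab session: pre_test, training (one run), post_test.

    Columns: trial, signal_level, category; stimulus duration (300 ms) and
    the per-level category allocation are recorded as DataFrame attrs.
    """
    if group not in ("young", "older"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    if kind == "pre_test":
        levels, counts = PRE_TEST_LEVELS, [16] * len(PRE_TEST_LEVELS)
    elif kind == "post_test":
        levels, counts = POST_TEST_LEVELS, [15] * len(POST_TEST_LEVELS)
    elif kind == "training":
        # 256 trials over 15 levels: middle level gets 18, the rest 17
        levels = TRAINING_LEVELS
        counts = [17] * len(levels)
        counts[len(levels) // 2] += 1
        logger.info("training run: unequal per-level counts %s", counts)
    else:
        raise ValueError(f"unknown session kind {kind!r}")
    splits = _alternating_split(counts, rng)
    rows = []
    for lev, (n_rad, n_con) in zip(levels, splits):
        rows += [(lev, "radial")] * n_rad + [(lev, "concentric")] * n_con
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order],
                      columns=["signal_level", "category"])
    df.insert(0, "trial", np.arange(len(df)))
    df.attrs.update(kind=kind, group=group, stimulus_duration_ms=300,
                    feedback=(kind == "training"))
    return df


_ALPHABET = string.ascii_uppercase


def build_letter_stream(run: RunDesign, target_prob: float = 0.15,
                        seed: int | None = None,
                        interval_s: float = 0.5,
                        letter_duration_s: float = 0.08) -> pd.DataFrame:
    """Letter stream for the fixation-task control runs.

    A capital letter appears every 500 ms throughout the run (stimulus and
    fixation conditions alike) for 80 ms; one target letter per run, shown
    with probability ``target_prob`` per slot, other slots drawing uniformly
    from the remaining Roman alphabet.
    """
    rng = np.random.default_rng(seed)
    target = _ALPHABET[rng.integers(26)]
    others = [c for c in _ALPHABET if c != target]
    onsets = np.arange(0.0, run.duration_s, interval_s)
    is_target = rng.random(len(onsets)) < target_prob
    letters = [target if t else others[rng.integers(25)] for t in is_target]
    df = pd.DataFrame({
        "onset": onsets,
        "duration": letter_duration_s,
        "letter": letters,
        "is_target": is_target,
    })
    df.attrs.update(target_letter=target, target_prob=target_prob)
    return df
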