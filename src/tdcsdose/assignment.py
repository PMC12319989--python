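"""Covariate-adaptive minimization of baseline typing speed.

Allocation rule: the first three subjects go sequentially to the three arms;
each later subject is placed in whichever arm yields the smallest
cross-group imbalance of typing speed (WPM) over the three candidate
placements, where imbalance is the variance across the group means (summed
over balancing covariates; typing speed is the only one here).  Ties break
deterministically to the smallest group, then the lowest group index; a
seeded random tie-break is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ScoringError(ValueError):
    pass


def typing_wpm(typing_log: pd.DataFrame, n_words: int = 63,
               per_chars: float | None = None) -> float:
    """Typing speed in words per minute from a typing-test log.

    WPM = ``n_words`` / elapsed minutes, where elapsed time is the timestamp
    of the final required press.  Set ``per_chars`` (e.g. total characters)
    to use the chars/5 convention instead of the explicit word count.
    """
    if typing_log.empty or "t_ms" not in typing_log:
        raise ScoringError("typing log has no completion timestamp")
    elapsed_min = float(typing_log["t_ms"].max()) / 60000.0
    if elapsed_min <= 0:
        raise ScoringError("non-positive elapsed time")
    words = per_chars / 5.0 if per_chars is not None else float(n_words)
    return words / elapsed_min


def group_variance(speeds) -> float:
    """Sample variance (ddof=1); empty and singleton groups count as 0."""
    a = np.asarray(speeds, dtype=float)
    if a.size < 2:
        return 0.0
    return float(np.var(a, ddof=1))


def summed_variance(groups: list[list[float]]) -> float:
    """Total within-group variance (diagnostic; NOT the allocation objective —
    minimizing it clusters similar speeds together and anti-balances)."""
    return sum(group_variance(g) for g in groups)


def allocation_imbalance(groups: list[list[float]]) -> float:
    """Allocation objective: variance across the group mean speeds.

    Placing each newcomer to minimize this keeps the arms' mean WPM close,
    which is what minimization is for; fewer than two non-empty groups give
    an imbalance of 0.
    """
    means = [float(np.mean(g)) for g in groups if len(g) > 0]
    if len(means) < 2:
        return 0.0
    return float(np.var(means))


@dataclass
class AssignmentState:
    """Roster of the three arms plus a replayable assignment history."""

    groups: list = field(default_factory=lambda: [[], [], []])
    history: list = field(default_factory=list)  # (wpm, group_idx) pairs
    rng_seed: int | None = None

    @classmethod
    def fresh(cls, n_groups: int = 3, rng_seed: int | None = None):
        return cls(groups=[[] for _ in range(n_groups)], history=[],
                   rng_seed=rng_seed)

    @property
    def n_assigned(self) -> int:
        return sum(len(g) for g in self.groups)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"groups": self.groups, "history": self.history,
             "rng_seed": self.rng_seed}, indent=2))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(groups=[list(g) for g in d["groups"]],
                   history=[tuple(h) for h in d["history"]],
                   rng_seed=d.get("rng_seed"))


def assign_group(state: AssignmentState, new_wpm: float,
                 random_ties: bool = False,
                 max_group_size: int | None = None) -> tuple[int, AssignmentState]:
    """Place one subject; returns ``(group_idx, updated_state)``.

    ``max_group_size`` restricts candidate arms (used when a fixed per-arm
    sample size must be honoured); the minimization itself is unchanged.
    """
    n_groups = len(state.groups)
    candidates = [g for g in range(n_groups)
                  if max_group_size is None or len(state.groups[g]) < max_group_size]
    if not candidates:
        raise ScoringError("all groups are full")

    if state.n_assigned < n_groups:
        # sequential seeding of the first three subjects
        choice = next(g for g in range(n_groups)
                      if len(state.groups[g]) == 0 and g in candidates)
    else:
        costs = []
        for g in candidates:
            trial = [list(grp) for grp in state.groups]
            trial[g].append(new_wpm)
            costs.append(allocation_imbalance(trial))
        costs = np.asarray(costs)
        best = costs.min()
        tied = [g for g, c in zip(candidates, costs)
                if c <= best + 1e-12 * max(1.0, abs(best))]
        if len(tied) > 1 and random_ties:
            rng = np.random.default_rng(
                None if state.rng_seed is None
                else state.rng_seed + state.n_assigned)
            choice = int(rng.choice(tied))
        else:
            # smallest current group, then lowest index
            choice = min(tied, key=lambda g: (len(state.groups[g]), g))

    new_groups = [list(g) for g in state.groups]
    new_groups[choice].append(new_wpm)
    return choice, AssignmentState(
        groups=new_groups,
        history=state.history + [(new_wpm, choice)],
        rng_seed=state.rng_seed,
    )


def replay(history, n_groups: int = 3) -> AssignmentState:
    """Rebuild a state from its history; assignments must reproduce exactly."""
    state = AssignmentState.fresh(n_groups)
    for wpm, recorded in history:
        choice, state = assign_group(state, wpm)
        if choice != recorded:
            raise ScoringError(
                f"history does not replay: expected group {recorded}, "
                f"got {choice}")
    return state
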