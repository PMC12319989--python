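"""Sequence-learning performance scoring and attentiveness exclusions.

The behavioral outcome is NCS — the number of correct sequences per 10-s
trial, where a correct sequence is 5 consecutive keypresses matching the
target with no errors.  The task display advances on every press regardless
of correctness, so presses are partitioned into fixed consecutive 5-press
blocks; an incomplete trailing block never counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import DEFAULT_SEQUENCE, N_TRIALS, TRIAL_S


class StructuralError(ValueError):
    pass


@dataclass
class TrialScore:
    trial_idx: int
    ncs: int
    n_presses: int
    accuracy: float      # fraction of presses matching the target position
    n_correct: int
    max_gap_s: float     # longest wait for a press (incl. leading gap)


@dataclass
class BehaviorOutcome:
    mean_ncs: float
    first_trial_ncs: float
    last10_mean_ncs: float
    gain: float
    excluded: bool = False
    exclusion_reasons: tuple = ()


def score_trial(keys, t_ms=None, target=DEFAULT_SEQUENCE,
                trial_idx: int = 1, trial_s: float = TRIAL_S) -> TrialScore:
    """Score one trial's ordered keypresses against the target sequence.

    ``ncs`` counts complete 5-press blocks whose presses all match the
    target; ``accuracy`` is per-press correctness at the advancing sequence
    position; ``max_gap_s`` includes the wait from trial start to the first
    press (a trial with no presses has max_gap_s = trial_s).
    """
    keys = np.asarray(keys, dtype=int)
    n = keys.size
    target = np.asarray(target, dtype=int)
    m = target.size
    if n == 0:
        return TrialScore(trial_idx, 0, 0, 0.0, 0, float(trial_s))

    correct = keys == target[np.arange(n) % m]
    n_blocks = n // m
    ncs = int(correct[: n_blocks * m].reshape(n_blocks, m).all(axis=1).sum())

    if t_ms is None:
        max_gap = 0.0
    else:
        t = np.asarray(t_ms, dtype=float) / 1000.0
        gaps = np.diff(np.concatenate([[0.0], t]))
        max_gap = float(gaps.max())
    return TrialScore(trial_idx, ncs, n, float(correct.mean()),
                      int(correct.sum()), max_gap)


def score_subject(log: pd.DataFrame, target=DEFAULT_SEQUENCE,
                  n_trials: int = N_TRIALS,
                  trial_s: float = TRIAL_S) -> list[TrialScore]:
    """Score all trials of one subject's log; missing trials score as empty."""
    scores = []
    for trial in range(1, n_trials + 1):
        sub = log[log["trial"] == trial].sort_values("press_idx")
        scores.append(score_trial(sub["key"].to_numpy(),
                                  sub["t_ms"].to_numpy(), target,
                                  trial_idx=trial, trial_s=trial_s))
    return scores


def apply_exclusions(scores: list[TrialScore],
                     accuracy_threshold: float = 0.5,
                     gap_threshold_s: float = 3.0,
                     gap_trials_threshold: int = 3) -> tuple[bool, tuple]:
    """Preregistered attentiveness exclusions.

    A subject is excluded if pooled keypress accuracy is below 50%, if
    pauses longer than 3 s occur consistently (in at least
    ``gap_trials_threshold`` distinct trials), or if any trial has no
    presses at all.  All triggered reasons are reported.
    """
    reasons = []
    total = sum(s.n_presses for s in scores)
    pooled_acc = (sum(s.n_correct for s in scores) / total) if total else 0.0
    if pooled_acc < accuracy_threshold:
        reasons.append("accuracy")
    if any(s.n_presses == 0 for s in scores):
        reasons.append("empty trial")
    n_gap_trials = sum(1 for s in scores
                       if s.n_presses > 0 and s.max_gap_s > gap_threshold_s)
    if n_gap_trials >= gap_trials_threshold:
        reasons.append("pauses")
    return bool(reasons), tuple(reasons)


def behavior_outcomes(scores: list[TrialScore],
                      n_trials: int = N_TRIALS) -> BehaviorOutcome:
    """Per-subject summary: overall mean NCS, first trial, last-10 mean, gain."""
    if len(scores) != n_trials:
        raise StructuralError(f"expected {n_trials} trials, got {len(scores)}")
    ncs = np.array([s.ncs for s in scores], dtype=float)
    excluded, reasons = apply_exclusions(scores)
    return BehaviorOutcome(
        mean_ncs=float(ncs.mean()),
        first_trial_ncs=float(ncs[0]),
        last10_mean_ncs=float(ncs[-10:].mean()),
        gain=float(ncs[-10:].mean() - ncs[0]),
        excluded=excluded,
        exclusion_reasons=reasons,
    )


def score_cohort_behavior(keypress_logs: pd.DataFrame,
                          target=DEFAULT_SEQUENCE,
                          task_id: str = "L:S1") -> pd.DataFrame:
    """Score every subject in a pooled keypress log CSV.

    Returns one row per subject: mean_ncs, first_trial_ncs, last10_mean_ncs,
    gain, excluded, exclusion_reasons.
    """
    logs = keypress_logs[keypress_logs["task_id"] == task_id]
    rows = []
    for sid, sub in logs.groupby("subject_id", sort=True):
        scores = score_subject(sub, target)
        out = behavior_outcomes(scores)
        rows.append({"subject_id": sid, "mean_ncs": out.mean_ncs,
                     "first_trial_ncs": out.first_trial_ncs,
                     "last10_mean_ncs": out.last10_mean_ncs,
                     "gain": out.gain, "excluded": out.excluded,
                     "exclusion_reasons": ";".join(out.exclusion_reasons)})
    return pd.DataFrame(rows)
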