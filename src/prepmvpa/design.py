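"""Delayed go/no-go finger-press experiment designs.

A session consists of functional runs of event-related trials. Each trial
shows an instructing cue (which finger to press, or which finger sequence),
holds a variable preparation delay, and then either triggers (go) or
withholds (no-go) the movement. The trial-type inventory, delay / ITI /
go-probability distributions and run structure follow the delayed
single-finger-press paradigm this package analyzes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialSpec",
    "RunDesign",
    "ExperimentDesign",
    "generate_experiment",
    "FINGERS",
    "CONDITIONS",
    "PREP_DURATIONS",
    "PREP_PROBS",
    "ITIS",
    "ITI_PROBS",
    "GO_PROB",
    "MOVE_PHASE",
    "REWARD_PHASE",
    "REST_PADDING",
]

#: Cued fingers, labelled by the digit shown on screen (1=thumb, 3=middle,
#: 5=little).
FINGERS = (1, 3, 5)

#: Labels of the six analyzed conditions: 3 fingers x {planning, execution}.
CONDITIONS = ("plan:1", "plan:3", "plan:5", "exec:1", "exec:3", "exec:5")

#: Preparation-delay support (s) and probabilities.
PREP_DURATIONS = (4.0, 6.0, 8.0)
PREP_PROBS = (0.56, 0.30, 0.14)

#: Intertrial-interval support (s) and probabilities.  The proportions follow
#: a halving pattern and sum to one.
ITIS = (1.0, 2.0, 4.0, 8.0, 16.0)
ITI_PROBS = (0.52, 0.26, 0.13, 0.06, 0.03)

GO_PROB = 0.6
MOVE_PHASE = 2.5  # movement (or stay) phase duration, s
REWARD_PHASE = 0.5  # reward phase duration, s
REST_PADDING = 10.0  # rest at the start and end of each run, s


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the delayed-movement task.

    Parameters
    ----------
    finger : int
        Cued digit, one of ``FINGERS`` (1=thumb, 3=middle, 5=little).
    is_sequence : bool
        Whether this is a multifinger-sequence trial type (modeled in the
        design and GLM, but not analyzed multivariately) rather than a
        repeated single-finger press.
    prep_duration : float
        Preparation (delay) phase duration in seconds, one of
        ``PREP_DURATIONS``.
    is_go : bool
        Whether the movement was triggered (go) or withheld (no-go).
    iti : float
        Intertrial interval following the reward phase, seconds.
    onset : float
        Instructing-cue onset, seconds from run start.
    """

    finger: int
    is_sequence: bool
    prep_duration: float
    is_go: bool
    iti: float
    onset: float

    @property
    def go_time(self) -> float:
        """Onset of the movement (go/no-go cue) phase."""
        return self.onset + self.prep_duration

    @property
    def end(self) -> float:
        """End of the trial including its ITI."""
        return self.go_time + MOVE_PHASE + REWARD_PHASE + self.iti

    @property
    def trial_type(self) -> str:
        """Label of the trial type, e.g. ``'1'`` or ``'s1'``."""
        return f"s{self.finger}" if self.is_sequence else f"{self.finger}"


@dataclass(frozen=True)
class RunDesign:
    """Ordered trials of a single functional run."""

    trials: tuple[TrialSpec, ...]
    rest_padding: float = REST_PADDING

    @property
    def duration(self) -> float:
        """Run duration in seconds (last trial end plus final rest)."""
        last = self.trials[-1]
        return last.go_time + MOVE_PHASE + REWARD_PHASE + last.iti + self.rest_padding

    def n_volumes(self, tr: float) -> int:
        return int(math.ceil(self.duration / tr))


@dataclass(frozen=True)
class ExperimentDesign:
    """A session of functional runs sharing one trial inventory."""

    runs: tuple[RunDesign, ...]
    trials_per_run: int
    rest_padding: float = REST_PADDING
    tr: float = 1.0

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _run_trial_inventory(reps_per_type: int) -> list[tuple[int, bool, bool]]:
    """(finger, is_sequence, is_go) inventory for one run.

    Each of the 6 trial types (3 fingers x {single, sequence}) is repeated
    ``reps_per_type`` times with a fixed go/no-go split that realizes the 60%
    go probability (3 go + 2 no-go at the standard 5 repetitions).
    """
    n_go = int(round(GO_PROB * reps_per_type))
    n_go = min(max(n_go, 1), reps_per_type)
    inventory = []
    for finger in FINGERS:
        for is_sequence in (False, True):
            for k in range(reps_per_type):
                inventory.append((finger, is_sequence, k < n_go))
    return inventory


def generate_experiment(
    n_runs: int,
    seed: int | np.random.Generator,
    *,
    reps_per_type: int = 5,
    rest_padding: float = REST_PADDING,
    tr: float = 1.0,
) -> ExperimentDesign:
    """Generate a randomized delayed go/no-go experiment design.

    Every run contains ``6 * reps_per_type`` trials (30 at the default of 5
    repetitions per trial type), in uniformly random order, with exact
    per-type go/no-go counts and delays / ITIs sampled independently from
    the task distributions.

    Parameters
    ----------
    n_runs : int
        Number of functional runs (>= 1).
    seed : int or numpy Generator
        Randomness source; a fixed integer reproduces the design exactly.
    reps_per_type : int, optional
        Repetitions of each of the 6 trial types per run.  The default (5)
        yields the standard 30-trial run; smaller values give shortened runs
        for quick simulations.
    rest_padding : float, optional
        Rest at the start and end of each run, seconds.
    tr : float, optional
        Repetition time of the accompanying acquisition, seconds.

    Returns
    -------
    ExperimentDesign
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if reps_per_type < 1:
        raise ValueError(f"reps_per_type must be >= 1, got {reps_per_type}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    runs = []
    inventory = _run_trial_inventory(reps_per_type)
    n_trials = len(inventory)
    for _ in range(n_runs):
        order = rng.permutation(n_trials)
        preps = rng.choice(PREP_DURATIONS, size=n_trials, p=PREP_PROBS)
        itis = rng.choice(ITIS, size=n_trials, p=ITI_PROBS)
        trials = []
        onset = rest_padding
        for i, idx in enumerate(order):
            finger, is_seq, is_go = inventory[idx]
            trial = TrialSpec(
                finger=finger,
                is_sequence=is_seq,
                prep_duration=float(preps[i]),
                is_go=is_go,
                iti=float(itis[i]),
                onset=onset,
            )
            trials.append(trial)
            onset = trial.end
        runs.append(RunDesign(trials=tuple(trials), rest_padding=rest_padding))
    return ExperimentDesign(
        runs=tuple(runs),
        trials_per_run=n_trials,
        rest_padding=rest_padding,
        tr=tr,
    )
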