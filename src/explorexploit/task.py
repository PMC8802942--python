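"""Task data model for the four-cycle object search task.

A session consists of *problems*, each played over four *cycles* of
trials.  On every trial the animal touches one of four objects shown at
four display locations.  For each problem one or two objects are targets:
touching a target not yet selected in the current cycle is correct and
rewarded, and a cycle ends as soon as every target has been selected
once.  Cycle 1 is the *explore* cycle (targets unknown, discovered by
sampling); cycles 2-4 are *exploit* cycles (targets known, reselected
for further reward).

This module defines the trial/problem records, response-type
classification, the problem-exclusion rule, and closed-form chance
expectations for the search behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

N_OBJECTS = 4
N_LOCATIONS = 4
N_CYCLES = 4

#: a problem is excluded when any single cycle contains this many or more
#: failed (no-response or aborted) trials
EXCLUSION_FAILED_TRIALS = 6


class MalformedTrialError(ValueError):
    """A trial is inconsistent with its problem's object set or arrangement."""


class ResponseType(str, Enum):
    """Classification of a single touch relative to the cycle history."""

    T = "T"                      #: correct selection of a not-yet-selected target
    NT_novel = "NT_novel"        #: nontarget not previously sampled this cycle
    NT_revisit = "NT_revisit"    #: nontarget already sampled this cycle
    T_revisit = "T_revisit"      #: target already selected this cycle (unrewarded)
    no_response = "no_response"  #: no touch registered (or trial aborted)


@dataclass
class TrialRecord:
    """One behavioral trial.

    Times are in seconds from trial start.  ``arrangement`` maps each
    object id (1-4) to the display location (1-4) it occupied on this
    trial and must be a bijection.  ``chosen_object``/``chosen_location``
    are ``None`` on no-response trials; any event timestamp may be
    ``None`` on aborted trials.
    """

    session_id: str
    animal_id: str
    problem_id: str
    n_targets: int
    object_set: int
    cycle: int
    trial_in_cycle: int
    arrangement: dict[int, int]
    chosen_object: Optional[int] = None
    chosen_location: Optional[int] = None
    correct: bool = False
    rewarded: bool = False
    aborted: bool = False
    t_ch_on: Optional[float] = None
    t_go: Optional[float] = None
    t_touch: Optional[float] = None
    t_fb_on: Optional[float] = None

    def __post_init__(self) -> None:
        objs = sorted(self.arrangement)
        locs = sorted(self.arrangement.values())
        if objs != list(range(1, N_OBJECTS + 1)) or locs != list(range(1, N_LOCATIONS + 1)):
            raise MalformedTrialError(
                f"arrangement {self.arrangement!r} is not a bijection of "
                f"objects 1-{N_OBJECTS} onto locations 1-{N_LOCATIONS}"
            )
        if self.chosen_object is not None:
            loc = self.arrangement[self.chosen_object]
            if self.chosen_location is None:
                self.chosen_location = loc
            elif self.chosen_location != loc:
                raise MalformedTrialError(
                    f"chosen_location {self.chosen_location} inconsistent with "
                    f"arrangement (object {self.chosen_object} at {loc})"
                )
        times = [t for t in (self.t_ch_on, self.t_go, self.t_touch, self.t_fb_on)
                 if t is not None]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise MalformedTrialError("event times must be strictly increasing")

    @property
    def failed(self) -> bool:
        """True for trials with no registered choice: no-response or aborted."""
        return self.aborted or self.chosen_object is None

    def event_time(self, alignment: str) -> Optional[float]:
        return {"CH": self.t_ch_on, "FB": self.t_fb_on}[alignment]


@dataclass
class ProblemRecord:
    """One problem: a fixed target assignment played over four cycles."""

    problem_id: str
    n_targets: int
    object_set: int
    target_objects: frozenset[int]
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.target_objects = frozenset(self.target_objects)
        if len(self.target_objects) != self.n_targets:
            raise ValueError("target_objects size must equal n_targets")
        if not self.target_objects <= set(range(1, N_OBJECTS + 1)):
            raise ValueError("target ids must lie in 1-4")

    def cycles(self) -> dict[int, list[TrialRecord]]:
        out: dict[int, list[TrialRecord]] = {}
        for t in self.trials:
            out.setdefault(t.cycle, []).append(t)
        return out


def classify_response(
    trial: TrialRecord,
    cycle_history: Sequence[TrialRecord],
    targets: Iterable[int],
) -> ResponseType:
    """Classify one touch against the history of the same cycle.

    ``cycle_history`` holds the earlier trials of the same problem and
    cycle, in order.  A touched object is ``T`` when it is a target not
    yet selected this cycle, ``T_revisit`` when a target already selected
    this cycle (possible only with two targets), and ``NT_novel`` /
    ``NT_revisit`` for nontargets depending on whether the object has
    already been sampled this cycle.
    """
    targets = frozenset(targets)
    if not targets <= set(trial.arrangement):
        raise MalformedTrialError(f"targets {set(targets)} outside trial's object set")
    if trial.failed:
        return ResponseType.no_response
    obj = trial.chosen_object
    if obj not in trial.arrangement:
        raise MalformedTrialError(f"chosen object {obj} outside trial's object set")
    sampled = {t.chosen_object for t in cycle_history if not t.failed}
    selected_targets = sampled & targets
    if obj in targets:
        return ResponseType.T_revisit if obj in selected_targets else ResponseType.T
    return ResponseType.NT_revisit if obj in sampled else ResponseType.NT_novel


def classify_problem(problem: ProblemRecord) -> list[ResponseType]:
    """Response type of every trial of a problem, in order."""
    out: list[ResponseType] = []
    history: dict[int, list[TrialRecord]] = {}
    for trial in problem.trials:
        hist = history.setdefault(trial.cycle, [])
        out.append(classify_response(trial, hist, problem.target_objects))
        hist.append(trial)
    return out


def apply_problem_exclusion(
    problems: Sequence[ProblemRecord],
) -> tuple[list[ProblemRecord], list[dict]]:
    """Drop problems with poor task focus; return (kept, exclusion log).

    A problem is excluded when the animal failed to respond (no touch, or
    trial aborted by fixation break / early release) on
    ``EXCLUSION_FAILED_TRIALS`` or more trials within a single cycle.
    Aborted trials count toward the threshold alongside explicit
    no-response trials; both indicate disengagement.  Idempotent.
    """
    kept: list[ProblemRecord] = []
    log: list[dict] = []
    for prob in problems:
        failed_per_cycle = {
            c: sum(t.failed for t in trials) for c, trials in prob.cycles().items()
        }
        bad = {c: n for c, n in failed_per_cycle.items() if n >= EXCLUSION_FAILED_TRIALS}
        if bad:
            log.append({
                "problem_id": prob.problem_id,
                "failed_trials_per_cycle": failed_per_cycle,
                "cycles_over_threshold": sorted(bad),
                "rule": "no-response/aborted trials counted jointly",
            })
        else:
            kept.append(prob)
    return kept, log


def expected_search_trials(n_objects: int, n_targets: int) -> float:
    """Expected trials for an optimal (revisit-free) random search.

    A searcher sampling objects uniformly at random without revisits
    induces a uniform random permutation of the objects; the search ends
    at the position of the last target, so the expectation is that of
    the maximum of ``n_targets`` positions drawn without replacement
    from ``1..n_objects``: ``n_targets * (n_objects + 1) / (n_targets + 1)``.

    For four objects this gives 2.50 with one target and 10/3 = 3.33
    with two.  With ``n_targets == n_objects`` every object must be
    sampled and the expectation degenerates to ``n_objects``.
    """
    if not 1 <= n_targets <= n_objects:
        raise ValueError(f"need 1 <= n_targets <= n_objects, got {n_targets}, {n_objects}")
    return float(Fraction(n_targets * (n_objects + 1), n_targets + 1))


def chance_revisit_probability(n_already_sampled: int, n_objects: int = N_OBJECTS) -> float:
    """Revisit probability of a memoryless uniform chooser.

    With ``k`` objects already sampled this cycle, a chooser ignoring
    its own history picks a previously sampled object with probability
    ``k / n_objects``: 0, 25, 50 and 75% for k = 0..3 of four objects.
    """
    if not 0 <= n_already_sampled < n_objects:
        raise ValueError(
            f"need 0 <= n_already_sampled < n_objects, got {n_already_sampled}, {n_objects}"
        )
    return n_already_sampled / n_objects


def first_target_probability(n_objects: int, n_targets: int) -> float:
    """Probability that the first object sampled is a target (n_targets / n_objects)."""
    if not 1 <= n_targets <= n_objects:
        raise ValueError(f"need 1 <= n_targets <= n_objects, got {n_targets}, {n_objects}")
    return n_targets / n_objects
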