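"""Classification of participant behavior: anchoring, adaptation, and
conclusion correctness.

A participant reports an initial sampling strategy, watches it execute one
location at a time, may deviate mid-run or add steps afterwards, and
finally accepts or rejects the given hypothesis.  Three behavioral axes
are classified:

* *anchoring* — executing the initial plan exactly, with no adjustment;
* *adaptation timing* — whether any added step interrupts the initial plan
  (encounter-conditional / area-restricted search) or waits until the plan
  completes;
* *conclusion correctness* — accepting the given hypothesis is correct
  only when the assigned dataset actually supports it; rejecting a
  supported hypothesis is a Type 1 error, accepting when the data follow
  the alternative is a Type 2 error.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulation import LogStep, ObservationLog
from .strategies import (
    SamplingStrategy,
    average_interval_discrepancy,
    classify_strategy,
    detect_magic_number,
)
from .synthetic_data import InvalidParameterError

__all__ = [
    "ParticipantRecord",
    "BehaviorSummary",
    "ClassificationUnavailable",
    "classify_adaptation",
    "conclusion_outcome",
    "cohort_summary",
    "records_to_json",
    "records_from_json",
    "convert_external_log",
]

EXPERTISE = ("expert", "novice")
CONCLUSIONS = ("accept", "reject")
CONFIDENCE = ("very", "moderately", "slightly", "not_at_all")
OUTCOMES = ("correct", "type1_error", "type2_error", "none")


class ClassificationUnavailable(ValueError):
    """The record lacks the executed log needed for adaptation analysis."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's assigned condition, plan, execution, and conclusion."""

    participant_id: str
    expertise: str = "expert"
    assigned_hypothesis: Optional[str] = None   # "given" | "alternative" | None
    initial_strategy: Optional[SamplingStrategy] = None
    executed_log: Optional[ObservationLog] = None
    conclusion: Optional[str] = None            # "accept" | "reject" | None
    confidence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.expertise not in EXPERTISE:
            raise InvalidParameterError(f"expertise must be one of {EXPERTISE}")
        if self.conclusion is not None and self.conclusion not in CONCLUSIONS:
            raise InvalidParameterError(f"conclusion must be one of {CONCLUSIONS}")
        if self.confidence is not None and self.confidence not in CONFIDENCE:
            raise InvalidParameterError(f"confidence must be one of {CONFIDENCE}")
        if self.expertise == "expert" and (
            self.assigned_hypothesis is None or self.conclusion is None
        ):
            raise InvalidParameterError(
                "expert records require assigned_hypothesis and conclusion"
            )


@dataclass(frozen=True)
class BehaviorSummary:
    anchored_no_adjustment: bool
    deviated_before_completion: bool
    completed_initial_then_added: bool
    eventually_visited_all_initial: bool
    changed_magic_number: Optional[bool]    # None when no magic number exists
    n_magic_number_changes: Optional[int]
    conclusion_outcome: str

    def __post_init__(self) -> None:
        if self.anchored_no_adjustment and (
            self.deviated_before_completion or self.completed_initial_then_added
        ):
            raise InvalidParameterError("anchored record cannot also have adjusted")
        if self.deviated_before_completion and self.completed_initial_then_added:
            raise InvalidParameterError(
                "at most one adjustment-timing flag may be set"
            )


def conclusion_outcome(record: ParticipantRecord) -> str:
    """Correctness of the accept/reject call against the assigned dataset."""
    hyp, concl = record.assigned_hypothesis, record.conclusion
    if hyp is None or concl is None:
        return "none"
    if hyp == "given":
        return "correct" if concl == "accept" else "type1_error"
    return "correct" if concl == "reject" else "type2_error"


def classify_adaptation(record: ParticipantRecord) -> BehaviorSummary:
    """Classify one record's adaptation behavior from its executed log.

    Anchoring means the executed steps match the initial plan exactly —
    same locations, same counts, no additions.  A deviation is any added
    step occurring before every planned initial step has executed; adding
    only after the plan completes counts as adjusted-after-completion.
    Magic-number changes are counted per location whose final total differs
    from the initial magic number (undefined when the initial counts were
    not constant).
    """
    if record.executed_log is None:
        raise ClassificationUnavailable(
            f"record {record.participant_id} has no executed log"
        )
    if record.initial_strategy is None:
        raise ClassificationUnavailable(
            f"record {record.participant_id} has no initial strategy"
        )
    log = record.executed_log
    plan = record.initial_strategy.initial_steps
    plan_pairs = [(s.location, s.n) for s in plan]

    executed_initial = [s for s in log.steps if s.phase == "initial"]
    executed_pairs = [(s.location, len(s.replicate_indices)) for s in executed_initial]
    has_added = any(s.phase == "added" for s in log.steps)

    anchored = (not has_added) and executed_pairs == plan_pairs

    deviated = False
    n_initial_done = 0
    for s in log.steps:
        if s.phase == "initial":
            n_initial_done += 1
        elif n_initial_done < len(plan):
            deviated = True
            break
    completed_then_added = has_added and not deviated

    visited = {s.location for s in log.steps}
    eventually_all = set(l for l, _ in plan_pairs) <= visited

    magic = detect_magic_number(record.initial_strategy)
    if magic is None:
        changed: Optional[bool] = None
        n_changes: Optional[int] = None
    else:
        totals: Counter[int] = Counter()
        for s in log.steps:
            totals[s.location] += len(s.replicate_indices)
        n_changes = sum(1 for tot in totals.values() if tot != magic)
        changed = n_changes > 0

    return BehaviorSummary(
        anchored_no_adjustment=anchored,
        deviated_before_completion=deviated,
        completed_initial_then_added=completed_then_added,
        eventually_visited_all_initial=eventually_all,
        changed_magic_number=changed,
        n_magic_number_changes=n_changes,
        conclusion_outcome=conclusion_outcome(record),
    )


def _fraction(k: int, n: int) -> float:
    return k / n if n else 0.0


def cohort_summary(
    records: Sequence[ParticipantRecord], threshold: float = 1.0
) -> dict:
    """Cohort-level counts and fractions of heuristic use, adaptation, and
    conclusion outcomes, mirroring how the behavioral findings are tallied.

    Magic-number-change rate is computed as (locations whose total count
    changed) / (all locations sampled), over records that had a magic
    number to change.
    """
    if not records:
        raise InvalidParameterError("cohort_summary requires >= 1 record")
    n = len(records)
    n_equal = 0
    magic_hist: Counter[int] = Counter()
    adaptation: dict[str, Counter] = {
        "anchored": Counter(), "completed_then_added": Counter(),
        "deviated": Counter(), "other": Counter(),
    }
    eventually_all_among_deviators = 0
    n_deviators = 0
    outcomes: Counter[str] = Counter()
    n_changes_total = 0
    n_locations_sampled = 0
    n_with_log = 0
    for rec in records:
        if rec.initial_strategy is not None:
            cls = classify_strategy(rec.initial_strategy, threshold=threshold)
            if cls.is_equal_spacing:
                n_equal += 1
            if cls.magic_number is not None:
                magic_hist[cls.magic_number] += 1
        outcomes[conclusion_outcome(rec)] += 1
        if rec.executed_log is None:
            continue
        n_with_log += 1
        summary = classify_adaptation(rec)
        hyp = rec.assigned_hypothesis or "none"
        if summary.anchored_no_adjustment:
            adaptation["anchored"][hyp] += 1
        elif summary.deviated_before_completion:
            adaptation["deviated"][hyp] += 1
            n_deviators += 1
            if summary.eventually_visited_all_initial:
                eventually_all_among_deviators += 1
        elif summary.completed_initial_then_added:
            adaptation["completed_then_added"][hyp] += 1
        else:
            adaptation["other"][hyp] += 1
        if summary.n_magic_number_changes is not None:
            n_changes_total += summary.n_magic_number_changes
            n_locations_sampled += len(
                {s.location for s in rec.executed_log.steps}
            )
    n_magic = sum(magic_hist.values())
    return {
        "n_records": n,
        "n_with_executed_log": n_with_log,
        "equal_spacing": {"count": n_equal, "fraction": _fraction(n_equal, n)},
        "magic_number": {
            "count": n_magic,
            "fraction": _fraction(n_magic, n),
            "histogram": dict(sorted(magic_hist.items())),
        },
        "adaptation": {
            key: {"count": sum(cnt.values()), "by_hypothesis": dict(cnt)}
            for key, cnt in adaptation.items()
        },
        "deviators_eventually_visiting_all": {
            "count": eventually_all_among_deviators,
            "of": n_deviators,
        },
        "conclusions": dict(outcomes),
        "magic_number_changes": {
            "count": n_changes_total,
            "locations_sampled": n_locations_sampled,
            "rate": _fraction(n_changes_total, n_locations_sampled),
        },
    }


# ---------------------------------------------------------------------------
# participant-log serialization (schema version 1)
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def _record_to_obj(rec: ParticipantRecord) -> dict:
    obj: dict = {
        "participant_id": rec.participant_id,
        "expertise": rec.expertise,
        "assigned_hypothesis": rec.assigned_hypothesis,
        "conclusion": rec.conclusion,
        "confidence": rec.confidence,
    }
    if rec.initial_strategy is not None:
        obj["initial_strategy"] = json.loads(rec.initial_strategy.to_json())
    if rec.executed_log is not None:
        obj["executed_steps"] = [
            {
                "location": s.location,
                "phase": s.phase,
                "replicate_indices": list(s.replicate_indices),
                "moisture": list(s.moisture),
                "strength": list(s.strength),
            }
            for s in rec.executed_log.steps
        ]
    return obj


def _record_from_obj(obj: dict) -> ParticipantRecord:
    strategy = None
    if "initial_strategy" in obj:
        strategy = SamplingStrategy.from_json(json.dumps(obj["initial_strategy"]))
    log = None
    if "executed_steps" in obj:
        steps = tuple(
            LogStep(
                int(s["location"]), s["phase"],
                tuple(int(i) for i in s["replicate_indices"]),
                tuple(float(v) for v in s["moisture"]),
                tuple(float(v) for v in s["strength"]),
            )
            for s in obj["executed_steps"]
        )
        log = ObservationLog(steps, cumulative=())
    return ParticipantRecord(
        participant_id=obj["participant_id"],
        expertise=obj.get("expertise", "expert"),
        assigned_hypothesis=obj.get("assigned_hypothesis"),
        initial_strategy=strategy,
        executed_log=log,
        conclusion=obj.get("conclusion"),
        confidence=obj.get("confidence"),
    )


def records_to_json(records: Sequence[ParticipantRecord]) -> str:
    return json.dumps(
        {
            "schema_version": SCHEMA_VERSION,
            "records": [_record_to_obj(r) for r in records],
        },
        indent=2,
    )


def records_from_json(text: str) -> list[ParticipantRecord]:
    obj = json.loads(text)
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise InvalidParameterError(
            f"unsupported participant-log schema version {obj.get('schema_version')}"
        )
    return [_record_from_obj(r) for r in obj["records"]]


def convert_external_log(path: str) -> list[ParticipantRecord]:
    """Converter stub for externally digitized participant logs.

    An external deposit is expected to provide, per participant: an
    identifier, expertise level, assigned hypothesis, the ordered initial
    plan as (location, measurement-count) pairs, the executed step
    sequence with phase tags and observed (moisture, strength) values, and
    the final accept/reject conclusion with a confidence rating.  Map
    those onto the schema of :func:`records_from_json`; this stub only
    documents the expectation, since external deposit formats vary.
    """
    raise NotImplementedError(
        "adapt the external file to the records_from_json schema (version 1)"
    )
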