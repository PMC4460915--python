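"""Streaming retirement engine for capture events in circulation.

Each image set circulates to multiple volunteers until one of four stopping
rules fires, checked after every incoming classification in this order:

* **Blank** — the first ``blank_run`` (default 5) classifications are all
  'nothing here', consecutively from the start;
* **Blank_Consensus** — ``blank_total`` (default 10) 'nothing here'
  classifications in total, not necessarily consecutive;
* **Consensus** — ``consensus_votes`` (default 10) matching classifications
  of the same species *set* (a 'lion-zebra' answer matches only other
  'lion-zebra' answers, not plain 'lion');
* **Complete** — ``complete_nonblank`` (default 25) non-blank
  classifications, regardless of agreement.

Retirement is absorbing: once a state leaves ``active`` it never changes.
Classifications that arrive after retirement (the live site re-circulated
images, so 11-57 answers per animal image were common) are counted
separately and still flow to the consensus stage.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from .tables_io import ClassificationEvent

__all__ = [
    "ACTIVE",
    "BLANK",
    "BLANK_CONSENSUS",
    "CONSENSUS",
    "COMPLETE",
    "RetirementThresholds",
    "RetirementState",
    "RetirementOutcome",
    "RetiredStateError",
    "ingest",
    "run_stream",
]

ACTIVE = "active"
BLANK = "Blank"
BLANK_CONSENSUS = "Blank_Consensus"
CONSENSUS = "Consensus"
COMPLETE = "Complete"


class RetiredStateError(RuntimeError):
    """A classification was ingested into an already-retired state."""


@dataclasses.dataclass(frozen=True)
class RetirementThresholds:
    """Stopping-rule thresholds; defaults are the deployed values."""

    blank_run: int = 5
    blank_total: int = 10
    consensus_votes: int = 10
    complete_nonblank: int = 25

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 1:
                raise ValueError(f"{field.name} must be positive")


@dataclasses.dataclass
class RetirementState:
    """Per-capture-event accumulator deciding when an image set retires."""

    thresholds: RetirementThresholds = dataclasses.field(
        default_factory=RetirementThresholds
    )
    n_total: int = 0
    n_blank: int = 0
    n_nonblank: int = 0
    leading_blank_run_intact: bool = True
    votes_by_combination: dict[frozenset[str], int] = dataclasses.field(
        default_factory=dict
    )
    status: str = ACTIVE

    def ingest(self, event: ClassificationEvent) -> "RetirementState":
        """Consume one classification; may flip ``status`` to a retirement
        reason. Raises :class:`RetiredStateError` on a retired state."""
        if self.status != ACTIVE:
            raise RetiredStateError(
                f"cannot ingest into a state retired as {self.status}"
            )
        self.n_total += 1
        if event.is_blank:
            self.n_blank += 1
        else:
            self.leading_blank_run_intact = False
            self.n_nonblank += 1
            combo = event.species_set
            self.votes_by_combination[combo] = (
                self.votes_by_combination.get(combo, 0) + 1
            )
        self.status = self._check_rules()
        return self

    def _check_rules(self) -> str:
        t = self.thresholds
        if self.leading_blank_run_intact and self.n_blank >= t.blank_run:
            return BLANK
        if self.n_blank >= t.blank_total:
            return BLANK_CONSENSUS
        if self.votes_by_combination and (
            max(self.votes_by_combination.values()) >= t.consensus_votes
        ):
            return CONSENSUS
        if self.n_nonblank >= t.complete_nonblank:
            return COMPLETE
        return ACTIVE


def ingest(state: RetirementState, event: ClassificationEvent) -> RetirementState:
    """Functional alias for :meth:`RetirementState.ingest`."""
    return state.ingest(event)


@dataclasses.dataclass(frozen=True)
class RetirementOutcome:
    """Replay result for one capture event."""

    status: str
    n_consumed: int
    n_post_retirement: int = 0


def run_stream(
    events: Iterable[ClassificationEvent],
    thresholds: RetirementThresholds | None = None,
) -> Mapping[str, RetirementOutcome]:
    """Replay a classification stream through per-event retirement states.

    ``events`` must be ordered by classification time within each capture
    event (interleaving across events is fine). Classifications arriving
    after retirement are tallied as ``n_post_retirement`` rather than
    ingested; they are not discarded upstream and still reach consensus.
    """
    thresholds = thresholds or RetirementThresholds()
    states: dict[str, RetirementState] = {}
    post: dict[str, int] = {}
    order: list[str] = []
    for event in events:
        cid = event.capture_event_id
        if cid not in states:
            states[cid] = RetirementState(thresholds=thresholds)
            post[cid] = 0
            order.append(cid)
        if states[cid].status != ACTIVE:
            post[cid] += 1
        else:
            states[cid].ingest(event)
    return {
        cid: RetirementOutcome(
            status=states[cid].status,
            n_consumed=states[cid].n_total,
            n_post_retirement=post[cid],
        )
        for cid in order
    }
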