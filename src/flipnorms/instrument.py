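"""FLI-P checklist structure and scoring with basal/ceiling rules.

The checklist is 64 ordered statements about listening behaviour, grouped
into six hierarchical skill areas (sound awareness through advanced
open-set listening).  A rater marks each item "mostly" (skill demonstrated
regularly, across places and people) or "rarely" (occasionally or not at
all).  The total score is simply the count of "mostly" responses, 0-64.

Two administration rules accompany scoring:

* the *ceiling* ends the assessment once a run of consecutive "rarely"
  responses is recorded (the run length is configurable; default 4);
* the *basal window* is the four highest-indexed "mostly" items, re-checked
  between administrations to detect regression.  It is informational only
  and never alters the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

N_ITEMS = 64
N_AREAS = 6
BASAL_SIZE = 4
DEFAULT_CEILING_RUN = 4

MOSTLY = "mostly"
RARELY = "rarely"
_VALID_RESPONSES = {MOSTLY, RARELY}


class InstrumentError(ValueError):
    """Malformed or structurally invalid instrument definition."""


@dataclass(frozen=True)
class ItemDef:
    index: int   # 1..64
    area: int    # 1..6
    text: str

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_ITEMS:
            raise InstrumentError(f"item index {self.index} outside 1..{N_ITEMS}")
        if not 1 <= self.area <= N_AREAS:
            raise InstrumentError(f"item {self.index}: area {self.area} outside 1..{N_AREAS}")
        if not self.text:
            raise InstrumentError(f"item {self.index}: empty text")


@dataclass
class InstrumentDefinition:
    items: list[ItemDef]
    areas: list[str]

    def __post_init__(self) -> None:
        if len(self.areas) != N_AREAS:
            raise InstrumentError(f"expected {N_AREAS} areas, got {len(self.areas)}")
        if len(self.items) != N_ITEMS:
            raise InstrumentError(f"expected {N_ITEMS} items, got {len(self.items)}")
        indices = [it.index for it in self.items]
        if indices != list(range(1, N_ITEMS + 1)):
            raise InstrumentError("item indices must be exactly 1..64 in ascending order")
        # areas must partition 1..64 into contiguous, ordered, non-empty runs
        areas_seq = [it.area for it in self.items]
        seen: list[int] = []
        for a in areas_seq:
            if not seen or a != seen[-1]:
                seen.append(a)
        if seen != sorted(set(areas_seq)) or set(areas_seq) != set(range(1, N_AREAS + 1)):
            raise InstrumentError(
                "areas must be contiguous ascending blocks covering all 6 areas"
            )


@dataclass
class ResponseSet:
    """Item responses; items absent from the map are unanswered."""

    responses: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, resp in self.responses.items():
            if not 1 <= idx <= N_ITEMS:
                raise ValueError(f"response for item {idx}: index outside 1..{N_ITEMS}")
            if resp not in _VALID_RESPONSES:
                raise ValueError(
                    f"response for item {idx}: {resp!r} not in {sorted(_VALID_RESPONSES)}"
                )

    def mostly_indices(self) -> list[int]:
        return sorted(i for i, r in self.responses.items() if r == MOSTLY)


@dataclass
class ScoredAssessment:
    child_id: str
    age: float                      # months
    score: int                      # 0..64, count of "mostly"
    ceiling: int | None             # first index of the terminating rarely-run
    basal: list[int]                # up to 4 highest-indexed "mostly" items
    warnings: list[str] = field(default_factory=list)


def load_instrument(source: str | Path | dict) -> InstrumentDefinition:
    """Load an instrument definition from a JSON file path or parsed dict.

    The document must carry ``areas`` (6 names) and ``items``
    (64 ``{index, area, text}`` records).  Structural violations raise
    :class:`InstrumentError` naming the offending record.
    """
    if isinstance(source, (str, Path)):
        try:
            with open(source) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InstrumentError(f"cannot parse instrument document {source}: {exc}") from exc
    else:
        doc = source
    try:
        areas = list(doc["areas"])
        raw_items = doc["items"]
    except (KeyError, TypeError) as exc:
        raise InstrumentError(f"instrument document missing field: {exc}") from exc
    items = []
    for rec in raw_items:
        try:
            items.append(ItemDef(index=int(rec["index"]), area=int(rec["area"]),
                                 text=str(rec["text"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise InstrumentError(f"malformed item record {rec!r}: {exc}") from exc
    return InstrumentDefinition(items=items, areas=areas)


def load_default_instrument() -> InstrumentDefinition:
    """The packaged default checklist definition.

    Only the six publicly printed exemplar items carry real statement text;
    the remaining items are clearly marked placeholders, since the full
    item set is proprietary.  Structure (64 items, 6 areas) is faithful.
    """
    with resources.files("flipnorms.data").joinpath("instrument.json").open() as fh:
        return load_instrument(json.load(fh))


def find_ceiling(responses: ResponseSet, run_length: int = DEFAULT_CEILING_RUN) -> int | None:
    """First item index starting a run of >= run_length consecutive "rarely".

    Items are scanned in ascending index order; unanswered items break a
    run.  Returns ``None`` when no qualifying run exists.
    """
    if run_length < 1:
        raise ValueError(f"run_length must be >= 1, got {run_length}")
    run_start = None
    run_len = 0
    for idx in range(1, N_ITEMS + 1):
        if responses.responses.get(idx) == RARELY:
            if run_len == 0:
                run_start = idx
            run_len += 1
            if run_len >= run_length:
                return run_start
        else:
            run_len = 0
            run_start = None
    return None


def basal_window(responses: ResponseSet) -> list[int]:
    """The up-to-four highest-indexed "mostly" items, ascending."""
    mostly = responses.mostly_indices()
    return mostly[-BASAL_SIZE:]


def score_assessment(
    child_id: str,
    age: float,
    responses: ResponseSet,
    instrument: InstrumentDefinition | None = None,
    run_length: int = DEFAULT_CEILING_RUN,
) -> ScoredAssessment:
    """Score one administration: count of "mostly" responses.

    The ceiling and basal window are attached for administration QC.
    Conditions that cannot occur under a clean administration — no ceiling
    reached, "mostly" responses above the ceiling, unanswered items below
    the ceiling — are reported as warnings, never errors, and never change
    the score (only explicit "mostly" records count).
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    mostly = responses.mostly_indices()
    score = len(mostly)
    ceiling = find_ceiling(responses, run_length=run_length)
    warnings: list[str] = []
    if ceiling is None:
        warnings.append("no ceiling reached")
        answered_through = N_ITEMS
    else:
        if any(i > ceiling for i in mostly):
            warnings.append("responses above ceiling: 'mostly' recorded past the ceiling run")
        answered_through = ceiling
    unanswered_below = [
        i for i in range(1, answered_through) if i not in responses.responses
    ]
    if unanswered_below:
        warnings.append(
            f"{len(unanswered_below)} unanswered item(s) below the ceiling "
            "counted as not-'mostly'"
        )
    return ScoredAssessment(
        child_id=child_id,
        age=age,
        score=score,
        ceiling=ceiling,
        basal=basal_window(responses),
        warnings=warnings,
    )
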