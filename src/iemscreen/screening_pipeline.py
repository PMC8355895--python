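"""Two-tier screening funnel: primary screen → recall → confirmation.

Every specimen moves forward through at most four stages:

1. **Primary screen** — the first dried-blood-spot panel is flagged against
   the cut-off table; a specimen is *primary positive* per the trigger policy
   (``any_abnormal_marker``: at least one marker out of range, or
   ``any_pattern_match``: at least one full disorder signature satisfied).
2. **Recall** — primary positives are asked back for a repeat specimen; some
   are lost to follow-up.  The recall panel is re-flagged with the *same*
   cut-offs and trigger policy.
3. **Confirmation** — recall positives undergo diagnostic biochemistry or
   sequencing.  Confirmation is an oracle input here (a diagnosis map, or the
   simulator's truth labels); the confirmatory assays themselves are not
   modelled.

The funnel counts are monotone by construction:
confirmed ≤ recall positive ≤ recalled ≤ primary positive ≤ screened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .disorder_rules import DisorderPattern, category_of, match_disorders
from .panel_model import (
    AnalytePanel,
    CutoffTable,
    FlagResult,
    IemscreenError,
    MarkerDefinition,
    compute_derived_markers,
    flag_panel,
)

logger = logging.getLogger("iemscreen")

TRIGGER_POLICIES = ("any_abnormal_marker", "any_pattern_match")

FINAL_STATES = (
    "screen_negative",
    "lost_to_followup",
    "recall_negative",
    "confirmed",
    "recall_positive_unconfirmed",
)


class PipelineError(IemscreenError):
    """A contract violation in the screening funnel."""


@dataclass
class ScreeningRecord:
    """Funnel state of one specimen; fields fill in as stages run forward."""

    specimen_id: str
    cohort: str
    primary_flags: FlagResult
    primary_positive: bool
    recalled: bool = False
    lost: bool = False
    recall_flags: FlagResult | None = None
    recall_positive: bool | None = None
    confirmed_disorder: str | None = None
    truth_label: str | None = None

    @property
    def final_state(self) -> str:
        if not self.primary_positive:
            return "screen_negative"
        if self.lost:
            return "lost_to_followup"
        if not self.recalled:
            return "pending_recall"
        if not self.recall_positive:
            return "recall_negative"
        if self.confirmed_disorder is not None:
            return "confirmed"
        return "recall_positive_unconfirmed"


@dataclass
class CohortSummary:
    """Aggregated funnel counts plus the confirmed disease spectrum."""

    n_screened: int
    n_primary_positive: int
    n_recalled: int
    n_recall_positive: int
    n_confirmed: int
    per_disorder: dict[str, int] = field(default_factory=dict)
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        funnel = (
            self.n_confirmed,
            self.n_recall_positive,
            self.n_recalled,
            self.n_primary_positive,
            self.n_screened,
        )
        if any(b < a for a, b in zip(funnel, funnel[1:])):
            raise PipelineError(f"funnel counts are not monotone: {funnel}")
        if self.per_disorder and sum(self.per_disorder.values()) != self.n_confirmed:
            raise PipelineError("per-disorder counts must sum to n_confirmed")

    @property
    def per_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d, c in self.per_disorder.items():
            cat = self.category_map.get(d, "?")
            out[cat] = out.get(cat, 0) + c
        return out

    @classmethod
    def from_counts(
        cls,
        n_screened: int,
        n_primary_positive: int,
        n_recalled: int,
        n_confirmed: int,
        n_recall_positive: int | None = None,
        per_disorder: Mapping[str, int] | None = None,
        category_map: Mapping[str, str] | None = None,
    ) -> "CohortSummary":
        """Build a summary from published funnel counts.

        When the recall-tier positive count is not reported separately,
        recalled specimens are taken as persisting positives
        (n_recall_positive = n_recalled), matching the convention that PPV is
        computed over all recalled specimens.
        """
        return cls(
            n_screened=n_screened,
            n_primary_positive=n_primary_positive,
            n_recalled=n_recalled,
            n_recall_positive=n_recalled if n_recall_positive is None else n_recall_positive,
            n_confirmed=n_confirmed,
            per_disorder=dict(per_disorder or {}),
            category_map=dict(category_map or {}),
        )


def _is_positive(
    flags: FlagResult, patterns: Sequence[DisorderPattern], policy: str
) -> bool:
    if policy == "any_abnormal_marker":
        return flags.is_positive
    if policy == "any_pattern_match":
        return bool(match_disorders(flags, patterns, mode="all_markers").candidates)
    raise ValueError(f"unknown trigger policy {policy!r}")


def run_primary_screen(
    panels: Iterable[AnalytePanel],
    cutoffs: CutoffTable,
    patterns: Sequence[DisorderPattern],
    trigger_policy: str = "any_abnormal_marker",
    schema: Sequence[MarkerDefinition] | None = None,
) -> list[ScreeningRecord]:
    """Flag every primary-tier panel and mark primary positives."""
    if trigger_policy not in TRIGGER_POLICIES:
        raise ValueError(f"unknown trigger policy {trigger_policy!r}")
    schema = cutoffs.schema() if schema is None else schema
    records: list[ScreeningRecord] = []
    seen: set[str] = set()
    for panel in panels:
        if panel.tier != "primary":
            raise PipelineError(f"specimen {panel.specimen_id}: expected a primary-tier panel")
        if panel.specimen_id in seen:
            raise PipelineError(f"duplicate specimen_id {panel.specimen_id!r}")
        seen.add(panel.specimen_id)
        extended = compute_derived_markers(panel, schema, strict=False)
        flags = flag_panel(extended, cutoffs, specimen_id=panel.specimen_id)
        records.append(
            ScreeningRecord(
                specimen_id=panel.specimen_id,
                cohort=panel.cohort,
                primary_flags=flags,
                primary_positive=_is_positive(flags, patterns, trigger_policy),
                truth_label=panel.truth_label,
            )
        )
    n_pos = sum(r.primary_positive for r in records)
    logger.info("primary screen: %d/%d positive", n_pos, len(records))
    return records


def apply_recall(
    records: Sequence[ScreeningRecord],
    recall_panels: Iterable[AnalytePanel],
    loss_events: Iterable[str],
    cutoffs: CutoffTable,
    patterns: Sequence[DisorderPattern],
    trigger_policy: str = "any_abnormal_marker",
    schema: Sequence[MarkerDefinition] | None = None,
) -> list[ScreeningRecord]:
    """Apply recall outcomes: losses to follow-up and repeat-panel re-flagging.

    Recall panels may exist only for primary-positive specimens, and every
    primary positive must either be recalled or lost.  Recall panels are
    flagged with the same cut-off table and trigger policy as tier 1 (no
    recall-specific thresholds are defined).
    """
    schema = cutoffs.schema() if schema is None else schema
    by_id = {r.specimen_id: r for r in records}
    lost = set(loss_events)
    for sid in lost:
        rec = by_id.get(sid)
        if rec is None or not rec.primary_positive:
            raise PipelineError(f"loss event for non-primary-positive specimen {sid!r}")
        rec.lost = True
    for panel in recall_panels:
        rec = by_id.get(panel.specimen_id)
        if rec is None or not rec.primary_positive:
            raise PipelineError(
                f"recall panel for non-primary-positive specimen {panel.specimen_id!r}"
            )
        if panel.specimen_id in lost:
            raise PipelineError(f"specimen {panel.specimen_id!r} both recalled and lost")
        if panel.tier != "recall":
            raise PipelineError(f"specimen {panel.specimen_id}: expected a recall-tier panel")
        extended = compute_derived_markers(panel, schema, strict=False)
        flags = flag_panel(extended, cutoffs, specimen_id=panel.specimen_id)
        rec.recalled = True
        rec.recall_flags = flags
        rec.recall_positive = _is_positive(flags, patterns, trigger_policy)
    unaccounted = [
        r.specimen_id for r in records if r.primary_positive and not r.recalled and not r.lost
    ]
    if unaccounted:
        raise PipelineError(
            f"{len(unaccounted)} primary positives have neither a recall panel nor a "
            f"loss event (first: {unaccounted[0]!r})"
        )
    n_rec = sum(r.recalled for r in records)
    n_pos = sum(bool(r.recall_positive) for r in records)
    logger.info("recall: %d recalled (%d lost), %d recall-positive", n_rec, len(lost), n_pos)
    return list(records)


def confirm(
    records: Sequence[ScreeningRecord],
    diagnoses: Mapping[str, str],
) -> list[ScreeningRecord]:
    """Attach confirmed diagnoses (specimen id → disorder id).

    Only recall-positive specimens may be confirmed; remaining recall
    positives stay in the ``recall_positive_unconfirmed`` state — the
    false-positive mass of the screening funnel.
    """
    by_id = {r.specimen_id: r for r in records}
    for sid, disorder in diagnoses.items():
        rec = by_id.get(sid)
        if rec is None:
            raise PipelineError(f"diagnosis for unknown specimen {sid!r}")
        if not rec.recall_positive:
            raise PipelineError(f"diagnosis for non-recall-positive specimen {sid!r}")
        rec.confirmed_disorder = disorder
    logger.info("confirmation: %d confirmed", len(diagnoses))
    return list(records)


def summarize(
    records: Sequence[ScreeningRecord],
    patterns: Sequence[DisorderPattern] | None = None,
) -> CohortSummary:
    """Aggregate records into funnel counts and the confirmed disease spectrum."""
    per_disorder: dict[str, int] = {}
    for r in records:
        if r.confirmed_disorder is not None:
            per_disorder[r.confirmed_disorder] = per_disorder.get(r.confirmed_disorder, 0) + 1
    return CohortSummary(
        n_screened=len(records),
        n_primary_positive=sum(r.primary_positive for r in records),
        n_recalled=sum(r.recalled for r in records),
        n_recall_positive=sum(bool(r.recall_positive) for r in records),
        n_confirmed=sum(r.confirmed_disorder is not None for r in records),
        per_disorder=per_disorder,
        category_map=category_of(patterns) if patterns else {},
    )


def records_to_frame(records: Sequence[ScreeningRecord]):
    """Flatten records to a pandas DataFrame (one row per specimen)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "cohort": r.cohort,
                "primary_positive": r.primary_positive,
                "primary_abnormal": ";".join(f"{m}:{d}" for m, d in r.primary_flags.abnormal),
                "recalled": r.recalled,
                "lost": r.lost,
                "recall_positive": r.recall_positive,
                "confirmed_disorder": r.confirmed_disorder or "",
                "truth_label": r.truth_label or "",
                "final_state": r.final_state,
            }
        )
    return pd.DataFrame(rows)
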