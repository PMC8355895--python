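"""Per-disorder marker signatures and pattern matching.

Each inborn error of metabolism (IEM) screened by MS/MS has a biochemical
signature: a set of markers deviating in a fixed direction (e.g. primary
carnitine deficiency = free carnitine C0 low; phenylketonuria = Phe and
Phe/Tyr high).  The packaged fixture encodes the 16 disorders confirmed in
the Liuzhou screening programme, grouped into amino-acid (AAMD), fatty-acid
(FAMD) and organic-acid (OAMD) metabolic disorders, together with the
reference intervals and the observed case ranges (median, min, max) at the
primary and recall tiers.

Matching supports two semantics: ``all_markers`` (a disorder is a candidate
only when every required marker flags in the required direction — the joint
signature) and ``any_marker`` (one suffices).  MMA and PA share an identical
signature (C3, C3/C2, C3/C0 high) and are biochemically indistinguishable at
this tier; both are reported and the tie is broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .panel_model import (
    CutoffTable,
    FixtureError,
    FlagResult,
    MarkerStatus,
    _load_structured,
)

CATEGORIES = ("AAMD", "FAMD", "OAMD")
MATCH_MODES = ("all_markers", "any_marker")

#: disorders whose signatures coincide and need confirmatory testing to split
BIOCHEMICALLY_INDISTINGUISHABLE = frozenset({"MMA", "PA"})


@dataclass(frozen=True)
class DisorderPattern:
    """Signature of one disorder.

    ``required`` lists (marker, direction) pairs that must all deviate for a
    full-pattern match.  ``reported_reference`` keeps the per-disorder
    reference intervals as printed in the source screening report (metadata;
    the cut-off table governs flagging).  ``observed_primary`` and
    ``observed_recall`` map marker → (median, min, max) over confirmed cases
    at each screening tier and drive the cohort simulator's affected draws.
    """

    disorder_id: str
    category: str
    required: tuple[tuple[str, str], ...]
    reported_reference: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    observed_primary: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    observed_recall: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    cases: int = 0

    def __post_init__(self) -> None:
        if not self.required:
            raise FixtureError(f"pattern {self.disorder_id!r} has no required markers")
        if self.category not in CATEGORIES:
            raise FixtureError(f"pattern {self.disorder_id!r}: unknown category {self.category!r}")
        for marker, direction in self.required:
            if direction not in ("low", "high"):
                raise FixtureError(
                    f"pattern {self.disorder_id!r}: bad direction {direction!r} for {marker!r}"
                )


@dataclass
class MatchScore:
    disorder_id: str
    n_satisfied: int
    n_required: int

    @property
    def fraction_satisfied(self) -> float:
        return self.n_satisfied / self.n_required


@dataclass
class MatchReport:
    """Ranked disorder candidates for one flagged specimen.

    ``scores`` lists every disorder with at least one satisfied signature
    marker, sorted by fraction satisfied (descending) with lexicographic
    tie-break; ``candidates`` is the subset passing the requested match mode.
    """

    specimen_id: str
    mode: str
    scores: list[MatchScore]

    @property
    def candidates(self) -> list[MatchScore]:
        if self.mode == "all_markers":
            return [s for s in self.scores if s.n_satisfied == s.n_required]
        return [s for s in self.scores if s.n_satisfied >= 1]

    @property
    def candidate_ids(self) -> list[str]:
        return [s.disorder_id for s in self.candidates]


def load_patterns(path: str | Path | None = None) -> list[DisorderPattern]:
    """Load and validate disorder patterns (default: the packaged 16-IEM fixture)."""
    raw = _load_structured(path, "patterns.json")
    rows = raw.get("patterns", None)
    if not rows:
        raise FixtureError("pattern fixture is empty")
    patterns = []
    errors = []
    for row in rows:
        try:
            patterns.append(
                DisorderPattern(
                    disorder_id=row["disorder"],
                    category=row["category"],
                    required=tuple((m, d) for m, d in row["required"]),
                    reported_reference={
                        m: (float(lo), float(hi))
                        for m, (lo, hi) in row.get("reported_reference", {}).items()
                    },
                    observed_primary={
                        m: (float(md), float(lo), float(hi))
                        for m, (md, lo, hi) in row.get("observed_primary", {}).items()
                    },
                    observed_recall={
                        m: (float(md), float(lo), float(hi))
                        for m, (md, lo, hi) in row.get("observed_recall", {}).items()
                    },
                    cases=int(row.get("cases", 0)),
                )
            )
        except (KeyError, TypeError, ValueError, FixtureError) as exc:
            errors.append(f"{row.get('disorder', '<unnamed>')}: {exc}")
    if errors:
        raise FixtureError("invalid pattern rows: " + "; ".join(errors))
    ids = [p.disorder_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate disorder ids in pattern fixture")
    return patterns


def validate_patterns(patterns: Sequence[DisorderPattern], cutoffs: CutoffTable) -> None:
    """Cross-check patterns against a cut-off table.

    Every required marker must have a cut-off entry, and each required
    direction must be consistent with the observed case range lying outside
    the reference interval on that side.
    """
    problems = []
    for p in patterns:
        for marker, direction in p.required:
            if marker not in cutoffs:
                problems.append(f"{p.disorder_id}: marker {marker!r} has no cut-off entry")
                continue
            obs = p.observed_primary.get(marker)
            ref = p.reported_reference.get(marker)
            if obs is None or ref is None:
                continue
            _, obs_min, obs_max = obs
            lo, hi = ref
            if direction == "high" and not obs_min > hi:
                problems.append(
                    f"{p.disorder_id}: {marker} marked high but observed min {obs_min} <= reference upper {hi}"
                )
            if direction == "low" and not obs_max < lo:
                problems.append(
                    f"{p.disorder_id}: {marker} marked low but observed max {obs_max} >= reference lower {lo}"
                )
    if problems:
        raise FixtureError("pattern/cut-off validation failed: " + "; ".join(problems))


def patterns_by_id(patterns: Sequence[DisorderPattern]) -> dict[str, DisorderPattern]:
    return {p.disorder_id: p for p in patterns}


def category_of(patterns: Sequence[DisorderPattern]) -> dict[str, str]:
    return {p.disorder_id: p.category for p in patterns}


def match_disorders(
    flags: FlagResult,
    patterns: Sequence[DisorderPattern],
    mode: str = "all_markers",
) -> MatchReport:
    """Match a flagged panel against disorder signatures.

    A required (marker, direction) is satisfied when the marker's status
    equals the direction.  Results are deterministic: sorted by fraction
    satisfied descending, then disorder id ascending.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    scores = []
    for p in patterns:
        n_sat = 0
        for marker, direction in p.required:
            status = flags.statuses.get(marker)
            if status is None:
                raise FixtureError(
                    f"pattern {p.disorder_id!r} requires marker {marker!r} "
                    "which the flag result does not cover"
                )
            if status == MarkerStatus(direction):
                n_sat += 1
        if n_sat >= 1:
            scores.append(MatchScore(p.disorder_id, n_sat, len(p.required)))
    scores.sort(key=lambda s: (-s.fraction_satisfied, s.disorder_id))
    return MatchReport(specimen_id=flags.specimen_id, mode=mode, scores=scores)
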