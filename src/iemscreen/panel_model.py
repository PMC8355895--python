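"""Analyte-panel data model, derived-ratio computation and cut-off flagging.

A newborn-screening MS/MS panel quantifies free carnitine (C0), amino acids
and acylcarnitine species in a dried blood spot, in μmol/L.  Screening labs
additionally evaluate analyte *ratios* (e.g. Phe/Tyr, C3/C2) because they are
more specific than single concentrations.  This module models the marker
schema, computes the ratio markers from the measured primaries, and compares
every marker against a reference interval ("cut-off") table: a value below the
lower bound flags ``low``, above the upper bound flags ``high``, and values on
a closed interval (bounds included) are ``normal``.

The packaged default cut-off table is the Liuzhou screening panel: 41 primary
markers and 13 ratio markers.  Three of the ratios (Phe/Tyr, Cit/Phe, Met/Phe)
are tagged ``table3-extension``: they are referenced by disorder signatures
but were published only as per-disorder reference columns, not in the main
cut-off panel.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("iemscreen")

#: fraction of missing markers above which a panel is logged as a QC failure
QC_MISSING_FRACTION = 0.10

PANEL_META_COLUMNS = ("specimen_id", "tier", "cohort", "truth_label")


class IemscreenError(Exception):
    """Base class for package errors."""


class MissingMarkerError(IemscreenError):
    """A ratio references a primary marker that is absent from the panel."""


class DegenerateRatioError(IemscreenError):
    """A ratio denominator sums to zero."""


class FixtureError(IemscreenError):
    """A packaged or user-supplied fixture violates its schema."""


class MarkerStatus(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"
    MISSING = "missing"


@dataclass(frozen=True)
class MarkerDefinition:
    """One marker of the panel schema.

    Ratio markers carry the primary markers whose concentration sums form the
    numerator and denominator; primary markers have empty tuples and μmol/L
    units (ratios are dimensionless).
    """

    id: str
    kind: str  # "primary" | "ratio"
    numerator: tuple[str, ...] = ()
    denominator: tuple[str, ...] = ()
    units: str = "μmol/L"

    def __post_init__(self) -> None:
        if self.kind == "ratio":
            if not self.numerator or not self.denominator:
                raise FixtureError(f"ratio marker {self.id!r} needs numerator and denominator")
        elif self.kind == "primary":
            if self.numerator or self.denominator:
                raise FixtureError(f"primary marker {self.id!r} must not carry ratio members")
        else:
            raise FixtureError(f"unknown marker kind {self.kind!r}")


_RATIO_TERM = re.compile(r"^\(?(?P<body>[^()]+)\)?$")


def parse_marker_token(token: str) -> MarkerDefinition:
    """Build a :class:`MarkerDefinition` from a marker name token.

    Tokens follow the screening-panel spelling: plain names ("Phe", "C5-OH")
    are primary markers; ratio names use "/" with optional parenthesised sums,
    e.g. "C3/C2", "C0/(C16 + C18)", "(C16 + C18:1)/C2".  Parsing is
    case-sensitive after trimming whitespace.
    """
    token = token.strip()
    if "/" not in token:
        return MarkerDefinition(id=token, kind="primary")
    # split on the single top-level slash
    depth = 0
    split_at = -1
    for i, ch in enumerate(token):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "/" and depth == 0:
            split_at = i
            break
    if split_at < 0:
        raise FixtureError(f"cannot parse ratio marker token {token!r}")

    def members(part: str) -> tuple[str, ...]:
        m = _RATIO_TERM.match(part.strip())
        if m is None:
            raise FixtureError(f"cannot parse ratio term {part!r} in {token!r}")
        return tuple(s.strip() for s in m.group("body").split("+"))

    return MarkerDefinition(
        id=token,
        kind="ratio",
        numerator=members(token[:split_at]),
        denominator=members(token[split_at + 1:]),
        units="",
    )


def build_schema(marker_ids: Iterable[str]) -> list[MarkerDefinition]:
    """Parse a list of marker name tokens into a validated schema."""
    schema = [parse_marker_token(t) for t in marker_ids]
    ids = [m.id for m in schema]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate marker ids in schema")
    primaries = {m.id for m in schema if m.kind == "primary"}
    for m in schema:
        for ref in (*m.numerator, *m.denominator):
            if ref not in primaries:
                raise FixtureError(f"ratio {m.id!r} references unknown primary {ref!r}")
    return schema


def primary_markers(schema: Sequence[MarkerDefinition]) -> list[str]:
    return [m.id for m in schema if m.kind == "primary"]


def ratio_markers(schema: Sequence[MarkerDefinition]) -> list[MarkerDefinition]:
    return [m for m in schema if m.kind == "ratio"]


@dataclass
class CutoffTable:
    """Marker → (lower, upper) reference intervals used for flagging.

    ``boundary`` controls interval strictness: "closed" (default, values equal
    to a bound are normal) or "open" (bound values flag).  ``source`` records
    where each entry came from ("table1" screening panel vs "table3-extension").
    """

    entries: dict[str, tuple[float, float]]
    version: str = ""
    boundary: str = "closed"
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.boundary not in ("closed", "open"):
            raise FixtureError(f"unknown boundary policy {self.boundary!r}")
        for marker, (lo, hi) in self.entries.items():
            if not (lo < hi):
                raise FixtureError(f"cut-off for {marker!r} must have lower < upper")
            if lo < 0:
                raise FixtureError(f"cut-off for {marker!r} must be non-negative")

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    def __getitem__(self, marker: str) -> tuple[float, float]:
        return self.entries[marker]

    @property
    def markers(self) -> list[str]:
        return list(self.entries)

    def schema(self) -> list[MarkerDefinition]:
        """The marker schema implied by this table's marker tokens."""
        return build_schema(self.entries)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "CutoffTable":
        """Load a cut-off table from JSON/YAML; default is the packaged panel."""
        raw = _load_structured(path, "cutoffs.json")
        try:
            entries = {e["marker"]: (float(e["lower"]), float(e["upper"])) for e in raw["entries"]}
            source = {e["marker"]: e.get("source", "table1") for e in raw["entries"]}
        except (KeyError, TypeError) as exc:
            raise FixtureError(f"malformed cut-off fixture: {exc}") from exc
        if len(entries) != len(raw["entries"]):
            raise FixtureError("duplicate markers in cut-off fixture")
        return cls(
            entries=entries,
            version=raw.get("version", ""),
            boundary=raw.get("boundary", "closed"),
            source=source,
        )


def _load_structured(path: str | Path | None, default_name: str) -> dict:
    """Read a JSON (or YAML, by extension) fixture; None means the packaged one."""
    if path is None:
        text = resources.files("iemscreen.data").joinpath(default_name).read_text("utf-8")
        return json.loads(text)
    path = Path(path)
    text = path.read_text("utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


@dataclass
class AnalytePanel:
    """One specimen's measured primary-marker concentrations plus metadata.

    ``values`` maps primary marker id → concentration in μmol/L; a missing
    measurement is stored as ``None``.  ``truth_label`` is only ever set by
    the cohort simulator and names the disorder a simulated specimen actually
    has (the confirmation oracle).
    """

    specimen_id: str
    values: dict[str, float | None]
    tier: str = "primary"  # "primary" | "recall"
    cohort: str = "newborn"  # "newborn" | "high_risk"
    truth_label: str | None = None
    collected_at: str | None = None

    def __post_init__(self) -> None:
        if self.tier not in ("primary", "recall"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.cohort not in ("newborn", "high_risk"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        for marker, v in self.values.items():
            if v is not None and (math.isnan(v) if isinstance(v, float) else False):
                self.values[marker] = None
            elif v is not None and v < 0:
                raise ValueError(f"negative concentration for {marker!r} in {self.specimen_id}")

    def missing_fraction(self, schema: Sequence[MarkerDefinition]) -> float:
        prim = primary_markers(schema)
        n_missing = sum(1 for m in prim if self.values.get(m) is None)
        return n_missing / len(prim) if prim else 0.0


@dataclass
class FlagResult:
    """Per-marker screening statuses for one specimen.

    ``abnormal`` lists (marker, direction) pairs for every low/high marker, in
    cut-off table order; ``statuses`` covers every marker that has a cut-off
    entry.
    """

    specimen_id: str
    statuses: dict[str, MarkerStatus]
    abnormal: list[tuple[str, str]]

    @property
    def is_positive(self) -> bool:
        return bool(self.abnormal)


def compute_derived_markers(
    panel: AnalytePanel | Mapping[str, float | None],
    schema: Sequence[MarkerDefinition],
    *,
    strict: bool = True,
) -> dict[str, float | None]:
    """Extend a primary value map with the schema's ratio markers.

    Each ratio is (sum of numerator values) / (sum of denominator values);
    primary values pass through unchanged.  With ``strict=True`` a missing
    referenced primary raises :class:`MissingMarkerError` and a zero
    denominator raises :class:`DegenerateRatioError`; with ``strict=False``
    the affected ratio becomes ``None`` (missing) so panels with incomplete
    measurements still flow through screening.
    """
    values = panel.values if isinstance(panel, AnalytePanel) else dict(panel)
    extended: dict[str, float | None] = dict(values)
    for marker in ratio_markers(schema):
        member_values = []
        missing = None
        for ref in (*marker.numerator, *marker.denominator):
            v = values.get(ref)
            if v is None:
                missing = ref
                break
            member_values.append(v)
        if missing is not None:
            if strict:
                raise MissingMarkerError(
                    f"ratio {marker.id!r} references missing marker {missing!r}"
                )
            extended[marker.id] = None
            continue
        num = sum(values[r] for r in marker.numerator)  # type: ignore[misc]
        den = sum(values[r] for r in marker.denominator)  # type: ignore[misc]
        if den == 0:
            if strict:
                raise DegenerateRatioError(f"zero denominator for ratio {marker.id!r}")
            extended[marker.id] = None
            continue
        extended[marker.id] = num / den
    return extended


def flag_panel(
    extended_values: Mapping[str, float | None],
    cutoffs: CutoffTable,
    *,
    specimen_id: str = "",
) -> FlagResult:
    """Compare an extended value map against the cut-off table.

    Status is ``low`` below the lower bound, ``high`` above the upper bound,
    ``normal`` inside the interval and ``missing`` for absent values (missing
    never flags).  Under the default closed-boundary policy a value exactly on
    a bound is normal; under "open" it flags on the corresponding side.
    """
    if not cutoffs.entries:
        raise FixtureError("cut-off table is empty")
    statuses: dict[str, MarkerStatus] = {}
    abnormal: list[tuple[str, str]] = []
    closed = cutoffs.boundary == "closed"
    n_missing = 0
    for marker, (lo, hi) in cutoffs.entries.items():
        v = extended_values.get(marker)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            statuses[marker] = MarkerStatus.MISSING
            n_missing += 1
            continue
        if (v < lo) if closed else (v <= lo):
            statuses[marker] = MarkerStatus.LOW
            abnormal.append((marker, "low"))
        elif (v > hi) if closed else (v >= hi):
            statuses[marker] = MarkerStatus.HIGH
            abnormal.append((marker, "high"))
        else:
            statuses[marker] = MarkerStatus.NORMAL
    if n_missing > QC_MISSING_FRACTION * len(cutoffs.entries):
        logger.warning(
            "QC-fail: specimen %s has %d/%d markers missing (processed anyway)",
            specimen_id or "<unnamed>", n_missing, len(cutoffs.entries),
        )
    return FlagResult(specimen_id=specimen_id, statuses=statuses, abnormal=abnormal)


def flag_analyte_panel(
    panel: AnalytePanel, cutoffs: CutoffTable, schema: Sequence[MarkerDefinition] | None = None
) -> FlagResult:
    """Convenience: derive ratios (lenient mode) and flag one panel."""
    schema = cutoffs.schema() if schema is None else schema
    extended = compute_derived_markers(panel, schema, strict=False)
    return flag_panel(extended, cutoffs, specimen_id=panel.specimen_id)


# ---------------------------------------------------------------------------
# CSV I/O

def read_panels(path: str | Path, cohort: str | None = None) -> list[AnalytePanel]:
    """Read analyte panels from CSV/TSV (header = metadata + marker columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    marker_cols = [c for c in df.columns if c not in PANEL_META_COLUMNS]
    panels = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        values = {
            m: (None if pd.isna(rec[m]) else float(rec[m])) for m in marker_cols
        }
        truth = rec.get("truth_label")
        panels.append(
            AnalytePanel(
                specimen_id=str(rec["specimen_id"]),
                values=values,
                tier=str(rec.get("tier", "primary")),
                cohort=str(cohort or rec.get("cohort", "newborn")),
                truth_label=None if (truth is None or pd.isna(truth)) else str(truth),
            )
        )
    return panels


def write_panels(panels: Sequence[AnalytePanel], path: str | Path) -> None:
    """Write panels to CSV with a stable marker column order."""
    if not panels:
        raise ValueError("no panels to write")
    markers = list(panels[0].values)
    rows = []
    for p in panels:
        row: dict[str, object] = {
            "specimen_id": p.specimen_id,
            "tier": p.tier,
            "cohort": p.cohort,
            "truth_label": p.truth_label if p.truth_label is not None else "",
        }
        row.update({m: p.values.get(m) for m in markers})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
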