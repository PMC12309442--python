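"""Reading, validating and writing call-annotation tables.

Two dialects are supported:

* **Raven selection tables** — the tab-separated export of Raven Pro, which
  must contain at least the columns ``"Begin Time (s)"`` and
  ``"End Time (s)"``.  Recording/individual/context metadata are supplied by
  the caller because Raven stores them outside the table.
* **Generic CSV** — the package's own flat format with columns
  ``recording_id,individual_id,context,raw_context,onset_s,offset_s``.

Both normalise to an :class:`AnnotationSet`: per recording, calls are sorted
by onset, must not overlap, and share a single context label drawn from
``{"natural", "non_natural"}``.  Raw context labels (e.g. the predator-model
print ``tiger``/``pattern``/``spots``/``white``) are mapped to those two
classes through a configurable mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import AnnotationFormatError, ConfigurationError, ValidationError

CONTEXTS = ("natural", "non_natural")

#: Default mapping from predator-model print labels to the two context
#: classes: the tiger print is the natural Sumatran predator; abstract
#: pattern, spotted and plain-white prints are non-natural.
DEFAULT_CONTEXT_MAP: dict[str, str] = {
    "tiger": "natural",
    "pattern": "non_natural",
    "spots": "non_natural",
    "white": "non_natural",
    "natural": "natural",
    "non_natural": "non_natural",
}

RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"

CSV_COLUMNS = [
    "recording_id",
    "individual_id",
    "context",
    "raw_context",
    "onset_s",
    "offset_s",
]


def normalize_context(label: str, context_map: Mapping[str, str] | None = None) -> str:
    """Map a raw context label to ``natural``/``non_natural``.

    Raises :class:`ConfigurationError` if the label is not in the mapping.
    """
    mapping = DEFAULT_CONTEXT_MAP if context_map is None else context_map
    key = str(label).strip()
    if key in mapping:
        mapped = mapping[key]
    elif key.lower() in mapping:
        mapped = mapping[key.lower()]
    else:
        raise ConfigurationError(
            f"context label {label!r} has no mapping to {CONTEXTS}; "
            "supply a context_map entry for it"
        )
    if mapped not in CONTEXTS:
        raise ConfigurationError(
            f"context map sends {label!r} to {mapped!r}, not one of {CONTEXTS}"
        )
    return mapped


@dataclass(frozen=True)
class CallAnnotation:
    """One annotated call: who called, when, and under which context."""

    recording_id: str
    individual_id: str
    context: str
    onset_s: float
    offset_s: float
    raw_context: str = ""
    extras: tuple = ()  # opaque (key, value) pairs from extra input columns

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(
                f"context must be one of {CONTEXTS}, got {self.context!r}"
            )
        if not self.onset_s >= 0:
            raise ValidationError(f"onset_s must be >= 0, got {self.onset_s}")
        if not self.offset_s > self.onset_s:
            raise ValidationError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s}) "
                f"in recording {self.recording_id!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


class AnnotationSet:
    """A validated, ordered collection of calls grouped by recording.

    Construction sorts calls by ``(recording_id, onset_s)`` and enforces the
    non-overlap invariant: within a recording the next call's onset must be
    at or after the previous call's offset (a zero silent gap is valid and
    joins the two calls into one combination downstream).  Context must be
    constant within a recording.
    """

    def __init__(self, calls: Iterable[CallAnnotation]):
        self._calls = sorted(calls, key=lambda c: (c.recording_id, c.onset_s, c.offset_s))
        self._validate()

    def _validate(self) -> None:
        prev: CallAnnotation | None = None
        for i, call in enumerate(self._calls):
            if prev is not None and call.recording_id == prev.recording_id:
                if call.onset_s < prev.offset_s:
                    raise ValidationError(
                        f"overlapping calls in recording {call.recording_id!r}: "
                        f"call at {call.onset_s:.6f}s starts before the previous "
                        f"call ends at {prev.offset_s:.6f}s (sorted row {i})"
                    )
                if call.context != prev.context:
                    raise ValidationError(
                        f"context changes within recording {call.recording_id!r} "
                        f"({prev.context!r} -> {call.context!r})"
                    )
            prev = call

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[CallAnnotation]:
        return iter(self._calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self._calls, other._calls):
            if (
                a.recording_id != b.recording_id
                or a.individual_id != b.individual_id
                or a.context != b.context
                or abs(a.onset_s - b.onset_s) > 1e-9
                or abs(a.offset_s - b.offset_s) > 1e-9
            ):
                return False
        return True

    # -- views --------------------------------------------------------------
    @property
    def recordings(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self._calls:
            seen.setdefault(c.recording_id, None)
        return list(seen)

    def by_recording(self) -> dict[str, list[CallAnnotation]]:
        groups: dict[str, list[CallAnnotation]] = {}
        for c in self._calls:
            groups.setdefault(c.recording_id, []).append(c)
        return groups

    def context_of(self, recording_id: str) -> str:
        for c in self._calls:
            if c.recording_id == recording_id:
                return c.context
        raise KeyError(recording_id)

    def subset(self, recording_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(recording_ids)
        return AnnotationSet(c for c in self._calls if c.recording_id in keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "recording_id": c.recording_id,
                    "individual_id": c.individual_id,
                    "context": c.context,
                    "raw_context": c.raw_context,
                    "onset_s": c.onset_s,
                    "offset_s": c.offset_s,
                }
                for c in self._calls
            ],
            columns=CSV_COLUMNS,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, context_map: Mapping[str, str] | None = None
    ) -> "AnnotationSet":
        required = {"recording_id", "individual_id", "context", "onset_s", "offset_s"}
        missing = required - set(frame.columns)
        if missing:
            raise AnnotationFormatError(
                f"annotation frame is missing required columns: {sorted(missing)}"
            )
        calls = []
        for row in frame.itertuples(index=False):
            raw = getattr(row, "raw_context", "") or str(row.context)
            calls.append(
                CallAnnotation(
                    recording_id=str(row.recording_id),
                    individual_id=str(row.individual_id),
                    context=normalize_context(row.context, context_map),
                    raw_context=str(raw),
                    onset_s=float(row.onset_s),
                    offset_s=float(row.offset_s),
                )
            )
        return cls(calls)


def read_raven_table(
    path: str | Path,
    recording_id: str,
    individual_id: str,
    context: str,
    context_map: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read a Raven Pro selection table (tab-separated export).

    Only ``"Begin Time (s)"`` and ``"End Time (s)"`` are required; any other
    columns (``Selection``, ``View``, call-type labels, ...) are preserved as
    opaque per-call metadata because Raven exports vary by version.  The
    ``context`` argument may be a raw predator-model label (e.g. ``tiger``);
    it is normalised through ``context_map``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return AnnotationSet([])
    for col in (RAVEN_BEGIN, RAVEN_END):
        if col not in table.columns:
            raise AnnotationFormatError(
                f"{path}: not a Raven selection table — missing column {col!r}"
            )
    ctx = normalize_context(context, context_map)
    extra_cols = [c for c in table.columns if c not in (RAVEN_BEGIN, RAVEN_END)]
    calls = []
    for rownum, row in enumerate(table.itertuples(index=False), start=2):
        rowd = dict(zip(table.columns, row))
        onset = float(rowd[RAVEN_BEGIN])
        offset = float(rowd[RAVEN_END])
        if not offset > onset:
            raise ValidationError(
                f"{path} line {rownum}: End Time ({offset}) must exceed "
                f"Begin Time ({onset})"
            )
        calls.append(
            CallAnnotation(
                recording_id=recording_id,
                individual_id=individual_id,
                context=ctx,
                raw_context=str(context),
                onset_s=onset,
                offset_s=offset,
                extras=tuple((c, rowd[c]) for c in extra_cols),
            )
        )
    return AnnotationSet(calls)


def read_csv_annotations(
    path: str | Path, context_map: Mapping[str, str] | None = None
) -> AnnotationSet:
    """Read the package's flat CSV annotation format."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"recording_id": str, "individual_id": str})
    except pd.errors.EmptyDataError:
        return AnnotationSet([])
    if frame.empty and set(frame.columns) >= {"recording_id", "onset_s"}:
        return AnnotationSet([])
    return AnnotationSet.from_frame(frame, context_map)


def write_csv_annotations(annotations: AnnotationSet, path: str | Path) -> Path:
    """Write an :class:`AnnotationSet` so that reading it back is lossless.

    Onset/offset are written with full double precision (pandas' default
    float repr round-trips exactly).
    """
    path = Path(path)
    annotations.to_frame().to_csv(path, index=False)
    return path
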