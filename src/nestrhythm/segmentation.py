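"""Hierarchical segmentation of call sequences by silent-gap thresholds.

Alarm-call sequences are organised into three nested levels by the duration
of the silent gap (next onset minus current offset) between consecutive
calls:

* gap <= 0.2 s        -> same **combination**
* 0.2 s < gap <= 2 s  -> new combination, same **bout**
* 2 s < gap <= 20 s   -> new bout, same **series**
* gap > 20 s          -> new series

The boundary closure is half-open on the lower side of each band so every
non-negative gap is classified exactly once; gaps of exactly 0.2, 2 and 20 s
stay in the tighter unit, matching the inclusive "0.2 s or less" rule for
combinations and the strict "more than" lower bounds of the wider bands.

The walk over gaps is a single bottom-up pass; each gap is classified once,
so the resulting tree is unique and its leaves partition the recording's
calls in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotations_io import AnnotationSet, CallAnnotation
from .errors import ValidationError

LEVELS = ("combination", "bout", "series")


@dataclass(frozen=True)
class GapThresholds:
    """Silent-gap thresholds (seconds) separating the three levels."""

    combination_max_gap: float = 0.2
    bout_max_gap: float = 2.0
    series_max_gap: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.combination_max_gap < self.bout_max_gap < self.series_max_gap):
            raise ValidationError(
                "thresholds must satisfy 0 < combination < bout < series, got "
                f"{self.combination_max_gap}, {self.bout_max_gap}, {self.series_max_gap}"
            )

    def classify_gap(self, gap: float) -> str:
        """Classify a silent gap into the unit boundary it creates.

        Returns one of ``"combination"`` (gap joins two calls in the same
        combination), ``"bout"`` (new combination, same bout), ``"series"``
        (new bout, same series) or ``"new_series"``.
        """
        if gap < 0:
            raise ValidationError(f"negative silent gap ({gap}): calls overlap")
        if gap <= self.combination_max_gap:
            return "combination"
        if gap <= self.bout_max_gap:
            return "bout"
        if gap <= self.series_max_gap:
            return "series"
        return "new_series"


@dataclass
class Combination:
    call_indices: list[int]
    onset_s: float
    offset_s: float


@dataclass
class Bout:
    combinations: list[Combination]

    @property
    def onset_s(self) -> float:
        return self.combinations[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.combinations[-1].offset_s


@dataclass
class Series:
    bouts: list[Bout]

    @property
    def onset_s(self) -> float:
        return self.bouts[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.bouts[-1].offset_s


@dataclass
class RecordingTree:
    """Series -> bouts -> combinations -> call indices for one recording."""

    recording_id: str
    individual_id: str
    context: str
    calls: list[CallAnnotation]
    series: list[Series] = field(default_factory=list)

    def shape(self) -> list[list[list[int]]]:
        """Nested call counts: ``shape[series][bout][combination] = n_calls``."""
        return [
            [[len(c.call_indices) for c in b.combinations] for b in s.bouts]
            for s in self.series
        ]


class SegmentationTree:
    """Per-recording segmentation results plus the thresholds that built them."""

    def __init__(self, recordings: dict[str, RecordingTree], thresholds: GapThresholds):
        self.recordings = recordings
        self.thresholds = thresholds

    def __getitem__(self, recording_id: str) -> RecordingTree:
        return self.recordings[recording_id]

    def __iter__(self):
        return iter(self.recordings.values())

    def to_records(self) -> pd.DataFrame:
        """Flat leaf table: one row per call with its lineage indices."""
        rows = []
        for rec in self:
            for si, s in enumerate(rec.series):
                for bi, b in enumerate(s.bouts):
                    for ci, c in enumerate(b.combinations):
                        for idx in c.call_indices:
                            call = rec.calls[idx]
                            rows.append(
                                {
                                    "recording_id": rec.recording_id,
                                    "series_idx": si,
                                    "bout_idx": bi,
                                    "combination_idx": ci,
                                    "call_idx": idx,
                                    "onset_s": call.onset_s,
                                    "offset_s": call.offset_s,
                                }
                            )
        return pd.DataFrame(
            rows,
            columns=[
                "recording_id",
                "series_idx",
                "bout_idx",
                "combination_idx",
                "call_idx",
                "onset_s",
                "offset_s",
            ],
        )

    def to_dict(self) -> dict:
        """Nested JSON-serialisable representation."""
        out: dict = {"thresholds": vars(self.thresholds), "recordings": {}}
        for rec in self:
            out["recordings"][rec.recording_id] = {
                "individual_id": rec.individual_id,
                "context": rec.context,
                "series": [
                    {
                        "onset_s": s.onset_s,
                        "offset_s": s.offset_s,
                        "bouts": [
                            {
                                "onset_s": b.onset_s,
                                "offset_s": b.offset_s,
                                "combinations": [
                                    {
                                        "onset_s": c.onset_s,
                                        "offset_s": c.offset_s,
                                        "call_indices": list(c.call_indices),
                                    }
                                    for c in b.combinations
                                ],
                            }
                            for b in s.bouts
                        ],
                    }
                    for s in rec.series
                ],
            }
        return out


def _segment_recording(calls: list[CallAnnotation], thresholds: GapThresholds) -> list[Series]:
    if not calls:
        return []
    first = Combination([0], calls[0].onset_s, calls[0].offset_s)
    series_list = [Series([Bout([first])])]
    for i in range(1, len(calls)):
        gap = calls[i].onset_s - calls[i - 1].offset_s
        kind = thresholds.classify_gap(gap)
        comb = Combination([i], calls[i].onset_s, calls[i].offset_s)
        cur_series = series_list[-1]
        cur_bout = cur_series.bouts[-1]
        if kind == "combination":
            cur = cur_bout.combinations[-1]
            cur.call_indices.append(i)
            cur.offset_s = calls[i].offset_s
        elif kind == "bout":
            cur_bout.combinations.append(comb)
        elif kind == "series":
            cur_series.bouts.append(Bout([comb]))
        else:  # new_series
            series_list.append(Series([Bout([comb])]))
    return series_list


def segment(
    annotations: AnnotationSet, thresholds: GapThresholds | None = None
) -> SegmentationTree:
    """Build the combination/bout/series hierarchy for every recording.

    A single-call recording yields one series containing one bout containing
    one single-call combination.
    """
    thresholds = thresholds or GapThresholds()
    recordings: dict[str, RecordingTree] = {}
    for rec_id, calls in annotations.by_recording().items():
        recordings[rec_id] = RecordingTree(
            recording_id=rec_id,
            individual_id=calls[0].individual_id,
            context=calls[0].context,
            calls=calls,
            series=_segment_recording(calls, thresholds),
        )
    return SegmentationTree(recordings, thresholds)


def count_units(tree: SegmentationTree) -> pd.DataFrame:
    """Per-recording unit counts; sum the columns for overall totals.

    Returns a DataFrame indexed by recording_id with columns
    ``series, bouts, combinations, calls``.
    """
    rows = {}
    for rec in tree:
        n_bouts = sum(len(s.bouts) for s in rec.series)
        n_combs = sum(len(b.combinations) for s in rec.series for b in s.bouts)
        rows[rec.recording_id] = {
            "series": len(rec.series),
            "bouts": n_bouts,
            "combinations": n_combs,
            "calls": len(rec.calls),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["series", "bouts", "combinations", "calls"], dtype=int)
    df.index.name = "recording_id"
    return df
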