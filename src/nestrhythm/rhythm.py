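"""Inter-onset intervals, ratio statistics and rhythmic-category bins.

For each hierarchical level the inter-onset interval t_k is the time from
the onset of one unit to the onset of the next unit *under the same parent*
(calls within a combination; combinations within a bout; bouts within a
series).  The rhythm statistic is the ratio of adjacent intervals,

    r_k = t_k / (t_k + t_{k+1}),  0 < r_k < 1,

so a perfectly regular tempo gives r_k = 0.5 and interval pairs in 1:2,
1:3 and 2:1 duration ratio give 1/3, 1/4 and 2/3.  Ratios are never formed
across parent boundaries.

Each small-integer rhythmic category has an *on-integer* bin centred on its
nominal ratio and a two-segment *off-integer* bin flanking it; an excess of
on over off counts (after offsetting by bin width) is the statistical
signature of that rhythmic category.  The default boundaries are the
3-decimal values conventional in the comparative-rhythm literature
(e.g. 1:1 on = [0.444, 0.555]); an exact-fraction variant is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .segmentation import LEVELS, SegmentationTree

#: Nominal ratio of each rhythmic category.
NOMINAL_RATIOS = {"1:1": 0.5, "1:2": 1 / 3, "1:3": 0.25, "2:1": 2 / 3}


@dataclass(frozen=True)
class CategoryBins:
    """On/off bin boundaries for one rhythmic category.

    The on-integer bin is the closed interval ``[on_lo, on_hi]``; the
    off-integer bin is the union ``[off_lo, on_lo) U (on_hi, off_hi]``.
    """

    off_lo: float
    on_lo: float
    on_hi: float
    off_hi: float

    def __post_init__(self) -> None:
        if not (self.off_lo < self.on_lo < self.on_hi < self.off_hi):
            raise ValidationError(
                f"bin boundaries must be strictly increasing, got {self}"
            )

    @property
    def on_width(self) -> float:
        return self.on_hi - self.on_lo

    @property
    def off_width(self) -> float:
        return (self.on_lo - self.off_lo) + (self.off_hi - self.on_hi)


class RatioBinScheme:
    """An ordered set of rhythmic categories with on/off bin boundaries.

    Categories are checked in insertion order during classification, so a
    boundary point shared by two adjacent off-regions (e.g. r = 0.4 between
    the 1:2 and 1:1 off bins) is resolved deterministically in favour of the
    earlier category.  A point shared between an on bin and its own off bin
    belongs to the on bin.
    """

    def __init__(self, categories: Mapping[str, CategoryBins]):
        self.categories = dict(categories)
        for name, bins in self.categories.items():
            nominal = NOMINAL_RATIOS.get(name)
            if nominal is not None and not (bins.on_lo <= nominal <= bins.on_hi):
                raise ValidationError(
                    f"on-integer bin of {name} ({bins.on_lo}-{bins.on_hi}) does not "
                    f"contain its nominal ratio {nominal:.3f}"
                )

    @classmethod
    def default(cls) -> "RatioBinScheme":
        """The conventional 3-decimal boundaries."""
        return cls(
            {
                "1:1": CategoryBins(0.400, 0.444, 0.555, 0.600),
                "1:2": CategoryBins(0.286, 0.308, 0.364, 0.400),
                "1:3": CategoryBins(0.222, 0.235, 0.267, 0.286),
                "2:1": CategoryBins(0.600, 0.636, 0.692, 0.714),
            }
        )

    @classmethod
    def exact_fractions(cls) -> "RatioBinScheme":
        """The same bins with exact small-fraction boundaries.

        The conventional decimals are truncations of these fractions
        (0.444 = 4/9, 0.555 = 5/9, 0.308 = 4/13, ...).
        """
        return cls(
            {
                "1:1": CategoryBins(2 / 5, 4 / 9, 5 / 9, 3 / 5),
                "1:2": CategoryBins(2 / 7, 4 / 13, 4 / 11, 2 / 5),
                "1:3": CategoryBins(2 / 9, 4 / 17, 4 / 15, 2 / 7),
                "2:1": CategoryBins(3 / 5, 7 / 11, 9 / 13, 5 / 7),
            }
        )

    def labels(self, categories: Iterable[str] | None = None) -> list[str]:
        cats = list(categories) if categories is not None else list(self.categories)
        out = []
        for c in cats:
            out.extend([f"{c} off", f"{c} on"])
        return out

    def label_width(self, label: str) -> float:
        category, kind = label.rsplit(" ", 1)
        bins = self.categories[category]
        return bins.on_width if kind == "on" else bins.off_width

    def classify(self, r: float) -> str:
        return classify_ratio(r, self)


def classify_ratio(r: float, scheme: RatioBinScheme | None = None) -> str:
    """Assign a ratio to an on/off-integer bin label, or ``"unbinned"``.

    Classification is total on (0, 1): every ratio gets exactly one label.
    """
    scheme = scheme or RatioBinScheme.default()
    if not (0 < r < 1):
        raise ValidationError(f"ratio must lie strictly in (0, 1), got {r}")
    for name, bins in scheme.categories.items():
        if bins.on_lo <= r <= bins.on_hi:
            return f"{name} on"
        if bins.off_lo <= r < bins.on_lo or bins.on_hi < r <= bins.off_hi:
            return f"{name} off"
    return "unbinned"


INTERVAL_COLUMNS = [
    "level",
    "recording_id",
    "individual_id",
    "context",
    "series_idx",
    "bout_idx",
    "combination_idx",
    "parent_id",
    "k",
    "t_k",
]


def compute_intervals(
    tree: SegmentationTree, levels: Sequence[str] | str | None = None
) -> pd.DataFrame:
    """Inter-onset intervals t_k per level, tagged with lineage and context.

    A parent with m children contributes m - 1 intervals; parents with a
    single child contribute nothing.  ``parent_id`` identifies the parent
    group so that downstream ratio computation never crosses parents.
    """
    if levels is None:
        levels = LEVELS
    elif isinstance(levels, str):
        levels = (levels,)
    for lv in levels:
        if lv not in LEVELS:
            raise ValidationError(f"unknown level {lv!r}; expected one of {LEVELS}")

    rows = []

    def add(level, rec, si, bi, ci, parent, onsets):
        for k in range(len(onsets) - 1):
            t_k = onsets[k + 1] - onsets[k]
            rows.append(
                {
                    "level": level,
                    "recording_id": rec.recording_id,
                    "individual_id": rec.individual_id,
                    "context": rec.context,
                    "series_idx": si,
                    "bout_idx": bi,
                    "combination_idx": ci,
                    "parent_id": parent,
                    "k": k,
                    "t_k": t_k,
                }
            )

    for rec in tree:
        for si, s in enumerate(rec.series):
            if "series" in levels:
                onsets = [b.onset_s for b in s.bouts]
                add("series", rec, si, -1, -1, f"{rec.recording_id}/s{si}", onsets)
            for bi, b in enumerate(s.bouts):
                if "bout" in levels:
                    onsets = [c.onset_s for c in b.combinations]
                    add("bout", rec, si, bi, -1, f"{rec.recording_id}/s{si}/b{bi}", onsets)
                if "combination" in levels:
                    for ci, c in enumerate(b.combinations):
                        onsets = [rec.calls[i].onset_s for i in c.call_indices]
                        add(
                            "combination",
                            rec,
                            si,
                            bi,
                            ci,
                            f"{rec.recording_id}/s{si}/b{bi}/c{ci}",
                            onsets,
                        )
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def compute_ratios(intervals: pd.DataFrame) -> pd.DataFrame:
    """Ratios of adjacent intervals within each parent group.

    For a parent with j intervals this yields max(j - 1, 0) ratios
    r_k = t_k / (t_k + t_{k+1}).
    """
    if not intervals.empty and (intervals["t_k"] <= 0).any():
        bad = intervals.loc[intervals["t_k"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive interval t_k={bad['t_k']} in parent {bad['parent_id']!r}"
        )
    rows = []
    if not intervals.empty:
        for (level, parent), grp in intervals.groupby(["level", "parent_id"], sort=False):
            grp = grp.sort_values("k")
            t = grp["t_k"].to_numpy()
            meta = grp.iloc[0]
            for k in range(len(t) - 1):
                rows.append(
                    {
                        "level": level,
                        "recording_id": meta["recording_id"],
                        "individual_id": meta["individual_id"],
                        "context": meta["context"],
                        "parent_id": parent,
                        "k": k,
                        "t_first": t[k],
                        "t_second": t[k + 1],
                        "r_k": t[k] / (t[k] + t[k + 1]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "recording_id",
            "individual_id",
            "context",
            "parent_id",
            "k",
            "t_first",
            "t_second",
            "r_k",
        ],
    )


def classify_ratios(ratios: pd.DataFrame, scheme: RatioBinScheme | None = None) -> pd.DataFrame:
    """Add a ``bin_label`` column to a ratio table."""
    scheme = scheme or RatioBinScheme.default()
    out = ratios.copy()
    out["bin_label"] = [classify_ratio(r, scheme) for r in out["r_k"]] if len(out) else []
    return out


def tabulate_counts(
    ratios: pd.DataFrame,
    scheme: RatioBinScheme | None = None,
    labels: Sequence[str] | None = None,
    recordings: Sequence[str] | None = None,
    contexts: Mapping[str, str] | None = None,
    level: str | None = None,
) -> pd.DataFrame:
    """Zero-filled r_k counts per recording x bin, with bin widths.

    Every (recording, label) cell appears even when its count is zero — the
    zero-inflated count model needs the explicit zeros.  ``recordings`` may
    list recordings absent from ``ratios`` (e.g. recordings with no interval
    pairs at this level); ``contexts`` maps recording_id to its context.
    """
    scheme = scheme or RatioBinScheme.default()
    if labels is None:
        labels = scheme.labels()
    data = ratios
    if level is not None:
        data = data.loc[data["level"] == level]
    if "bin_label" not in data.columns:
        data = classify_ratios(data, scheme)
    if recordings is None:
        recordings = list(dict.fromkeys(data["recording_id"])) if len(data) else []
    if contexts is None:
        contexts = (
            dict(zip(data["recording_id"], data["context"])) if len(data) else {}
        )
    counted = (
        data.groupby(["recording_id", "bin_label"]).size() if len(data) else pd.Series(dtype=int)
    )
    rows = []
    for rec in recordings:
        for label in labels:
            rows.append(
                {
                    "recording_id": rec,
                    "level": level if level is not None else "all",
                    "bin_label": label,
                    "count": int(counted.get((rec, label), 0)),
                    "bin_width": scheme.label_width(label),
                    "context": contexts.get(rec, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["recording_id", "level", "bin_label", "count", "bin_width", "context"],
    )


def ratio_density(
    ratios: Sequence[float] | pd.Series,
    bandwidth: float | None = None,
    gridsize: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of ratios on (0, 1) with boundary reflection.

    The reflection at both edges keeps the estimate a proper density on the
    unit interval (it integrates to 1).  Bandwidth defaults to a Silverman
    rule computed from the data, floored at 0.005 so degenerate samples do
    not collapse the kernel.
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim and r.size < 2:
        raise InsufficientDataError("density estimation needs at least 2 ratios")
    if np.any((r <= 0) | (r >= 1)):
        raise ValidationError("ratios must lie strictly in (0, 1)")
    n = r.size
    if bandwidth is None:
        sd = float(np.std(r, ddof=1))
        iqr = float(np.subtract(*np.percentile(r, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = max(0.9 * spread * n ** (-1 / 5), 0.005)
    grid = np.linspace(0.0, 1.0, gridsize)
    # reflect the sample about both boundaries, then evaluate a plain KDE
    pts = np.concatenate([r, -r, 2.0 - r])
    z = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (n * bandwidth * math.sqrt(2 * math.pi))
    return grid, dens
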