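"""Shared fixtures: the hand-worked five-call example and a default
synthetic dataset."""

import numpy as np
import pytest

from nestrhythm import (
    AnnotationSet,
    CallAnnotation,
    SyntheticConfig,
    generate_dataset,
    segment,
)

#: Five calls spanning all four gap bands: gaps 0.15 (same combination),
#: 0.65 (new combination, same bout), 2.9 (new bout, same series),
#: 25.9 (new series).
WORKED_TIMES = [(0.0, 0.1), (0.25, 0.35), (1.0, 1.1), (4.0, 4.1), (30.0, 30.1)]


@pytest.fixture
def worked_annotations() -> AnnotationSet:
    return AnnotationSet(
        CallAnnotation("r1", "f1", "natural", on, off) for on, off in WORKED_TIMES
    )


@pytest.fixture
def worked_tree(worked_annotations):
    return segment(worked_annotations)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (14 recordings, both contexts)."""
    return generate_dataset(SyntheticConfig(), seed=2026)


def naive_segment_shape(onsets, offsets, thresholds):
    """Independent top-down reference segmentation.

    Splits the call sequence at gaps > series threshold into series, each
    series at gaps > bout threshold into bouts, each bout at gaps > the
    combination threshold into combinations — three separate passes, unlike
    the implementation's single bottom-up walk.  Returns the nested shape
    (calls per combination per bout per series).
    """

    def split(idx, max_gap):
        parts, cur = [], [idx[0]]
        for i in idx[1:]:
            if onsets[i] - offsets[i - 1] > max_gap:
                parts.append(cur)
                cur = [i]
            else:
                cur.append(i)
        parts.append(cur)
        return parts

    idx = list(range(len(onsets)))
    shape = []
    for series in split(idx, thresholds.series_max_gap):
        series_shape = []
        for bout in split(series, thresholds.bout_max_gap):
            bout_shape = [
                len(comb) for comb in split(bout, thresholds.combination_max_gap)
            ]
            series_shape.append(bout_shape)
        shape.append(series_shape)
    return shape


def random_gap_sequence(rng: np.random.Generator, n_calls: int):
    """Onsets/offsets whose gaps span all four bands, including the exact
    boundary values 0.2, 2 and 20 s."""
    band_choices = [
        lambda: rng.uniform(0.0, 0.2),
        lambda: rng.uniform(0.2, 2.0),
        lambda: rng.uniform(2.0, 20.0),
        lambda: rng.uniform(20.0, 40.0),
        lambda: float(rng.choice([0.0, 0.2, 2.0, 20.0])),
    ]
    onsets, offsets = [0.0], [rng.uniform(0.02, 0.1)]
    for _ in range(n_calls - 1):
        gap = band_choices[rng.integers(len(band_choices))]()
        onset = offsets[-1] + gap
        onsets.append(onset)
        offsets.append(onset + rng.uniform(0.02, 0.1))
    return onsets, offsets
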