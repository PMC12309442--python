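"""Synthetic annotation datasets with third-order self-embedded isochrony.

The generator inverts the segmentation rules: it lays down a nested point
process with a regular tempo at each level —

* calls within a combination spaced ``tempo_combination`` (default 0.259 s)
  onset-to-onset,
* combinations within a bout spaced ``tempo_bout`` (default 1.11 s),
* bouts within a series spaced ``tempo_series`` (default 8.74 s),
* series separated by a long silent gap (default 30 s, always > 20 s)

— with small multiplicative renewal jitter on every interval, and draws
call durations so that the silent gaps between units fall inside the
segmentation bands (<= 0.2 s within combinations, (0.2, 2] s between
combinations, (2, 20] s between bouts).  Each emitted dataset carries its
generating tree as ground truth, so ``segment(generate(...))`` must
reproduce the tree node-for-node.

Context effects emulate the study conditions: recordings under the
non-natural context get a slower bout tempo (log effect 0.167 by default)
and, optionally, degraded combination-level isochrony (extra jitter, or
alternating long-short call intervals that push ratios toward 1/3 and 2/3).

Jitter is renewal-style by default (each interval drawn independently, so
timing errors accumulate along a sequence); a metronome mode that jitters
onsets around a fixed grid is available via ``metronome=True``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations_io import AnnotationSet, CallAnnotation, write_csv_annotations
from .errors import GenerationError, ValidationError
from .segmentation import GapThresholds

MAX_RESAMPLE = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults emulate the study conditions
    (14 recordings from 7 females, ~1/4 natural-predator contexts, level
    tempos 0.259 / 1.11 / 8.74 s)."""

    n_recordings: int = 14
    n_individuals: int = 7
    n_series: int = 3
    bouts_per_series: int = 3
    combinations_per_bout: int = 3
    calls_per_combination: int = 4
    tempo_combination: float = 0.259  # s, call onset spacing within a combination
    tempo_bout: float = 1.11  # s, combination onset spacing within a bout
    tempo_series: float = 8.74  # s, bout onset spacing within a series
    inter_series_gap: float = 30.0  # s, silent gap between series (> 20)
    jitter_cv: float = 0.05  # coefficient of variation of interval jitter
    call_duration_min: float = 0.04
    call_duration_max: float = 0.12
    call_duration_floor: float = 0.01  # hard lower bound when a gap band binds
    combination_gap_cap: float = 0.18  # 0.9 x the 0.2 s combination threshold
    natural_every: int = 4  # recording i is natural when i % natural_every == 0
    bout_tempo_log_effect: float = 0.167  # non_natural bouts are slower by e^effect
    combination_isochrony_mode: str = "off"  # off | extra_jitter | alternating
    extra_jitter_cv: float = 0.15
    alternating_factor: float = 2.0  # long interval = factor x short interval
    metronome: bool = False
    thresholds: GapThresholds = field(default_factory=GapThresholds)

    def __post_init__(self) -> None:
        if not (0 < self.tempo_combination < self.tempo_bout < self.tempo_series):
            raise ValidationError("level tempos must be ordered T_comb < T_bout < T_series")
        if self.combination_isochrony_mode not in (
            "off",
            "extra_jitter",
            "alternating",
            "arrhythmic",
        ):
            raise ValidationError(
                f"unknown combination_isochrony_mode {self.combination_isochrony_mode!r}"
            )
        if not 0 <= self.jitter_cv < 1 / 3:
            raise ValidationError("jitter_cv must lie in [0, 1/3) (jitter truncated at 3 cv)")
        if self.call_duration_min <= 0 or self.call_duration_max < self.call_duration_min:
            raise ValidationError("invalid call-duration range")
        if self.call_duration_max >= self.tempo_combination * (1 - 3 * self.jitter_cv):
            raise ValidationError("call durations must be shorter than the shortest call interval")
        if self.inter_series_gap * (1 - 3 * self.jitter_cv) <= self.thresholds.series_max_gap:
            raise ValidationError("inter_series_gap too small: series would merge")

    def context_for(self, index: int) -> str:
        return "natural" if index % self.natural_every == 0 else "non_natural"


@dataclass
class GroundTruth:
    """The generating structure: per recording the nested call counts
    (shape[series][bout][combination]), the tempos, and the context effect."""

    seed: int
    config: SyntheticConfig
    shapes: dict[str, list[list[list[int]]]]
    contexts: dict[str, str]
    individuals: dict[str, str]
    tempos: dict[str, float]
    bout_tempo_log_effect: float

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["thresholds"] = asdict(self.config.thresholds)
        return {
            "seed": self.seed,
            "config": cfg,
            "shapes": self.shapes,
            "contexts": self.contexts,
            "individuals": self.individuals,
            "tempos": self.tempos,
            "bout_tempo_log_effect": self.bout_tempo_log_effect,
        }


def _jitter(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor 1 + eps, eps ~ N(0, cv^2) truncated at +-3 cv."""
    if cv == 0:
        return 1.0
    eps = rng.normal(0.0, cv)
    while abs(eps) > 3 * cv:
        eps = rng.normal(0.0, cv)
    return 1.0 + eps


def _call_intervals(config: SyntheticConfig, context: str, rng: np.random.Generator) -> np.ndarray:
    """Onset-to-onset intervals between the calls of one combination."""
    n = config.calls_per_combination - 1
    if n <= 0:
        return np.zeros(0)
    T = config.tempo_combination
    mode = config.combination_isochrony_mode if context == "non_natural" else "off"
    cv = config.extra_jitter_cv if mode == "extra_jitter" else config.jitter_cv
    if mode == "arrhythmic":
        # memoryless renewal at the same mean rate: the adjacent-interval
        # ratio of i.i.d. exponential intervals is uniform on (0, 1), i.e.
        # no rhythmic category at all
        floor = max(2 * config.call_duration_floor, 0.02)
        iv = rng.exponential(T, n)
        for _ in range(MAX_RESAMPLE):
            short = iv < floor
            if not short.any():
                break
            iv[short] = rng.exponential(T, int(short.sum()))
        else:
            raise GenerationError("could not draw positive arrhythmic intervals")
        return iv
    if mode == "alternating":
        f = config.alternating_factor
        short = T * 2.0 / (1.0 + f)
        base = np.array([short if k % 2 == 0 else short * f for k in range(n)])
    else:
        base = np.full(n, T)
    if config.metronome:
        # jitter onsets around the fixed grid, then difference
        onsets = np.concatenate([[0.0], np.cumsum(base)])
        onsets[1:] += np.array([base[k] * (_jitter(rng, cv) - 1.0) for k in range(n)])
        iv = np.diff(onsets)
    else:
        iv = np.array([base[k] * _jitter(rng, cv) for k in range(n)])
    if np.any(iv <= 0):
        raise GenerationError("non-positive call interval generated; reduce jitter")
    return iv


_GAP_EPS = 1e-6


def _build_combination(
    config: SyntheticConfig,
    context: str,
    rng: np.random.Generator,
    last_duration_cap: float | None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Relative call onsets and durations for one combination.

    Durations of non-final calls are drawn so the within-combination silent
    gap stays in (0, combination_gap_cap]; when the configured duration
    ceiling cannot keep the gap under the cap (long alternating intervals),
    the duration is extended to hold the gap at the cap.  The final call's
    duration is capped at ``last_duration_cap`` (imposed by the silent gap
    to the next combination); returns ``None`` if even the duration floor
    cannot satisfy that cap, so the caller can redraw the call intervals.
    """
    intervals = _call_intervals(config, context, rng)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    durations = np.empty(len(onsets))
    cap = config.combination_gap_cap
    for k in range(len(intervals)):
        hi = min(config.call_duration_max, intervals[k] - _GAP_EPS)
        if hi < config.call_duration_floor:
            return None  # interval too short for any call: redraw intervals
        lo = max(config.call_duration_min, intervals[k] - cap)
        if lo > hi:
            # duration pinned: either the cap binds (long interval) or the
            # interval is shorter than the configured minimum duration
            durations[k] = max(intervals[k] - cap, config.call_duration_floor)
            durations[k] = min(durations[k], intervals[k] - _GAP_EPS)
        else:
            durations[k] = rng.uniform(lo, hi)
    # final call
    hi = config.call_duration_max if last_duration_cap is None else min(
        config.call_duration_max, last_duration_cap
    )
    if hi < config.call_duration_floor:
        return None
    lo = min(config.call_duration_min, hi)
    durations[-1] = rng.uniform(lo, hi) if hi > lo else hi
    return onsets, durations


def generate_recording(
    config: SyntheticConfig,
    recording_id: str,
    individual_id: str,
    context: str,
    seed: int | np.random.Generator,
) -> tuple[AnnotationSet, list[list[list[int]]]]:
    """Generate one recording; returns its annotations and ground-truth shape.

    The onset-to-onset spacings at every level — which carry the tempos —
    are drawn once and never rejected, so the realised interval
    distributions match the configured ones exactly.  The silent-gap bands
    are satisfied by adapting call durations (within-combination gaps are
    capped directly; the last call of a combination is shortened, down to
    ``call_duration_floor``, so the gap to the next combination stays above
    the combination threshold).  Only combination internals are redrawn
    (up to 100 times) when durations alone cannot fit; a persistent
    violation raises a :class:`GenerationError` naming the band.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thr = config.thresholds
    bout_mult = (
        float(np.exp(config.bout_tempo_log_effect)) if context == "non_natural" else 1.0
    )

    calls: list[CallAnnotation] = []
    shape: list[list[list[int]]] = []
    last_offset: float | None = None  # offset of the last call emitted

    def emit(start: float, onsets: np.ndarray, durations: np.ndarray) -> float:
        for onset, dur in zip(onsets, durations):
            calls.append(
                CallAnnotation(
                    recording_id=recording_id,
                    individual_id=individual_id,
                    context=context,
                    raw_context=context,
                    onset_s=start + onset,
                    offset_s=start + onset + dur,
                )
            )
        return start + onsets[-1] + durations[-1]

    for s in range(config.n_series):
        series_shape: list[list[int]] = []
        if last_offset is None:
            series_onset = 0.0
        else:
            for _ in range(MAX_RESAMPLE):
                gap = config.inter_series_gap * _jitter(rng, config.jitter_cv)
                if gap > thr.series_max_gap:
                    break
            else:
                raise GenerationError(
                    f"could not draw an inter-series gap > {thr.series_max_gap}s "
                    "(band: new series)"
                )
            series_onset = last_offset + gap
        bout_onset = series_onset
        prev_bout_offset: float | None = None
        for b in range(config.bouts_per_series):
            if b > 0:
                # bout spacing (the series-level t_k); the band never binds at
                # sane configs, so the retry is a feasibility guard only
                for _ in range(MAX_RESAMPLE):
                    spacing = config.tempo_series * _jitter(rng, config.jitter_cv)
                    candidate = bout_onset + spacing
                    gap = candidate - prev_bout_offset
                    if thr.bout_max_gap < gap <= thr.series_max_gap:
                        bout_onset = candidate
                        break
                else:
                    raise GenerationError(
                        "could not place a bout with silent gap in "
                        f"({thr.bout_max_gap}, {thr.series_max_gap}]s (band: series level)"
                    )
            bout_shape: list[int] = []
            # combination spacings are the bout-level t_k: drawn once, kept
            spacings = [
                config.tempo_bout * bout_mult * _jitter(rng, config.jitter_cv)
                for _ in range(config.combinations_per_bout - 1)
            ]
            comb_onset = bout_onset
            for c in range(config.combinations_per_bout):
                next_spacing = (
                    spacings[c] if c < config.combinations_per_bout - 1 else None
                )
                built = None
                for _ in range(MAX_RESAMPLE):
                    built = _build_combination(
                        config,
                        context,
                        rng,
                        last_duration_cap=None if next_spacing is None else np.inf,
                    )
                    if built is None:
                        continue
                    onsets, durations = built
                    if next_spacing is not None:
                        span = float(onsets[-1])
                        cap = next_spacing - span - thr.combination_max_gap - _GAP_EPS
                        if cap < config.call_duration_floor:
                            built = None
                            continue  # redraw the call intervals
                        hi = min(config.call_duration_max, cap)
                        lo = min(config.call_duration_min, hi)
                        durations[-1] = rng.uniform(lo, hi) if hi > lo else hi
                        gap = next_spacing - span - durations[-1]
                        if gap > thr.bout_max_gap:
                            # duration cannot stretch the gap under the bout
                            # threshold within its range: pin it
                            need = next_spacing - span - thr.bout_max_gap
                            durations[-1] = need + _GAP_EPS
                    break
                if built is None:
                    raise GenerationError(
                        "could not place a combination with silent gap in "
                        f"({thr.combination_max_gap}, {thr.bout_max_gap}]s "
                        "(band: bout level)"
                    )
                end = emit(comb_onset, onsets, durations)
                bout_shape.append(len(onsets))
                if next_spacing is not None:
                    comb_onset = comb_onset + next_spacing
                prev_bout_offset = end
            series_shape.append(bout_shape)
        shape.append(series_shape)
        last_offset = prev_bout_offset
    return AnnotationSet(calls), shape


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[AnnotationSet, GroundTruth]:
    """Generate a full dataset of ``n_recordings`` recordings.

    Recordings are assigned to individuals round-robin and to contexts by
    the configured cycle (default: every 4th recording natural, matching
    one natural print among four predator models).  Identical
    ``(config, seed)`` give byte-identical output.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    all_calls: list[CallAnnotation] = []
    shapes: dict[str, list[list[list[int]]]] = {}
    contexts: dict[str, str] = {}
    individuals: dict[str, str] = {}
    for i in range(config.n_recordings):
        rec_id = f"rec{i:02d}"
        ind_id = f"ind{i % config.n_individuals}"
        ctx = config.context_for(i)
        annotations, shape = generate_recording(config, rec_id, ind_id, ctx, rng)
        all_calls.extend(annotations)
        shapes[rec_id] = shape
        contexts[rec_id] = ctx
        individuals[rec_id] = ind_id
    truth = GroundTruth(
        seed=seed,
        config=config,
        shapes=shapes,
        contexts=contexts,
        individuals=individuals,
        tempos={
            "combination": config.tempo_combination,
            "bout": config.tempo_bout,
            "series": config.tempo_series,
        },
        bout_tempo_log_effect=config.bout_tempo_log_effect,
    )
    return AnnotationSet(all_calls), truth


def write_dataset(
    annotations: AnnotationSet, truth: GroundTruth, outdir: str | Path
) -> dict:
    """Write annotations CSV, ground_truth.json and a manifest with the seed
    and a content hash; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_path = write_csv_annotations(annotations, outdir / "annotations.csv")
    truth_dict = truth.to_dict()
    (outdir / "ground_truth.json").write_text(json.dumps(truth_dict, indent=2))
    content_hash = hashlib.sha256(ann_path.read_bytes()).hexdigest()
    manifest = {
        "seed": truth.seed,
        "n_recordings": truth.config.n_recordings,
        "n_calls": len(annotations),
        "annotations": ann_path.name,
        "ground_truth": "ground_truth.json",
        "content_sha256": content_hash,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
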