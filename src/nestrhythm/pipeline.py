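"""End-to-end orchestration: annotations -> segmentation -> intervals and
ratios -> rhythmic-category counts -> count and tempo models -> report.

The count model is fitted per level with the factor levels used in the
study design: combination and series levels test {1:1 off, 1:1 on}; the
bout level, whose ratio distribution is bimodal with a secondary peak near
0.25, additionally tests {1:3 off, 1:3 on}.  Each level is analysed on the
full dataset and on the natural / non-natural context subsets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotations_io import AnnotationSet
from .errors import FitError, InsufficientDataError, NestRhythmError, ValidationError
from .rhythm import (
    RatioBinScheme,
    classify_ratios,
    compute_intervals,
    compute_ratios,
    ratio_density,
    tabulate_counts,
)
from .segmentation import LEVELS, GapThresholds, count_units, segment
from .stats_models import (
    fit_tempo_lmm,
    fit_zip_glmm,
    lrt_full_vs_null,
    pairwise_contrasts,
)

#: Rhythmic categories tested per level (the bout level is bimodal).
LEVEL_CATEGORIES: dict[str, list[str]] = {
    "combination": ["1:1"],
    "bout": ["1:1", "1:3"],
    "series": ["1:1"],
}

SCOPES = ("all", "natural", "non_natural")


def tempo_layer_ratio(level_means: Mapping[str, float] | Sequence[float]) -> tuple[int, int, int]:
    """Smallest-integer tempo triple across the three levels, scaled so the
    first term is 2 (the convention under which 0.259 : 1.11 : 8.74 reads
    2:9:67)."""
    if isinstance(level_means, Mapping):
        try:
            means = [level_means[lv] for lv in LEVELS]
        except KeyError as exc:
            raise ValidationError(f"missing level mean for {exc.args[0]!r}") from exc
    else:
        means = list(level_means)
    if len(means) != 3:
        raise ValidationError("need exactly three level means")
    if any(m is None or not np.isfinite(m) or m <= 0 for m in means):
        raise ValidationError(f"level means must be positive and finite, got {means}")
    m1, m2, m3 = sorted(means)
    return (2, round(2 * m2 / m1), round(2 * m3 / m1))


def _fit_level_scope(
    counts: pd.DataFrame, adjust: str, n_quad: int
) -> dict:
    """Full and null count-model fits plus LRT and contrasts for one
    level x scope cell; returns a JSON-ready dict."""
    full = fit_zip_glmm(counts, n_quad=n_quad)
    null = fit_zip_glmm(counts, intercept_only=True, n_quad=n_quad, compute_se=False)
    lrt = lrt_full_vs_null(full, null)
    contrasts = pairwise_contrasts(full, adjust=adjust)
    # the headline per-category "off vs on" contrasts
    category_tests = [
        c.to_dict()
        for c in contrasts
        if c.level_a.rsplit(" ", 1)[0] == c.level_b.rsplit(" ", 1)[0]
    ]
    return {
        "n_ratios": int(counts["count"].sum()),
        "n_recordings": int(counts["recording_id"].nunique()),
        "counts_by_bin": {
            lab: int(n)
            for lab, n in counts.groupby("bin_label")["count"].sum().items()
        },
        "fit": full.to_dict(),
        "lrt": lrt.to_dict(),
        "contrasts": [c.to_dict() for c in contrasts],
        "category_tests": category_tests,
    }


def run_analysis(
    annotations: AnnotationSet,
    thresholds: GapThresholds | None = None,
    scheme: RatioBinScheme | None = None,
    *,
    adjust: str = "tukey",
    n_quad: int = 25,
    seed: int = 0,
) -> dict:
    """Run the full analysis and return the report as a plain dict.

    The report is deterministic for identical inputs; ``seed`` is recorded
    in the provenance block (all model fits are themselves deterministic).
    Raises a structured error without emitting a partial report if any
    stage fails on invalid input.
    """
    if len(annotations) == 0:
        raise ValidationError("empty annotation set: nothing to analyse")
    thresholds = thresholds or GapThresholds()
    scheme = scheme or RatioBinScheme.default()

    tree = segment(annotations, thresholds)
    units = count_units(tree)
    intervals = compute_intervals(tree)
    ratios = classify_ratios(compute_ratios(intervals), scheme)

    rec_context = {rec.recording_id: rec.context for rec in tree}
    all_recordings = list(rec_context)

    levels_report: dict = {}
    bin_count_frames = []
    for level in LEVELS:
        labels = scheme.labels(LEVEL_CATEGORIES[level])
        level_report: dict = {}
        for scope in SCOPES:
            recs = [
                r
                for r in all_recordings
                if scope == "all" or rec_context[r] == scope
            ]
            sub = ratios.loc[
                (ratios["level"] == level) & (ratios["recording_id"].isin(recs))
            ]
            counts = tabulate_counts(
                sub,
                scheme,
                labels=labels,
                recordings=recs,
                contexts=rec_context,
                level=level,
            )
            if scope == "all":
                bin_count_frames.append(counts)
            try:
                level_report[scope] = _fit_level_scope(counts, adjust, n_quad)
            except (FitError, NestRhythmError) as exc:
                level_report[scope] = {
                    "skipped": str(exc),
                    "n_ratios": int(counts["count"].sum()),
                }
        levels_report[level] = level_report

    # tempo model across all levels
    tempo_report: dict
    level_means = (
        intervals.groupby("level")["t_k"].mean().reindex(list(LEVELS)).to_dict()
    )
    contexts_present = sorted(set(rec_context.values()))
    if len(contexts_present) == 2 and not intervals.empty:
        tempo_fit = fit_tempo_lmm(intervals)
        tempo_report = tempo_fit.to_dict()
        tempo_report["context_contrasts"] = [
            c.to_dict() for c in tempo_fit.context_contrasts(adjust=adjust)
        ]
        tempo_report["pairwise"] = [
            c.to_dict() for c in pairwise_contrasts(tempo_fit, adjust=adjust)
        ]
    else:
        tempo_report = {
            "skipped": "tempo model needs both contexts present",
            "contexts_present": contexts_present,
        }
    tempo_report["level_means_s"] = level_means
    if all(m is not None and np.isfinite(m) and m > 0 for m in level_means.values()):
        tempo_report["layer_ratio"] = list(tempo_layer_ratio(level_means))

    frame_hash = hashlib.sha256(
        annotations.to_frame().to_csv(index=False).encode()
    ).hexdigest()

    return {
        "provenance": {
            "package": "nestrhythm",
            "version": __version__,
            "seed": seed,
            "thresholds": {
                "combination_max_gap": thresholds.combination_max_gap,
                "bout_max_gap": thresholds.bout_max_gap,
                "series_max_gap": thresholds.series_max_gap,
            },
            "bin_scheme": {
                name: [b.off_lo, b.on_lo, b.on_hi, b.off_hi]
                for name, b in scheme.categories.items()
            },
            "adjust": adjust,
            "n_quad": n_quad,
            "input_sha256": frame_hash,
            "n_recordings": len(all_recordings),
        },
        "unit_counts": {
            "per_recording": units.to_dict(orient="index"),
            "total": {k: int(v) for k, v in units.sum().items()},
        },
        "levels": levels_report,
        "tempo": tempo_report,
        "_tables": {  # dataframes for CSV export; stripped from report.json
            "intervals": intervals,
            "ratios": ratios,
            "bin_counts": pd.concat(bin_count_frames, ignore_index=True)
            if bin_count_frames
            else pd.DataFrame(),
        },
    }


def write_report(report: dict, outdir: str | Path, plots: bool = False) -> Path:
    """Write report.json plus the flat CSV tables (and optional density
    panels) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.get("_tables", {})
    serialisable = {k: v for k, v in report.items() if k != "_tables"}
    (outdir / "report.json").write_text(json.dumps(serialisable, indent=2, sort_keys=True))
    if "intervals" in tables:
        tables["intervals"].to_csv(outdir / "intervals.csv", index=False)
    if "ratios" in tables:
        tables["ratios"].to_csv(outdir / "ratios.csv", index=False)
    if "bin_counts" in tables:
        tables["bin_counts"].to_csv(outdir / "bin_counts.csv", index=False)
    rows = []
    for level, scopes in report.get("levels", {}).items():
        for scope, res in scopes.items():
            for c in res.get("contrasts", []):
                rows.append({"model": f"{level}/{scope}", **c})
    for c in report.get("tempo", {}).get("context_contrasts", []):
        rows.append({"model": "tempo", **c})
    pd.DataFrame(rows).to_csv(outdir / "contrasts.csv", index=False)
    if plots and "ratios" in tables:
        _density_plots(tables["ratios"], outdir)
    return outdir / "report.json"


def _density_plots(ratios: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=False)
    for ax, level in zip(axes, LEVELS):
        vals = ratios.loc[ratios["level"] == level, "r_k"]
        ax.set_title(f"{level} level (n={len(vals)})")
        ax.set_xlabel("$r_k$")
        try:
            grid, dens = ratio_density(vals)
            ax.plot(grid, dens)
        except (InsufficientDataError, ValidationError):
            ax.text(0.5, 0.5, "too few ratios", ha="center")
        for x in (0.25, 1 / 3, 0.5, 2 / 3):
            ax.axvline(x, color="grey", lw=0.5, ls=":")
    axes[0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(outdir / "ratio_density.png", dpi=150)
    plt.close(fig)
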