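# nestrhythm

Hierarchical isochrony and rhythmic-category analysis for annotated animal
call sequences, built around the temporal structure of wild orangutan alarm
calls: calls nested in combinations, combinations in bouts, bouts in series,
with a (near-)regular tempo at every level — *self-embedded isochrony*.

The package is aimed at bioacousticians who have manually annotated call
onsets/offsets (e.g. Raven Pro selection tables) and want to test whether a
long vocal sequence is rhythmically organised at several nested time scales,
and whether that organisation carries information about context.

## What it computes

1. **Segmentation.** Calls are grouped by the silent gap (next onset minus
   current offset) between them: gap ≤ 0.2 s → same *combination*;
   0.2 < gap ≤ 2 s → same *bout*; 2 < gap ≤ 20 s → same *series*;
   gap > 20 s starts a new series. Thresholds are configurable.
2. **Interval and ratio statistics.** Per level, the inter-onset interval
   t_k is the time between the onsets of consecutive sibling units, and the
   rhythm statistic is the ratio of adjacent intervals

       r_k = t_k / (t_k + t_{k+1}),        0 < r_k < 1.

   A regular tempo gives r_k = 0.5; interval pairs in 1:2, 1:3 and 2:1
   duration ratio give 0.33, 0.25 and 0.66. Each r_k is classified into an
   *on-integer* bin centred on a small-integer ratio (e.g. 1:1 on =
   [0.444, 0.555]) or its flanking *off-integer* bin.
3. **Count models.** Per level, on/off bin counts per recording are
   modelled with a zero-inflated Poisson mixed model
   (log λ = β_bin + log bin-width + recording intercept, logit zero
   inflation constant), tested full-vs-null by likelihood ratio, with
   Tukey-adjusted pairwise contrasts. An excess of on over off counts per
   unit bin width is the evidence for a rhythmic category.
4. **Tempo model.** A linear mixed model of log t_k on the
   level × context grid with an individual random intercept measures how
   tempo differs between contexts (e.g. natural vs non-natural predator
   models) at each level, plus the small-integer tempo relation between
   levels (0.259 s : 1.11 s : 8.74 s ≈ 2:9:67).
5. **Synthetic ground truth.** A generator of third-order nested
   isochronous point processes (with configurable jitter, context effects
   and isochrony-degradation modes) makes every stage testable without
   field recordings.

## Worked example

Simulate a 14-recording dataset (7 individuals, both predator contexts),
analyse it, and render the report:

```bash
nestrhythm simulate --seed 7 --out sim
nestrhythm analyze --annotations sim/annotations.csv --format csv --out out
nestrhythm report --in out
```

prints (abridged):

```
14 recordings: 42 series, 126 bouts, 378 combinations, 1512 calls
combination  all          n=  756  LRT chi2=   93.514 df=1 p=4.03e-22
    1:1 off vs 1:1 on      est=-5.711 SE=0.706 z=-8.094 p=4.44e-16
series       all          n=   42  LRT chi2=   35.851 df=1 p=2.13e-09
    1:1 off vs 1:1 on      not estimable (a bin has no counts)
tempo level means: bout=1.254s, combination=0.259s, series=8.796s
layer tempo ratio: 2:10:68
tempo bout:non_natural vs bout:natural         est=+0.1597 SE=0.0074 p=0
tempo combination:non_natural vs combination:natural est=+0.0037 SE=0.0034 p=0.882
tempo series:non_natural vs series:natural     est=+0.0022 SE=0.0121 p=1
```

Reading this: at every level the full model beats the random-effects-only
null (isochrony present; the LRT is the primary test), and the negative
"1:1 off vs 1:1 on" contrast says the on-integer rate exceeds the
off-integer rate. With the default low jitter several off bins hold zero
counts, so those contrasts are flagged not estimable while the LRT still
applies. The generator's default non-natural bout-tempo effect (0.167 on
the log scale) is recovered as +0.1597 ± 0.0074 at the bout level and is
absent at the other two levels; it also pulls the pooled bout mean up to
1.254 s, which is why the layer ratio prints 2:10:68 here rather than the
2:9:67 implied by the natural-context tempos.

The same pipeline runs on real annotation tables:

```bash
nestrhythm analyze --annotations selections.txt --format raven \
    --context tiger --recording-id rec01 --individual-id f3 --out out
```

Python API: `read_raven_table` / `read_csv_annotations` → `segment` →
`compute_intervals` / `compute_ratios` → `classify_ratios` /
`tabulate_counts` → `fit_zip_glmm` / `fit_tempo_lmm`, or everything at once
with `run_analysis`. See `docs/methods.md` for the models and their
assumptions.

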