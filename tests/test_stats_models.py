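"""Count-model likelihood, LRT, contrasts and tempo-model behaviour."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nestrhythm import (
    FitError,
    UsageError,
    ValidationError,
    fit_tempo_lmm,
    fit_zip_glmm,
    lrt_full_vs_null,
    pairwise_contrasts,
)
from nestrhythm import SyntheticConfig, compute_intervals, generate_dataset, segment


def simulate_zip(
    rng,
    n_groups=50,
    beta_off=np.log(30.0),
    effect=0.8,
    sigma_u=0.3,
    pi=0.1,
    widths=(0.089, 0.111),
):
    """Draw counts from the zero-inflated Poisson random-intercept model."""
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma_u) if sigma_u > 0 else 0.0
        for lab, beta, w in [("off", beta_off, widths[0]), ("on", beta_off + effect, widths[1])]:
            lam = np.exp(beta + np.log(w) + u)
            y = 0 if rng.random() < pi else int(rng.poisson(lam))
            rows.append(
                {"count": y, "bin_label": lab, "bin_width": w, "recording_id": f"g{g}"}
            )
    return pd.DataFrame(rows)


class TestZipGlmmLimits:
    def test_poisson_closed_form(self):
        """With no random effect and no zero inflation the intercept-only
        MLE is the log of the mean count."""
        df = pd.DataFrame(
            {
                "count": [1, 2, 3],
                "bin_label": "a",
                "bin_width": 1.0,
                "recording_id": ["r1", "r2", "r3"],
            }
        )
        fit = fit_zip_glmm(df, fix_pi=0.0, fix_sigma_u=0.0)
        assert np.exp(fit.beta[0]) == pytest.approx(2.0, abs=1e-6)

    def test_offset_identity(self):
        df = pd.DataFrame(
            {
                "count": [1, 2, 3],
                "bin_label": "a",
                "bin_width": 1.0,
                "recording_id": ["r1", "r2", "r3"],
            }
        )
        f1 = fit_zip_glmm(df, fix_pi=0.0, fix_sigma_u=0.0)
        df2 = df.assign(bin_width=2.0)
        f2 = fit_zip_glmm(df2, fix_pi=0.0, fix_sigma_u=0.0)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(2.0), abs=1e-6)

    def test_pi_zero_matches_poisson_loglik(self):
        """ZIP likelihood with pi = 0 and sigma_u = 0 equals the plain
        Poisson log-likelihood evaluated at the same parameters."""
        rng = np.random.default_rng(21)
        df = simulate_zip(rng, n_groups=20, sigma_u=0.0, pi=0.0)
        fit = fit_zip_glmm(df, fix_pi=0.0, fix_sigma_u=0.0)
        from scipy.stats import poisson

        lmap = dict(zip(fit.labels, fit.beta))
        lam = np.exp(
            np.array([lmap[l] for l in df["bin_label"]]) + np.log(df["bin_width"])
        )
        assert fit.loglik == pytest.approx(
            float(poisson.logpmf(df["count"], lam).sum()), abs=1e-6
        )

    def test_sigma_zero_matches_unpooled_likelihood(self):
        """Marginalising a zero-variance random intercept changes nothing."""
        rng = np.random.default_rng(22)
        df = simulate_zip(rng, n_groups=15, sigma_u=0.0, pi=0.1)
        free = fit_zip_glmm(df, fix_sigma_u=0.0)
        # same model evaluated through the quadrature path with tiny sigma
        near0 = fit_zip_glmm(df, fix_sigma_u=1e-8)
        assert free.loglik == pytest.approx(near0.loglik, abs=1e-6)

    def test_quadrature_stability(self):
        rng = np.random.default_rng(23)
        df = simulate_zip(rng)
        f20 = fit_zip_glmm(df, n_quad=20, compute_se=False)
        f40 = fit_zip_glmm(df, n_quad=40, compute_se=False)
        assert abs(f20.loglik - f40.loglik) < 1e-4

    def test_all_zero_counts_degenerate(self):
        df = pd.DataFrame(
            {"count": [0, 0], "bin_label": ["a", "b"], "bin_width": 1.0,
             "recording_id": "r1"}
        )
        with pytest.raises(FitError):
            fit_zip_glmm(df)

    def test_negative_width_rejected(self):
        df = pd.DataFrame(
            {"count": [1], "bin_label": ["a"], "bin_width": [-1.0],
             "recording_id": "r1"}
        )
        with pytest.raises(ValidationError):
            fit_zip_glmm(df)


class TestZipGlmmRecovery:
    def test_single_replicate_recovery(self):
        rng = np.random.default_rng(24)
        df = simulate_zip(rng)
        fit = fit_zip_glmm(df)
        assert fit.converged
        (contrast,) = pairwise_contrasts(fit, adjust="none")
        # truth: off - on = -0.8
        assert abs(contrast.estimate + 0.8) < 4 * contrast.se
        assert 0.0 < fit.pi < 0.35
        assert 0.05 < fit.sigma_u < 0.7

    def test_statsmodels_zip_cross_check(self):
        """Without the random intercept, the fit must agree with the
        independent statsmodels ZeroInflatedPoisson implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(25)
        df = simulate_zip(rng, n_groups=60, sigma_u=0.0, pi=0.15)
        ours = fit_zip_glmm(df, fix_sigma_u=0.0)
        X = pd.get_dummies(df["bin_label"]).astype(float).to_numpy()
        ref = sm.ZeroInflatedPoisson(
            df["count"].to_numpy(),
            X,
            exog_infl=np.ones((len(df), 1)),
            exposure=df["bin_width"].to_numpy(),
        ).fit(disp=0)
        assert ours.loglik == pytest.approx(float(ref.llf), abs=1e-4)
        # params: [infl intercept (logit pi), beta_off, beta_on]
        assert ours.beta == pytest.approx(np.asarray(ref.params[1:]), abs=1e-3)
        assert ours.gamma0 == pytest.approx(float(ref.params[0]), abs=5e-3)

    def test_glmmtmb_cross_check(self, tmp_path):
        """Full mixed model against R glmmTMB (the reference implementation
        of the zero-inflated Poisson GLMM) on one simulated dataset."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(26)
        df = simulate_zip(rng, n_groups=40)
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "ref.json"
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
suppressMessages(library(glmmTMB))
d <- read.csv("{csv}")
m <- glmmTMB(count ~ 0 + bin_label + (1 | recording_id),
             offset = log(bin_width), ziformula = ~1,
             family = poisson, data = d)
res <- list(beta = unname(fixef(m)$cond), ll = as.numeric(logLik(m)),
            sigma = sqrt(unname(VarCorr(m)$cond$recording_id[1])),
            gamma0 = unname(fixef(m)$zi))
writeLines(jsonlite::toJSON(res, auto_unbox = TRUE), "{out}")
"""
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(out.read_text())
        ours = fit_zip_glmm(df, n_quad=30)
        assert ours.loglik == pytest.approx(ref["ll"], abs=0.05)
        assert ours.beta == pytest.approx(np.array(ref["beta"]), abs=0.02)
        assert ours.sigma_u == pytest.approx(ref["sigma"], abs=0.05)


class TestLrt:
    def test_identical_models(self):
        rng = np.random.default_rng(30)
        df = simulate_zip(rng, n_groups=10)
        full = fit_zip_glmm(df, compute_se=False)
        null = fit_zip_glmm(df, intercept_only=True, compute_se=False)
        lrt = lrt_full_vs_null(full, null)
        assert lrt.chi2 >= 0 and lrt.df == 1
        # degenerate self-comparison is a usage error (no extra parameters)
        with pytest.raises(UsageError):
            lrt_full_vs_null(full, full)

    def test_no_effect_gives_p_near_one_on_flat_data(self):
        df = pd.DataFrame(
            {
                "count": [5, 5] * 10,
                "bin_label": ["a", "b"] * 10,
                "bin_width": 1.0,
                "recording_id": np.repeat([f"r{i}" for i in range(10)], 2),
            }
        )
        full = fit_zip_glmm(df, compute_se=False)
        null = fit_zip_glmm(df, intercept_only=True, compute_se=False)
        lrt = lrt_full_vs_null(full, null)
        assert lrt.chi2 == pytest.approx(0.0, abs=1e-4)
        assert lrt.p > 0.95

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(31)
        a = fit_zip_glmm(simulate_zip(rng, n_groups=8), compute_se=False)
        b = fit_zip_glmm(
            simulate_zip(rng, n_groups=8), intercept_only=True, compute_se=False
        )
        with pytest.raises(UsageError):
            lrt_full_vs_null(a, b)


class TestContrasts:
    def test_two_level_factor_single_contrast(self):
        rng = np.random.default_rng(32)
        fit = fit_zip_glmm(simulate_zip(rng))
        contrasts = pairwise_contrasts(fit)
        assert len(contrasts) == 1
        c = contrasts[0]
        assert (c.level_a, c.level_b) == ("off", "on")
        assert c.estimate == pytest.approx(fit.beta[0] - fit.beta[1])

    def test_sign_convention_on_exceeds_off(self):
        """When the on-bin rate exceeds the off-bin rate the 'off vs on'
        estimate is negative."""
        rng = np.random.default_rng(33)
        fit = fit_zip_glmm(simulate_zip(rng, effect=0.8))
        (c,) = pairwise_contrasts(fit)
        assert c.estimate < 0 and c.p < 0.01

    def test_tukey_two_levels_equals_unadjusted(self):
        rng = np.random.default_rng(34)
        fit = fit_zip_glmm(simulate_zip(rng))
        (tk,) = pairwise_contrasts(fit, adjust="tukey")
        (un,) = pairwise_contrasts(fit, adjust="none")
        assert tk.p == pytest.approx(un.p, rel=1e-3)

    def test_bonferroni_scales_p(self):
        rng = np.random.default_rng(35)
        fit = fit_zip_glmm(simulate_zip(rng, effect=0.1))
        (bf,) = pairwise_contrasts(fit, adjust="bonferroni")
        (un,) = pairwise_contrasts(fit, adjust="none")
        assert bf.p == pytest.approx(min(1.0, un.p), rel=1e-9)


class TestTempoLmm:
    def test_noise_free_cell_means_exact(self):
        cfg = SyntheticConfig(jitter_cv=0.0, bout_tempo_log_effect=0.0)
        ann, _ = generate_dataset(cfg, seed=1)
        iv = compute_intervals(segment(ann))
        fit = fit_tempo_lmm(iv)
        for level, T in [("combination", 0.259), ("bout", 1.11), ("series", 8.74)]:
            for ctx in ("natural", "non_natural"):
                assert fit.cell_mean(level, ctx) == pytest.approx(np.log(T), abs=1e-6)
        for c in fit.context_contrasts():
            assert abs(c.estimate) < 1e-9

    def test_effect_recovery_and_null_levels(self, default_dataset):
        ann, truth = default_dataset
        iv = compute_intervals(segment(ann))
        fit = fit_tempo_lmm(iv)
        contrasts = {c.level_a.split(":")[0]: c for c in fit.context_contrasts()}
        bout = contrasts["bout"]
        assert abs(bout.estimate - truth.bout_tempo_log_effect) < 3 * bout.se
        assert bout.p < 0.05
        assert contrasts["combination"].p > 0.05
        assert contrasts["series"].p > 0.05
        assert fit.lrt.p < 0.001

    def test_pairwise_grid_size(self, default_dataset):
        ann, _ = default_dataset
        iv = compute_intervals(segment(ann))
        fit = fit_tempo_lmm(iv)
        assert len(fit.cells) == 6
        assert len(pairwise_contrasts(fit)) == 15

    def test_permuting_context_destroys_effect(self, default_dataset):
        """Relabelling recordings' contexts at random removes the bout
        contrast: permuted estimates centre on zero with mixed signs and
        the observed estimate exceeds every permuted magnitude."""
        ann, _ = default_dataset
        iv = compute_intervals(segment(ann))
        observed = [
            c
            for c in fit_tempo_lmm(iv).context_contrasts()
            if c.level_a.startswith("bout")
        ][0].estimate
        rng = np.random.default_rng(40)
        rec_ctx = iv.drop_duplicates("recording_id")[["recording_id", "context"]]
        permuted = []
        for _ in range(20):
            perm = rec_ctx.assign(
                context=rng.permutation(rec_ctx["context"].to_numpy())
            )
            shuffled = iv.drop(columns="context").merge(perm, on="recording_id")
            fit = fit_tempo_lmm(shuffled)
            bout = [c for c in fit.context_contrasts() if c.level_a.startswith("bout")]
            permuted.append(bout[0].estimate)
        permuted = np.array(permuted)
        assert abs(permuted.mean()) < observed / 3
        assert (np.abs(permuted) < observed).mean() >= 0.9

    def test_single_individual_falls_back_to_ols(self):
        cfg = SyntheticConfig(n_recordings=2, n_individuals=1)
        ann, _ = generate_dataset(cfg, seed=4)
        iv = compute_intervals(segment(ann))
        with pytest.warns(UserWarning, match="single individual"):
            fit = fit_tempo_lmm(iv)
        assert fit.backend == "ols"

    def test_positive_intervals_required(self):
        iv = pd.DataFrame(
            {
                "t_k": [1.0, -0.5],
                "level": "bout",
                "context": ["natural", "non_natural"],
                "individual_id": "f1",
            }
        )
        with pytest.raises(ValidationError):
            fit_tempo_lmm(iv)
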