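"""Seeded replicate studies quantifying the pipeline's operating
characteristics on synthetic cohorts.

These are the package's evidence that the workflow behaves as claimed:

* ``type2_demonstration`` — the multicollinearity story: with a true hazard
  effect carried by the near-collinear noise-block mean, how often does the
  raw Cox model flag any individual noise variable, and how often does the
  SPCA-Cox model flag the noise component?
* ``null_wald_calibration`` — per-term Wald test size under the null.
* ``null_decile_coverage`` — CI coverage of the decile stage under a null
  composite.
* ``decile_trend_recovery`` — sign of the decile trend under a true
  log-linear composite effect.

Scaled-down replicates use small cohorts; the null and trend studies raise
the baseline event rate so each term rests on enough events for Wald
asymptotics (documented in the methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BaselineHazard,
    CohortSpec,
    ExposureBlockSpec,
    calibrate_baseline_rate,
    generate_cohort,
    paper_like_spec,
)
from .model_selection import DisjointSupportError, default_lambda_grid, select_lambda_disjoint, select_n_components
from .preprocessing import standardize, winsorize
from .sparse_pca import PCA
from .survival import CoxPH
from .pipeline import run_decile_stage


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


NOISE_VARS = ("noise_day_db", "noise_evening_db", "noise_night_db")


def type2_demonstration(
    n_replicates: int = 100,
    n_subjects: int = 20_000,
    noise_effect: float = 0.0169,
    alpha: float = 0.05,
    seed: int = 0,
    variance_threshold: float = 0.90,
) -> dict:
    """Raw-Cox vs SPCA-Cox detection of a component-level noise effect."""
    spec = paper_like_spec(n_subjects=n_subjects, noise_effect=noise_effect)
    grid = default_lambda_grid()
    rows = []
    for ss in _child_seeds(seed, n_replicates):
        table = generate_cohort(spec, seed=_seed_int(ss))
        exposures = spec.exposure_names
        covs = [c.name for c in spec.covariates]
        sm = winsorize(standardize(table[exposures]), 5.0)
        sm_cov = winsorize(standardize(table[covs]), 5.0)
        time = table["time"].to_numpy()
        event = table["event"].to_numpy()
        design = pd.concat([sm.frame, sm_cov.frame], axis=1)
        raw = CoxPH().fit(design, (time, event))
        raw_p = raw.summary_.loc[list(NOISE_VARS), "p"]
        raw_detect = bool((raw_p < alpha).any())

        X = sm.frame.to_numpy()
        pca = PCA(n_components=X.shape[1]).fit(X)
        k = select_n_components(pca.explained_variance_ratio_, variance_threshold)
        spca_detect = False
        spca_p = np.nan
        note = ""
        try:
            sel = select_lambda_disjoint(X, k, grid=grid)
            supports = sel.fit.support()
            noise_idx = {exposures.index(v) for v in NOISE_VARS}
            overlaps = [len(noise_idx & set(s.tolist())) for s in supports]
            j = int(np.argmax(overlaps))
            if overlaps[j] == 0:
                note = "no component loads on the noise block"
            else:
                scores = sel.fit.transform(X)
                names = [f"SPC{i + 1}" for i in range(k)]
                d2 = pd.concat([pd.DataFrame(scores, columns=names), sm_cov.frame], axis=1)
                fit = CoxPH().fit(d2, (time, event))
                spca_p = float(fit.summary_.loc[names[j], "p"])
                spca_detect = spca_p < alpha
        except DisjointSupportError as exc:
            note = f"disjoint selection failed: {exc}"
        rows.append({
            "raw_detect": raw_detect,
            "spca_detect": spca_detect,
            "spca_p": spca_p,
            "min_raw_noise_p": float(raw_p.min()),
            "note": note,
        })
    detail = pd.DataFrame(rows)
    return {
        "raw_detection_rate": float(detail["raw_detect"].mean()),
        "spca_detection_rate": float(detail["spca_detect"].mean()),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
        "detail": detail,
    }


def _null_spec(n_subjects: int, event_fraction: float = 0.15, n_exposures: int = 3) -> CohortSpec:
    """Independent standard-ish exposures, no true effects, elevated event
    rate so small replicates carry adequate events per term."""
    blocks = tuple(
        ExposureBlockSpec(name=f"b{i}", variables=(f"x{i}",), means=(0.0,), sds=(1.0,))
        for i in range(n_exposures)
    )
    spec = CohortSpec(
        n_subjects=n_subjects,
        blocks=blocks,
        covariates=(),
        coefficients=(),
        censor_time=8.21,
        baseline=BaselineHazard("exponential", rate=0.02),
    )
    return calibrate_baseline_rate(spec, event_fraction)


def null_wald_calibration(
    n_replicates: int = 1000,
    n_subjects: int = 2000,
    n_terms: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of per-term Wald tests rejecting at ``alpha`` under the null."""
    spec = _null_spec(n_subjects, n_exposures=n_terms)
    rejections = 0
    total = 0
    for ss in _child_seeds(seed, n_replicates):
        table = generate_cohort(spec, seed=_seed_int(ss))
        sm = winsorize(standardize(table[[f"x{i}" for i in range(n_terms)]]), 5.0)
        fit = CoxPH().fit(sm.frame, (table["time"].to_numpy(), table["event"].to_numpy()))
        rejections += int((fit.p_ < alpha).sum())
        total += n_terms
    return {
        "rejection_rate": rejections / total,
        "n_instances": total,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def _decile_spec(n_subjects: int, composite_effect: float, event_fraction: float = 0.15) -> CohortSpec:
    spec = paper_like_spec(
        n_subjects=n_subjects,
        noise_effect=composite_effect,
        event_fraction=event_fraction,
        censor_time=8.21,
    )
    return spec


def null_decile_coverage(
    n_replicates: int = 200,
    n_subjects: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Coverage of the decile-stage 95% CIs when the composite is null."""
    spec = _decile_spec(n_subjects, composite_effect=0.0)
    covered = 0
    total = 0
    for ss in _child_seeds(seed, n_replicates):
        table = generate_cohort(spec, seed=_seed_int(ss))
        res = run_decile_stage(table)
        ok = (res.table["ci_low"] <= 1.0) & (1.0 <= res.table["ci_high"])
        covered += int(ok.sum())
        total += len(res.table)
    return {
        "coverage": covered / total,
        "n_instances": total,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def decile_trend_recovery(
    n_replicates: int = 100,
    n_subjects: int = 2000,
    composite_effect: float = 0.3,
    seed: int = 0,
) -> dict:
    """Fraction of replicates whose fitted decile log-HRs rise with the
    decile index (positive Spearman rank correlation) under a true
    log-linear composite effect."""
    spec = _decile_spec(n_subjects, composite_effect=composite_effect)
    positive = 0
    rhos = []
    for ss in _child_seeds(seed, n_replicates):
        table = generate_cohort(spec, seed=_seed_int(ss))
        res = run_decile_stage(table)
        rho = stats.spearmanr(np.arange(2, 11), res.table["coef"].to_numpy()).statistic
        rhos.append(float(rho))
        positive += int(rho > 0)
    return {
        "positive_trend_rate": positive / n_replicates,
        "mean_spearman": float(np.mean(rhos)),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def path_calibration_cohort(n_subjects: int = 20_000, seed: int = 0) -> tuple[CohortSpec, pd.DataFrame]:
    """The penalized-path calibration fixture: a cohort whose event count is
    scaled with n so the grid's penalty-to-score-noise ratio matches the
    full-scale design (events ~ rate * n^2 / N_full)."""
    full_n = 379_690
    event_fraction = 0.0395 * n_subjects / full_n
    spec = paper_like_spec(n_subjects=n_subjects, event_fraction=event_fraction, seed=seed)
    return spec, generate_cohort(spec, seed=seed)
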