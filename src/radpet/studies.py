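"""Simulation studies: statistical calibration and signal recovery.

These are the package's own verification experiments, reused by the test
suite and the acceptance script:

* type-I error of the log-rank test under an exponential null;
* Wald confidence-interval coverage of the Cox fit under a Weibull
  proportional-hazards truth;
* Boruta false-positive behaviour on pure-noise features;
* end-to-end recovery: on a strong-effect phantom cohort, does the pipeline
  select the intensity-skewness feature for the response target, with high
  held-out AUC, and does the low-skewness group show a protective hazard
  ratio, reproducing the qualitative direction of the clinical finding?

Problem sizes are chosen for desk-scale runs (minutes, one CPU); every
study takes an explicit seed and is fully deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import AnalysisConfig, _target_labels, extract_cohort_features
from .reliability import reliability_filter
from .response import _univariate_report
from .selection import BorutaSelector, UnitIntervalScaler, correlation_prune, split_cohort
from .survival import cox_fit, dichotomized_pfs_analysis, logrank_test
from .synthetic import SyntheticConfig, generate_cohort


def logrank_type1_study(n_reps: int = 1000, n_per_arm: int = 50,
                        seed: int = 0, level: float = 0.05) -> dict:
    """Rejection rate of the log-rank test when both arms are Exp(1)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        ta = rng.exponential(1.0, n_per_arm)
        tb = rng.exponential(1.0, n_per_arm)
        ea = np.ones(n_per_arm, dtype=bool)
        eb = np.ones(n_per_arm, dtype=bool)
        _, p = logrank_test(ta, ea, tb, eb)
        rejections += p < level
    return {"type1_rate": rejections / n_reps, "n_reps": n_reps,
            "n_per_arm": n_per_arm, "level": level}


def cox_coverage_study(n_reps: int = 500, n: int = 150, true_hr: float = 0.5,
                       shape: float = 1.2, seed: int = 0) -> dict:
    """Wald 95% CI coverage of the Cox fit under a Weibull PH truth.

    Binary covariate (balanced), administrative censoring at the 80th
    percentile of the event-time distribution.
    """
    rng = np.random.default_rng(seed)
    beta = np.log(true_hr)
    covered = 0
    for _ in range(n_reps):
        x = rng.integers(0, 2, n).astype(float)
        u = rng.random(n)
        t = (-np.log(u) / np.exp(beta * x)) ** (1.0 / shape)
        c = np.quantile(t, 0.8)
        times = np.minimum(t, c)
        events = t <= c
        fit = cox_fit(times, events, x)
        covered += fit.ci_low <= true_hr <= fit.ci_high
    return {"coverage": covered / n_reps, "n_reps": n_reps, "n": n,
            "true_hr": true_hr}


def boruta_null_study(n_runs: int = 50, n_samples: int = 200,
                      n_features: int = 10, n_trees: int = 100,
                      max_iter: int = 60, alpha: float = 0.01,
                      seed: int = 0) -> dict:
    """Fraction of pure-noise runs in which Boruta confirms nothing."""
    rng = np.random.default_rng(seed)
    clean = 0
    confirmed_counts = []
    for _ in range(n_runs):
        X = pd.DataFrame(rng.normal(size=(n_samples, n_features)),
                         columns=[f"noise{i}" for i in range(n_features)])
        y = rng.integers(0, 2, n_samples)
        if len(np.unique(y)) < 2:  # pragma: no cover - astronomically rare
            y[0] = 1 - y[0]
        sel = BorutaSelector(n_trees=n_trees, max_iter=max_iter, alpha=alpha,
                             random_state=int(rng.integers(2**31 - 1)))
        sel.fit(X, y)
        n_conf = int(sel.support_.sum())
        confirmed_counts.append(n_conf)
        clean += n_conf == 0
    return {"zero_confirmed_fraction": clean / n_runs, "n_runs": n_runs,
            "confirmed_counts": confirmed_counts}


def boruta_power_study(n_runs: int = 50, n_samples: int = 200,
                       n_noise: int = 10, effect: float = 1.5,
                       n_trees: int = 100, max_iter: int = 60,
                       alpha: float = 0.01, seed: int = 0) -> dict:
    """Fraction of runs confirming a feature with standardized mean
    difference ``effect`` between classes, among ``n_noise`` noise features."""
    rng = np.random.default_rng(seed)
    found = 0
    for _ in range(n_runs):
        y = rng.integers(0, 2, n_samples)
        signal = rng.normal(effect * y, 1.0)
        X = pd.DataFrame(rng.normal(size=(n_samples, n_noise)),
                         columns=[f"noise{i}" for i in range(n_noise)])
        X.insert(0, "signal", signal)
        sel = BorutaSelector(n_trees=n_trees, max_iter=max_iter, alpha=alpha,
                             random_state=int(rng.integers(2**31 - 1)))
        sel.fit(X, y)
        found += bool(sel.decision_["signal"] == "confirmed")
    return {"signal_confirmed_fraction": found / n_runs, "n_runs": n_runs}


def recovery_run(config: SyntheticConfig, analysis: AnalysisConfig) -> dict:
    """One end-to-end recovery run for the response target.

    Runs simulate -> segment -> extract -> CCC filter -> normalize/split ->
    Boruta -> prune, then evaluates the skewness feature's univariate model
    on the held-out test set and the Youden-dichotomized PFS analysis on the
    full cohort (low-skewness group as exposure).
    """
    patients, cohort = generate_cohort(config)
    tables, _, excluded = extract_cohort_features(patients, analysis)
    cohort = cohort[~cohort["patient_id"].isin(excluded)].reset_index(drop=True)
    merged = reliability_filter(tables["R1"], tables["R2"],
                                analysis.ccc_cutoff).merged

    labels = _target_labels(cohort, "response")
    split = split_cohort(cohort, ratio=analysis.ratio, seed=config.seed,
                         stratify_by="responder")
    scaler = UnitIntervalScaler().fit(merged.loc[split.train_ids])
    Xn_train = scaler.transform(merged.loc[split.train_ids])
    Xn_test = scaler.transform(merged.loc[split.test_ids])
    Xn_all = scaler.transform(merged)
    y_train = labels.loc[split.train_ids].to_numpy()
    y_test = labels.loc[split.test_ids].to_numpy()

    selector = BorutaSelector(n_trees=analysis.n_trees,
                              max_iter=analysis.max_iter,
                              alpha=analysis.alpha,
                              random_state=config.seed).fit(Xn_train, y_train)
    res = selector.result()
    signature = (correlation_prune(Xn_train, res.confirmed,
                                   res.median_importance, analysis.r_max)
                 if res.confirmed else [])
    # After pruning, near-duplicates of skewness may stand in for it;
    # selection credit requires the feature itself to be confirmed.
    skew_selected = "PET-Skewness" in res.confirmed

    report = _univariate_report(Xn_train["PET-Skewness"].to_numpy(), y_train,
                                Xn_test["PET-Skewness"].to_numpy(), y_test,
                                "PET-Skewness")
    surv = dichotomized_pfs_analysis(
        cohort, Xn_all["PET-Skewness"], report["youden_threshold"],
        exposure_side="le" if report["high_risk_side"] == "above" else "gt")
    return {
        "seed": config.seed,
        "skew_confirmed": bool(skew_selected),
        "skew_in_signature": "PET-Skewness" in signature,
        "signature": signature,
        "auc_skewness": report["auc"],
        "youden_threshold": report["youden_threshold"],
        "hr_low_skew": surv.cox.hr,
        "hr_ci": [surv.cox.ci_low, surv.cox.ci_high],
        "n_patients": int(len(cohort)),
    }


def recovery_study(n_seeds: int = 25, n_patients: int = 300,
                   seed: int = 0, n_trees: int = 120,
                   max_iter: int = 50,
                   grid_shape: tuple[int, int, int] = (48, 48, 36)) -> dict:
    """Repeated end-to-end recovery runs on strong-effect phantom cohorts.

    The phantom grid is smaller than the generator default (lesion and liver
    geometry are unchanged; only empty background shrinks), keeping a 25-run
    whole-pipeline study at n=300 within desk-scale minutes.
    """
    runs = []
    for k in range(n_seeds):
        config = SyntheticConfig(n_patients=n_patients, grid_shape=grid_shape,
                                 seed=(seed + 10_000 * (k + 1)) % 2**31)
        analysis = AnalysisConfig(n_trees=n_trees, max_iter=max_iter)
        runs.append(recovery_run(config, analysis))
    aucs = np.array([r["auc_skewness"] for r in runs])
    hrs = np.array([r["hr_low_skew"] for r in runs])
    ci_excl_1 = np.array([r["hr_ci"][1] < 1.0 for r in runs])
    return {
        "n_seeds": n_seeds,
        "n_patients": n_patients,
        "selection_fraction": float(np.mean([r["skew_confirmed"] for r in runs])),
        "median_auc_skewness": float(np.median(aucs)),
        "median_hr_low_skew": float(np.median(hrs)),
        "hr_below_1_fraction": float(np.mean(hrs < 1.0)),
        "ci_excludes_1_fraction": float(np.mean(ci_excl_1)),
        "runs": runs,
    }
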