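"""End-to-end clock construction and honest evaluation.

The procedure mirrors standard methylation-clock practice: restrict to
detection-filtered probes, fit an elastic net over a lambda path with
internal 10-fold CV ("lambda.min"), sweep the mixing parameter alpha, and
estimate out-of-sample accuracy by leave-one-out cross-validation in which
the *entire* selection — lambda path plus internal CV — is re-run on every
n-1 subset. Accuracy is summarized as mean/median absolute age error and an
ordinary least-squares regression of predicted on chronological age, overall
and per sex. No nonlinear age transform is applied anywhere: the clock is
linear on the beta scale and fetal (negative) ages are legitimate inputs and
outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AlignedDataset, BetaMatrix, ClockDefinition, align, sex_to_code
from .penalized import (
    ElasticNetConfig,
    ElasticNetFit,
    cv_select_lambda,
    fit_elastic_net,
    fit_lasso_logistic,
    make_lambda_path,
)

__all__ = [
    "GroupStats",
    "EvaluationReport",
    "SweepEntry",
    "SweepRecord",
    "evaluate",
    "alpha_sweep",
    "loocv",
    "select_model",
    "build_sex_model",
    "build_age_clock",
    "prepare_design",
]

DEFAULT_ALPHAS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    n: int
    mae: float
    medae: float
    r2: float
    slope: float
    intercept: float


@dataclass
class EvaluationReport:
    """Accuracy summary overall and per sex, plus per-sample residuals."""

    groups: dict[str, GroupStats]
    predictions: pd.DataFrame  # sample_id, true_age, predicted_age, residual, sex

    @property
    def overall(self) -> GroupStats:
        return self.groups["all"]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: {
                "n": g.n, "mae": g.mae, "medae": g.medae, "r2": g.r2,
                "slope": g.slope, "intercept": g.intercept,
            }
            for name, g in self.groups.items()
        }
        return pd.DataFrame(rows).T.rename_axis("group")


def _group_stats(pred: np.ndarray, true: np.ndarray) -> GroupStats:
    err = np.abs(pred - true)
    vt = true.var()
    if vt == 0:
        raise ValueError("zero variance in true ages")
    # OLS of predicted on true age
    slope = float(np.cov(true, pred, ddof=0)[0, 1] / vt)
    intercept = float(pred.mean() - slope * true.mean())
    vp = pred.var()
    r2 = 0.0 if vp == 0 else float(np.corrcoef(true, pred)[0, 1] ** 2)
    return GroupStats(
        n=len(pred), mae=float(err.mean()), medae=float(np.median(err)),
        r2=r2, slope=slope, intercept=intercept,
    )


def evaluate(pred_ages, true_ages, sex: Sequence[str] | None = None,
             sample_ids: Sequence[str] | None = None) -> EvaluationReport:
    """Accuracy report: mae, medae, and OLS (R^2, slope, intercept) of
    predicted on chronological age, overall and within each sex."""
    pred = np.asarray(pred_ages, dtype=float)
    true = np.asarray(true_ages, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("prediction and truth must be equal-length vectors")
    if len(pred) < 3:
        raise ValueError("need at least 3 samples to evaluate")
    sex_list = list(sex) if sex is not None else ["unknown"] * len(pred)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(pred))]
    groups = {"all": _group_stats(pred, true)}
    for label in ("female", "male"):
        m = np.array([s == label for s in sex_list])
        if m.sum() >= 3 and true[m].var() > 0:
            groups[label] = _group_stats(pred[m], true[m])
    preds = pd.DataFrame(
        {
            "sample_id": ids,
            "true_age": true,
            "predicted_age": pred,
            "residual": pred - true,
            "sex": sex_list,
        }
    )
    return EvaluationReport(groups=groups, predictions=preds)


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------

def prepare_design(data: AlignedDataset, probe_set: Iterable[str] | None = None,
                   max_missing_frac: float = 0.2):
    """Build the model design matrix: restrict to the probe set, drop probes
    with too much missingness, order probes deterministically, and mean-impute
    remaining missing betas. Returns (X, probe_ids)."""
    frame = data.beta.values
    if probe_set is not None:
        keep = sorted(set(probe_set) & set(frame.columns))
    else:
        keep = sorted(frame.columns)
    if not keep:
        raise ValueError("probe set does not intersect the beta matrix")
    sub = frame.loc[:, keep]
    frac_missing = sub.isna().mean(axis=0)
    keep = [p for p in keep if frac_missing[p] <= max_missing_frac]
    sub = sub.loc[:, keep]
    X = sub.to_numpy(float)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    return X, keep


def _clock_from_fit(fit: ElasticNetFit, name: str, provenance: dict) -> ClockDefinition | None:
    nz = fit.nonzero_coefficients()
    if not nz:
        return None
    return ClockDefinition(
        name=name, trait=fit.trait, intercept=fit.intercept,
        coefficients=nz, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# alpha sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepEntry:
    alpha: float
    clock: ClockDefinition | None
    n_cpgs: int
    lambda_min: float
    training_report: EvaluationReport
    loocv_report: EvaluationReport | None = None


@dataclass
class SweepRecord:
    entries: list[SweepEntry]

    def summary(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"alpha": e.alpha, "n_cpgs": e.n_cpgs, "lambda_min": e.lambda_min,
                   "train_r2": e.training_report.overall.r2,
                   "train_medae": e.training_report.overall.medae}
            if e.loocv_report is not None:
                o = e.loocv_report.overall
                rows_extra = {"loocv_r2": o.r2, "loocv_medae": o.medae,
                              "loocv_intercept": o.intercept}
                row.update(rows_extra)
            rows.append(row)
        return pd.DataFrame(rows)


def alpha_sweep(beta: BetaMatrix, metadata: pd.DataFrame,
                probe_set: Iterable[str] | None,
                alphas: Sequence[float] = DEFAULT_ALPHAS,
                cfg: ElasticNetConfig | None = None,
                run_loocv: bool = False) -> SweepRecord:
    """Fit one CV-selected clock per alpha; training predictions come from
    the single lambda.min fit on all samples. With ``run_loocv`` each alpha
    also gets a leave-one-out evaluation (much slower)."""
    alphas = [float(a) for a in alphas]
    if len(set(alphas)) != len(alphas):
        raise ValueError("duplicate alpha values")
    cfg = cfg or ElasticNetConfig()
    data = align(beta, metadata)
    ages = data.ages
    if np.isnan(ages).any():
        raise ValueError("all samples need an age for clock training")
    if len(ages) < cfg.cv_folds:
        raise ValueError("fewer samples than cv_folds")
    X, probes = prepare_design(data, probe_set)
    entries = []
    for a in alphas:
        cfg_a = replace(cfg, alpha=a)
        lambdas = make_lambda_path(X, ages, cfg_a)
        cv = cv_select_lambda(X, ages, cfg_a, lambdas)
        fit = fit_elastic_net(X, ages, cfg_a, cv.lambda_min, feature_names=probes)
        train_report = evaluate(fit.predict_linear(X), ages, data.sex, data.sample_ids)
        clock = _clock_from_fit(
            fit, name=f"clock_alpha{a:g}",
            provenance={"alpha": a, "lambda_min": cv.lambda_min,
                        "n_samples": len(ages), "rng_seed": cfg.rng_seed},
        )
        loocv_report = None
        if run_loocv:
            loocv_report, _ = loocv(beta, metadata, probe_set, a, cfg)
        entries.append(SweepEntry(
            alpha=a, clock=clock, n_cpgs=fit.n_nonzero, lambda_min=cv.lambda_min,
            training_report=train_report, loocv_report=loocv_report,
        ))
    return SweepRecord(entries=entries)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _iteration_seed(base_seed: int, sample_id: str) -> int:
    """Deterministic per-iteration seed independent of sample order."""
    return (base_seed * 100_003 + zlib.crc32(sample_id.encode())) % (2**31 - 1)


def loocv(beta: BetaMatrix, metadata: pd.DataFrame,
          probe_set: Iterable[str] | None, alpha: float,
          cfg: ElasticNetConfig | None = None,
          ) -> tuple[EvaluationReport, pd.DataFrame]:
    """Leave-one-out evaluation of the whole selection procedure.

    For every sample the lambda path and the internal k-fold CV are re-run on
    the remaining n-1 samples and the held-out sample is predicted by that
    model. Fold assignment is seeded per held-out sample (derived from the
    top-level seed and the sample id), so results do not depend on row order.
    """
    cfg = cfg or ElasticNetConfig()
    data = align(beta, metadata)
    order = np.argsort(np.asarray(data.sample_ids))  # canonical order
    ids = [data.sample_ids[i] for i in order]
    ages_all = data.ages[order]
    sex_all = [data.sex[i] for i in order]
    if np.isnan(ages_all).any():
        raise ValueError("all samples need an age for LOOCV")
    n = len(ids)
    if n < cfg.cv_folds + 1:
        raise ValueError("LOOCV needs at least cv_folds + 1 samples")
    frame = data.beta.values.iloc[order]
    if probe_set is not None:
        keep = sorted(set(probe_set) & set(frame.columns))
    else:
        keep = sorted(frame.columns)
    sub = frame.loc[:, keep]
    preds = np.empty(n)
    for i in range(n):
        tr_mask = np.ones(n, dtype=bool)
        tr_mask[i] = False
        tr = sub.iloc[tr_mask]
        frac_missing = tr.isna().mean(axis=0)
        cols = [p for p in keep if frac_missing[p] <= 0.2]
        Xtr = tr.loc[:, cols].to_numpy(float)
        if np.isnan(Xtr).any():
            mu = np.nanmean(Xtr, axis=0)
            rr, cc = np.where(np.isnan(Xtr))
            Xtr[rr, cc] = mu[cc]
        ytr = ages_all[tr_mask]
        cfg_i = replace(cfg, alpha=float(alpha),
                        rng_seed=_iteration_seed(cfg.rng_seed, ids[i]))
        lambdas = make_lambda_path(Xtr, ytr, cfg_i)
        cv = cv_select_lambda(Xtr, ytr, cfg_i, lambdas)
        fit = fit_elastic_net(Xtr, ytr, cfg_i, cv.lambda_min, feature_names=cols)
        xte = sub.iloc[i][cols].to_numpy(float)
        needed = np.flatnonzero(fit.coef)
        if np.isnan(xte[needed]).any():
            missing = [cols[j] for j in needed if np.isnan(xte[j])]
            raise ValueError(
                f"held-out sample {ids[i]} is missing clock probes: {missing[:5]}"
            )
        xte = np.where(np.isnan(xte), np.nanmean(Xtr, axis=0), xte)
        preds[i] = fit.intercept + xte @ fit.coef
    report = evaluate(preds, ages_all, sex_all, ids)
    pred_frame = report.predictions.copy()
    return report, pred_frame


# ---------------------------------------------------------------------------
# model selection across the sweep
# ---------------------------------------------------------------------------

def select_model(sweep: SweepRecord,
                 weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 ) -> tuple[SweepEntry, pd.DataFrame]:
    """Pick the sweep entry with the best rank-normalized composite of three
    criteria: minimize LOOCV medae, maximize LOOCV R^2, and minimize the
    magnitude of the LOOCV regression intercept (which drives systematic
    overestimation of young animals). Equal weights by default; the full
    ranking table is returned for audit. Ties resolve to the smaller alpha.
    """
    entries = [e for e in sweep.entries if e.loocv_report is not None]
    if not entries:
        raise ValueError("select_model needs LOOCV reports in the sweep")
    medae = np.array([e.loocv_report.overall.medae for e in entries])
    r2 = np.array([e.loocv_report.overall.r2 for e in entries])
    icpt = np.array([abs(e.loocv_report.overall.intercept) for e in entries])
    ranks = (
        weights[0] * rankdata(medae)
        + weights[1] * rankdata(-r2)
        + weights[2] * rankdata(icpt)
    )
    table = pd.DataFrame(
        {
            "alpha": [e.alpha for e in entries],
            "loocv_medae": medae,
            "loocv_r2": r2,
            "loocv_abs_intercept": icpt,
            "rank_score": ranks,
        }
    ).sort_values(["rank_score", "alpha"], kind="stable").reset_index(drop=True)
    best_alpha = float(table.iloc[0]["alpha"])
    chosen = next(e for e in entries if e.alpha == best_alpha)
    return chosen, table


# ---------------------------------------------------------------------------
# sex model and convenience builder
# ---------------------------------------------------------------------------

def build_sex_model(beta: BetaMatrix, metadata: pd.DataFrame,
                    probe_set: Iterable[str] | None = None,
                    cfg: ElasticNetConfig | None = None) -> ClockDefinition:
    """LASSO logistic sex classifier (female = 1, male = 0).

    The classification rule downstream is: predicted probability of female
    > 0.5 means female, otherwise male."""
    cfg = cfg or ElasticNetConfig()
    cfg = replace(cfg, alpha=1.0)
    data = align(beta, metadata)
    code = sex_to_code(data.sex)
    known = ~np.isnan(code)
    if known.sum() < len(code):
        kept = [s for s, k in zip(data.sample_ids, known) if k]
        data = align(data.beta.select_samples(kept), data.metadata)
        code = code[known]
    if len(np.unique(code)) < 2:
        raise ValueError("both sexes must be present to build a sex model")
    X, probes = prepare_design(data, probe_set)
    fit, cv = fit_lasso_logistic(X, code, cfg, feature_names=probes)
    clock = _clock_from_fit(
        fit, name="sex_model",
        provenance={"alpha": 1.0, "lambda_min": cv.lambda_min,
                    "n_samples": len(code), "rng_seed": cfg.rng_seed},
    )
    if clock is None:
        raise ValueError("sex model is empty (no informative probes at lambda.min)")
    return clock


def build_age_clock(beta: BetaMatrix, metadata: pd.DataFrame,
                    probe_set: Iterable[str] | None, alpha: float = 0.9,
                    cfg: ElasticNetConfig | None = None,
                    loocv_error: bool = True,
                    ) -> tuple[ClockDefinition, EvaluationReport, EvaluationReport | None]:
    """Fit a single-alpha age clock and (optionally) its LOOCV error.

    Returns (clock, training report, LOOCV report). The LOOCV median
    absolute error is stored on the clock as its reporting error band."""
    cfg = cfg or ElasticNetConfig()
    sweep = alpha_sweep(beta, metadata, probe_set, [alpha], cfg)
    entry = sweep.entries[0]
    if entry.clock is None:
        raise ValueError("fitted clock is empty at lambda.min")
    clock = entry.clock
    loocv_report = None
    if loocv_error:
        loocv_report, _ = loocv(beta, metadata, probe_set, alpha, cfg)
        clock = ClockDefinition(
            name=clock.name, trait=clock.trait, intercept=clock.intercept,
            coefficients=clock.coefficients,
            error_medae=loocv_report.overall.medae,
            error_mae=loocv_report.overall.mae,
            provenance=clock.provenance,
        )
    return clock, entry.training_report, loocv_report
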