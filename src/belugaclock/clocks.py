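"""Apply fitted clocks: epigenetic age estimation and sex classification.

Ships the two published beluga models as package data:

* the beluga age clock — a 24-term linear model (23 CpG coefficients plus
  intercept) mapping skin methylation beta values to age in years, reported
  with a +/- band from the leave-one-out median absolute error (2.87 y; a
  flag switches to the mean absolute error, 3.65 y);
* the beluga sex model — a single-CpG logistic classifier on probe
  cg15451847 (Y-linked), p_female = 1 / (1 + exp(-(0.6717 - 1.1579 * beta))).

Age estimates are never clipped: negative predictions are legitimate for
fetal samples. Missing clock probes are an error by default; cohort-mean
imputation is available behind an explicit flag because silently filling
clock CpGs corrupts age estimates.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BetaMatrix, ClockDefinition, read_clock_definition

__all__ = [
    "load_beluga_age_clock",
    "load_beluga_sex_model",
    "estimate_age",
    "classify_sex",
    "batch_report",
    "ClockApplicationError",
]

SEX_PROBE = "cg15451847"


class ClockApplicationError(ValueError):
    """A sample cannot be scored; carries the offending probes per sample."""

    def __init__(self, message: str, per_sample: dict[str, list[str]] | None = None):
        super().__init__(message)
        self.per_sample = per_sample or {}


def _data_path(name: str) -> Path:
    return resources.files("belugaclock").joinpath("data", name)


def load_beluga_age_clock() -> ClockDefinition:
    """The published beluga epigenetic age clock (24 terms)."""
    return read_clock_definition(_data_path("beluga_age_clock.json"))


def load_beluga_sex_model() -> ClockDefinition:
    """The published single-CpG beluga sex classifier."""
    return read_clock_definition(_data_path("beluga_sex_model.json"))


def _clock_design(clock: ClockDefinition, beta: BetaMatrix,
                  impute: bool) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Extract the clock-probe submatrix; returns (values, missing-per-sample).

    Raises immediately if a clock probe is absent from the matrix entirely.
    Missing (NaN) entries are reported per sample, or cohort-mean imputed
    when ``impute`` is set.
    """
    absent = [p for p in clock.probe_ids if p not in beta.values.columns]
    if absent:
        raise ClockApplicationError(
            f"clock '{clock.name}' probes absent from matrix: {absent}",
        )
    sub = beta.values.loc[:, clock.probe_ids]
    arr = sub.to_numpy(float)
    missing: dict[str, list[str]] = {}
    if np.isnan(arr).any():
        if impute:
            mu = np.nanmean(arr, axis=0)
            if np.isnan(mu).any():
                bad = [p for p, m in zip(clock.probe_ids, np.isnan(mu)) if m]
                raise ClockApplicationError(
                    f"cannot impute probes missing in every sample: {bad}")
            warnings.warn(
                f"imputing missing clock-probe betas with cohort means "
                f"for clock '{clock.name}'", stacklevel=3)
            rr, cc = np.where(np.isnan(arr))
            arr[rr, cc] = mu[cc]
        else:
            for i, sid in enumerate(beta.sample_ids):
                gaps = [p for p, m in zip(clock.probe_ids, np.isnan(arr[i])) if m]
                if gaps:
                    missing[sid] = gaps
    return arr, missing


def estimate_age(clock: ClockDefinition, beta: BetaMatrix,
                 error_band: str = "medae", impute: bool = False) -> pd.DataFrame:
    """Epigenetic age per sample: ``intercept + sum_j coeff_j * beta_j``.

    Returns a DataFrame with sample_id, age_years, range_low/range_high
    (age +/- the clock's stored error, selected by ``error_band`` in
    {"medae", "mae"}) and n_probes_used. Raises on missing clock probes
    unless ``impute`` is set."""
    if clock.trait != "age_linear":
        raise ValueError(f"clock '{clock.name}' is not an age clock")
    if error_band not in ("medae", "mae"):
        raise ValueError("error_band must be 'medae' or 'mae'")
    arr, missing = _clock_design(clock, beta, impute)
    if missing:
        raise ClockApplicationError(
            "samples with missing clock-probe betas: "
            + "; ".join(f"{s}: {ps[:3]}" for s, ps in list(missing.items())[:5]),
            per_sample=missing,
        )
    coef = np.array([clock.coefficients[p] for p in clock.probe_ids])
    ages = clock.intercept + arr @ coef
    err = clock.error_medae if error_band == "medae" else clock.error_mae
    out = pd.DataFrame(
        {
            "sample_id": beta.sample_ids,
            "age_years": ages,
            "range_low": ages - err if err is not None else np.nan,
            "range_high": ages + err if err is not None else np.nan,
            "n_probes_used": clock.n_probes,
        }
    )
    return out


def classify_sex(model: ClockDefinition, beta: BetaMatrix,
                 impute: bool = False) -> pd.DataFrame:
    """Sex call per sample from the logistic model.

    p_female comes from the inverse logit of the linear predictor;
    p_female > 0.5 calls female, anything else (including exactly 0.5)
    calls male."""
    if model.trait != "sex_logistic":
        raise ValueError(f"model '{model.name}' is not a sex model")
    arr, missing = _clock_design(model, beta, impute)
    if missing:
        raise ClockApplicationError(
            "samples with missing sex-probe betas: "
            + "; ".join(f"{s}: {ps}" for s, ps in list(missing.items())[:5]),
            per_sample=missing,
        )
    coef = np.array([model.coefficients[p] for p in model.probe_ids])
    eta = model.intercept + arr @ coef
    p_female = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "sample_id": beta.sample_ids,
            "p_female": p_female,
            "call": np.where(p_female > 0.5, "female", "male"),
        }
    )


def batch_report(clock: ClockDefinition, sex_model: ClockDefinition,
                 beta: BetaMatrix, error_band: str = "medae",
                 impute: bool = False) -> pd.DataFrame:
    """Combined per-sample report: age, error range, sex call and QC flags.

    Per-sample scoring failures (missing probes) become flagged rows rather
    than aborting the whole batch. Absent probe *columns* still abort,
    because then no sample can be scored."""
    rows = []
    age_arr, age_missing = _clock_design(clock, beta, impute)
    sex_arr, sex_missing = _clock_design(sex_model, beta, impute)
    age_coef = np.array([clock.coefficients[p] for p in clock.probe_ids])
    sex_coef = np.array([sex_model.coefficients[p] for p in sex_model.probe_ids])
    err = clock.error_medae if error_band == "medae" else clock.error_mae
    for i, sid in enumerate(beta.sample_ids):
        flags = []
        age = rng_lo = rng_hi = np.nan
        p_female = np.nan
        call = ""
        if sid in age_missing:
            flags.append(f"missing_clock_probes:{','.join(age_missing[sid][:3])}")
        else:
            age = float(clock.intercept + age_arr[i] @ age_coef)
            if err is not None:
                rng_lo, rng_hi = age - err, age + err
        if sid in sex_missing:
            flags.append(f"missing_sex_probe:{','.join(sex_missing[sid])}")
        else:
            eta = float(sex_model.intercept + sex_arr[i] @ sex_coef)
            p_female = 1.0 / (1.0 + np.exp(-eta))
            call = "female" if p_female > 0.5 else "male"
        rows.append(
            {
                "sample_id": sid,
                "age_years": age,
                "range_low": rng_lo,
                "range_high": rng_hi,
                "sex_call": call,
                "p_female": p_female,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
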