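"""Seeded synthetic methylation cohorts with known ground truth.

The generator emulates the statistical shape of a small wildlife calibration
cohort measured on a methylation array: ~67 samples, a few thousand CpG
probes, a right-skewed age distribution spanning fetal (negative) to old
ages, a small minority of CpGs whose beta values drift linearly with age
(mostly losing methylation, i.e. negative slopes), a handful of near-binary
sex-linked probes, and a low per-entry detection-failure rate. The age
signal is linear on the beta scale because the clock model class is linear
on the beta scale — recovery tests then measure the pipeline, not a model
mismatch. It does not emulate array chemistry, batch effects, probe
cross-reactivity or tissue heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, DetectionPMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "truth_recovery_score",
    "RecoveryScore",
]


@dataclass
class SimulationConfig:
    """Cohort generator settings (defaults mirror the calibration study)."""

    n_samples: int = 67
    n_probes: int = 3000
    n_age_informative: int = 40
    frac_negative_slope: float = 0.9
    slope_min: float = 0.002  # beta-units per year, magnitude
    slope_max: float = 0.01
    noise_sd: float = 0.03  # beta-units
    n_sex_linked: int = 10
    age_min: float = -1.0
    age_max: float = 49.0
    male_fraction: float = 36 / 67
    detection_failure_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_informative + self.n_sex_linked > self.n_probes:
            raise ValueError("informative + sex-linked probes exceed n_probes")
        for name in ("n_samples", "n_probes", "n_age_informative", "n_sex_linked"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.frac_negative_slope <= 1):
            raise ValueError("frac_negative_slope must be in [0, 1]")
        if self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring."""

    informative_probes: dict[str, float]  # probe -> slope (beta-units / year)
    informative_baselines: dict[str, float]
    sex_linked_probes: list[str]
    ages: pd.Series = field(repr=False)
    sex: pd.Series = field(repr=False)


def _draw_ages(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Right-skewed ages over [age_min, age_max]; at the default range the
    median lands near 21 years (Beta(2, 2.5) scaled)."""
    span = cfg.age_max - cfg.age_min
    return cfg.age_min + span * rng.beta(2.0, 2.5, size=cfg.n_samples)


def generate_cohort(cfg: SimulationConfig | None = None,
                    ) -> tuple[BetaMatrix, DetectionPMatrix, pd.DataFrame, GroundTruth]:
    """Generate (beta matrix, detection p-values, metadata, ground truth).

    Deterministic given ``cfg.rng_seed``. Betas are clipped to [0, 1]; a
    warning is raised if more than 1% of entries clip (a sign the config is
    unrealistic for beta-scale data).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n, p = cfg.n_samples, cfg.n_probes

    sample_ids = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"cgS{j:06d}" for j in range(p)]

    ages = _draw_ages(rng, cfg)
    n_male = int(round(n * cfg.male_fraction))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex)
    is_female = (sex == "female").astype(float)

    # probe roles
    perm = rng.permutation(p)
    idx_info = perm[: cfg.n_age_informative]
    idx_sex = perm[cfg.n_age_informative: cfg.n_age_informative + cfg.n_sex_linked]

    signal = np.empty((n, p))
    # background: Beta-distributed per-probe baselines, no trait dependence
    baselines = 0.05 + 0.90 * rng.beta(2.0, 2.0, size=p)
    signal[:] = baselines[None, :]

    # age-informative probes: beta = baseline + slope * age
    k = cfg.n_age_informative
    n_neg = int(round(cfg.frac_negative_slope * k))
    signs = np.array([-1.0] * n_neg + [1.0] * (k - n_neg))
    rng.shuffle(signs)
    mags = rng.uniform(cfg.slope_min, cfg.slope_max, size=k)
    slopes = signs * mags
    reach = mags * max(abs(cfg.age_max), abs(cfg.age_min))
    info_base = np.where(
        signs < 0,
        rng.uniform(reach + 0.05, 0.95),        # decreasing: start high
        rng.uniform(0.05, 0.95 - reach),        # increasing: start low
    )
    signal[:, idx_info] = info_base[None, :] + np.outer(ages, slopes)

    # sex-linked probes: two well-separated levels, direction random
    m = cfg.n_sex_linked
    if m:
        low = rng.uniform(0.30, 0.50, size=m)
        gap = rng.uniform(0.35, 0.45, size=m)
        female_high = rng.random(m) < 0.5
        lvl_f = np.where(female_high, low + gap, low)
        lvl_m = np.where(female_high, low, low + gap)
        signal[:, idx_sex] = (np.outer(is_female, lvl_f)
                              + np.outer(1.0 - is_female, lvl_m))

    noise = rng.normal(0.0, cfg.noise_sd, size=(n, p)) if cfg.noise_sd > 0 else 0.0
    raw = signal + noise
    clipped = np.clip(raw, 0.0, 1.0)
    clip_frac = float(np.mean(raw != clipped))
    if clip_frac >= 0.01:
        warnings.warn(
            f"{clip_frac:.1%} of simulated betas were clipped to [0, 1]; "
            "the configuration may be unrealistic for beta-scale data")

    # detection p-values: confident near-zero for passing entries,
    # Uniform(0.05, 1) for failures (independent across entries)
    fails = rng.random((n, p)) < cfg.detection_failure_rate
    pvals = rng.uniform(0.0, 1e-3, size=(n, p))
    pvals[fails] = rng.uniform(0.05, 1.0, size=int(fails.sum()))

    beta = BetaMatrix(pd.DataFrame(clipped, index=sample_ids, columns=probe_ids))
    det = DetectionPMatrix(pd.DataFrame(pvals, index=sample_ids, columns=probe_ids))
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_years": ages,
            "sex": sex,
            "source_class": "synthetic_calibration",
        }
    )
    truth = GroundTruth(
        informative_probes={probe_ids[j]: float(s) for j, s in zip(idx_info, slopes)},
        informative_baselines={probe_ids[j]: float(b) for j, b in zip(idx_info, info_base)},
        sex_linked_probes=[probe_ids[j] for j in idx_sex],
        ages=pd.Series(ages, index=sample_ids, name="age_years"),
        sex=pd.Series(sex, index=sample_ids, name="sex"),
    )
    return beta, det, meta, truth


@dataclass
class RecoveryScore:
    precision: float | None  # None when nothing was selected (undefined)
    recall: float
    n_selected: int
    n_true: int


def truth_recovery_score(selected, truth: GroundTruth) -> RecoveryScore:
    """Precision/recall of a selected probe set against the planted
    age-informative probes."""
    sel = set(selected)
    true = set(truth.informative_probes)
    hits = len(sel & true)
    return RecoveryScore(
        precision=(hits / len(sel)) if sel else None,
        recall=(hits / len(true)) if true else 0.0,
        n_selected=len(sel),
        n_true=len(true),
    )
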