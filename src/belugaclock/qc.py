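"""Probe and sample quality control plus per-CpG trait screening.

Three concerns live here:

* detection-p filtering — a probe is kept for clock building only if its
  detection p-value is confidently small in enough individuals (default:
  p < 0.05 in at least 10 samples);
* interarray-correlation outlier flagging — technical outlier arrays are
  detected from the matrix of pairwise sample-sample Pearson correlations,
  summarized by average-linkage clustering and a z-score rule on each
  sample's mean correlation to the rest of the cohort;
* per-CpG Pearson screening — the correlation of every probe's beta values
  with a trait (chronological age, or sex coded female=1/male=0), with a
  decile summary of |r| that records the sign skew (age-informative CpGs
  are predominantly demethylating, i.e. negative slopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import BetaMatrix, DetectionPMatrix

__all__ = [
    "filter_by_detection",
    "interarray_outliers",
    "correlate_trait",
    "bin_correlations",
    "rank_by_abs_corr",
    "drop_high_missing_probes",
    "OutlierReport",
]

#: Final detection-p filtering rule used for clock building.
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_MIN_SAMPLES = 10


def filter_by_detection(
    pvals: DetectionPMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> set[str]:
    """Probes whose detection p-value is < ``p_threshold`` in at least
    ``min_samples`` samples. Missing p-values count as failures."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if pvals.shape[0] == 0 or pvals.shape[1] == 0:
        raise ValueError("empty detection p-value matrix")
    arr = pvals.values.to_numpy()
    passing = np.nansum((arr < p_threshold) & np.isfinite(arr), axis=0)
    keep = passing >= min_samples
    return {p for p, k in zip(pvals.probe_ids, keep) if k}


@dataclass
class OutlierReport:
    flagged: list[str]
    mean_correlation: pd.Series
    linkage_matrix: np.ndarray
    sample_order: list[str]


def interarray_outliers(beta: BetaMatrix, z_cut: float = 2.0) -> OutlierReport:
    """Flag technical-outlier samples from interarray correlations.

    All pairwise sample-sample Pearson correlations are computed on shared
    (pairwise-complete) probes. An average-linkage dendrogram on distance
    1 - r is returned for inspection, and samples whose mean correlation to
    all other samples falls more than ``z_cut`` standard deviations below
    the cohort mean are flagged.
    """
    n = beta.shape[0]
    if n < 3:
        raise ValueError("interarray outlier detection needs >= 3 samples")
    corr = beta.values.T.corr(min_periods=3)  # sample x sample Pearson
    c = corr.to_numpy(float).copy()
    np.fill_diagonal(c, 1.0)
    mean_r = (c.sum(axis=1) - 1.0) / (n - 1)
    mu, sd = mean_r.mean(), mean_r.std(ddof=0)
    if sd == 0.0 or not np.isfinite(z_cut):
        flagged_mask = np.zeros(n, dtype=bool)
    else:
        flagged_mask = mean_r < mu - z_cut * sd
    dist = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    lk = linkage(squareform(dist, checks=False), method="average")
    ids = beta.sample_ids
    return OutlierReport(
        flagged=[s for s, f in zip(ids, flagged_mask) if f],
        mean_correlation=pd.Series(mean_r, index=ids, name="mean_interarray_r"),
        linkage_matrix=lk,
        sample_order=ids,
    )


def correlate_trait(beta: BetaMatrix, trait: np.ndarray, name: str = "trait") -> pd.DataFrame:
    """Pearson correlation of every probe with a per-sample trait vector.

    Observations are pairwise-complete per probe. Probes with fewer than 3
    complete observations or zero variance get ``r = NaN`` (reported as
    undefined, excluded from ranking). Returns a DataFrame indexed by probe
    with columns ``r`` and ``n_used``; the trait name is stored in
    ``df.attrs["trait"]``.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != beta.shape[0]:
        raise ValueError("trait length must equal the number of samples")
    B = beta.values.to_numpy(float)
    mask = np.isfinite(B) & np.isfinite(trait)[:, None]
    if np.any(mask.sum(axis=0) == 0):
        bad = [p for p, m in zip(beta.probe_ids, mask.sum(axis=0)) if m == 0]
        raise ValueError(f"all-missing probe/trait pairs: {bad[:5]}")
    Bz = np.where(mask, B, 0.0)
    t = np.where(np.isfinite(trait), trait, 0.0)
    n = mask.sum(axis=0).astype(float)
    sx = Bz.sum(axis=0)
    sy = mask.T @ t
    sxx = (Bz * Bz).sum(axis=0)
    syy = mask.T @ (t * t)
    sxy = Bz.T @ t
    cov = n * sxy - sx * sy
    varx = n * sxx - sx * sx
    vary = n * syy - sy * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(varx * vary)
    # zero-variance probes (or trait slices), or too few observations
    undef = (varx <= 0) | (vary <= 0) | (n < 3)
    r = np.where(undef, np.nan, np.clip(r, -1.0, 1.0))
    out = pd.DataFrame(
        {"r": r, "n_used": mask.sum(axis=0)}, index=pd.Index(beta.probe_ids, name="probe_id")
    )
    out.attrs["trait"] = name
    return out


BIN_EDGES = np.round(np.arange(0.0, 1.1, 0.1), 10)


def bin_correlations(tbl: pd.DataFrame) -> pd.DataFrame:
    """Decile summary of |r|: counts and percent-negative per bin.

    Bins are lower-inclusive, upper-exclusive ([0.0, 0.1) ... [0.9, 1.0]);
    |r| = 1.0 closes the top bin. Undefined correlations are excluded.
    Total count and overall percent-negative are stored in ``attrs``.
    """
    r = tbl["r"].to_numpy(float)
    r = r[np.isfinite(r)]
    idx = np.minimum(np.floor(np.abs(r) * 10).astype(int), 9)
    counts = np.bincount(idx, minlength=10)
    neg = np.bincount(idx, weights=(r < 0).astype(float), minlength=10)
    with np.errstate(invalid="ignore"):
        pct_neg = np.where(counts > 0, 100.0 * neg / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame(
        {
            "bin_low": BIN_EDGES[:-1],
            "bin_high": BIN_EDGES[1:],
            "n_cpgs": counts,
            "pct_negative": pct_neg,
        }
    )
    out.attrs["total"] = int(counts.sum())
    out.attrs["pct_negative_total"] = (
        100.0 * float((r < 0).sum()) / len(r) if len(r) else np.nan
    )
    return out


def rank_by_abs_corr(tbl: pd.DataFrame, top_k: int | None = None) -> list[str]:
    """Probe ids ordered by descending |r|; ties broken lexicographically by
    probe id. Undefined correlations are excluded from the ranking."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    defined = tbl[np.isfinite(tbl["r"])]
    order = sorted(defined.index, key=lambda p: (-abs(defined.at[p, "r"]), p))
    return order if top_k is None else order[:top_k]


def drop_high_missing_probes(beta: BetaMatrix, max_missing_frac: float = 0.2) -> set[str]:
    """Probes usable for model fitting: missingness at or below the cutoff.

    The coordinate-descent solver needs complete columns (remaining missing
    entries are mean-imputed by the pipeline), so heavily missing probes are
    excluded up front.
    """
    arr = beta.values.to_numpy()
    frac = np.mean(~np.isfinite(arr), axis=0)
    return {p for p, f in zip(beta.probe_ids, frac) if f <= max_missing_frac}
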