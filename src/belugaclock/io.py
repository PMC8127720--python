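"""Data model and readers/writers for methylation matrices, metadata and clocks.

The universal input is a sample x probe matrix of methylation beta values
(fractions in [0, 1]); a companion matrix of detection p-values shares its
axes. Sample metadata carries chronological age in years (negative for fetal
samples) and sex. A fitted clock is a portable linear model: an intercept
plus a probe -> coefficient mapping, serialized as JSON.

Probe identifiers (array probe names such as ``cg21419180``) are treated as
opaque strings; no genome coordinates are stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "DetectionPMatrix",
    "ClockDefinition",
    "AlignedDataset",
    "read_beta_matrix",
    "read_detection_pvalues",
    "read_metadata",
    "read_clock_definition",
    "write_clock_definition",
    "align",
    "sex_to_code",
]

#: Tokens (case-insensitive) treated as missing in delimited matrices.
MISSING_TOKENS = ("NA", "na", "Na", "nA", "NaN", "nan", "")

VALID_SEX = ("female", "male", "unknown")
VALID_TRAITS = ("age_linear", "sex_logistic")


class MatrixValidationError(ValueError):
    """Raised when a sample x probe matrix violates its invariants."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise MatrixValidationError(f"duplicate {what} ids: {sorted(set(dups))[:5]}")
    return ids


class _SampleProbeMatrix:
    """Sample x probe real matrix with entries in [0, 1] or missing (NaN).

    Backed by a pandas DataFrame indexed by sample id with probe-id columns.
    """

    _entry_name = "value"

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        _check_unique(values.index, "sample")
        _check_unique(values.columns, "probe")
        arr = values.to_numpy()
        finite = np.isfinite(arr)
        if np.any((arr[finite] < 0.0) | (arr[finite] > 1.0)):
            bad = arr[finite & ((arr < 0.0) | (arr > 1.0))][:3]
            raise MatrixValidationError(
                f"{self._entry_name} entries outside [0, 1]: e.g. {bad.tolist()}"
            )
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        values.index.name = "sample_id"
        self.values = values

    # -- axes -------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return f"{type(self).__name__}({n} samples x {p} probes)"

    # -- subsetting -------------------------------------------------------
    def select_probes(self, probes: Iterable[str]) -> "_SampleProbeMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.values.columns]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        return type(self)(self.values.loc[:, probes])

    def select_samples(self, samples: Iterable[str]) -> "_SampleProbeMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return type(self)(self.values.loc[samples, :])

    # -- io ---------------------------------------------------------------
    @classmethod
    def read(
        cls,
        path: str | Path,
        orientation: str = "samples_as_rows",
        sep: str | None = None,
    ) -> "_SampleProbeMatrix":
        """Read a delimited matrix. The caller declares the orientation;
        no auto-transposition is attempted (silent transposes are a classic
        failure mode).
        """
        if orientation not in ("samples_as_rows", "probes_as_rows"):
            raise ValueError(f"unknown orientation: {orientation!r}")
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        _check_unique(header, "header")
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
        non_numeric = df.columns[
            [not np.issubdtype(d, np.number) for d in df.dtypes]
        ]
        if len(non_numeric):
            raise MatrixValidationError(
                f"non-numeric cells in columns: {list(non_numeric)[:5]}"
            )
        if orientation == "probes_as_rows":
            df = df.T
        return cls(df)

    def write(self, path: str | Path, orientation: str = "samples_as_rows") -> None:
        df = self.values if orientation == "samples_as_rows" else self.values.T
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


class BetaMatrix(_SampleProbeMatrix):
    """Sample x probe methylation fractions, each entry in [0, 1] or missing."""

    _entry_name = "beta"


class DetectionPMatrix(_SampleProbeMatrix):
    """Per-sample, per-probe detection p-values (confidence in the beta).

    Axes must match the companion :class:`BetaMatrix` when paired.
    """

    _entry_name = "detection p"

    def check_paired(self, beta: BetaMatrix) -> None:
        if self.sample_ids != beta.sample_ids or self.probe_ids != beta.probe_ids:
            raise MatrixValidationError(
                "detection p-value matrix axes do not match the beta matrix"
            )


def read_beta_matrix(
    path: str | Path, orientation: str = "samples_as_rows", sep: str | None = None
) -> BetaMatrix:
    return BetaMatrix.read(path, orientation=orientation, sep=sep)


def read_detection_pvalues(
    path: str | Path, orientation: str = "samples_as_rows", sep: str | None = None
) -> DetectionPMatrix:
    return DetectionPMatrix.read(path, orientation=orientation, sep=sep)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def _normalize_sex(value) -> str:
    if pd.isna(value):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("f", "female", "1", "1.0"):
        return "female"
    if s in ("m", "male", "0", "0.0"):
        return "male"
    if s in ("unknown", "u", "", "na"):
        return "unknown"
    raise ValueError(f"unrecognized sex label: {value!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV with columns sample_id, age_years, sex
    and optionally source_class.

    Ages are years; fetal samples may be negative. Sex labels are normalized
    to female/male/unknown.
    """
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(df["sample_id"], "metadata sample")
    if "age_years" in df.columns:
        df["age_years"] = pd.to_numeric(df["age_years"], errors="raise")
        ages = df["age_years"].to_numpy(float)
        if np.any(~np.isfinite(ages) & ~np.isnan(ages)):
            raise ValueError("age_years must be finite when present")
    if "sex" in df.columns:
        df["sex"] = [_normalize_sex(v) for v in df["sex"]]
    else:
        df["sex"] = "unknown"
    if "source_class" not in df.columns:
        df["source_class"] = ""
    return df


def sex_to_code(sex: Iterable[str]) -> np.ndarray:
    """Numeric sex coding used throughout: female = 1, male = 0, unknown = NaN."""
    mapping = {"female": 1.0, "male": 0.0, "unknown": np.nan}
    return np.array([mapping[_normalize_sex(s)] for s in sex], dtype=float)


# ---------------------------------------------------------------------------
# clock definitions
# ---------------------------------------------------------------------------

@dataclass
class ClockDefinition:
    """A fitted linear methylation clock: the portable artifact of training.

    For ``trait == "age_linear"`` the prediction is
    ``age = intercept + sum_j coefficients[j] * beta[j]`` in years.
    For ``trait == "sex_logistic"`` the same linear predictor is interpreted
    through the inverse logit as the probability of being female.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    trait: str = "age_linear"
    error_medae: float | None = None
    error_mae: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("clock must have at least one probe coefficient")
        if self.trait not in VALID_TRAITS:
            raise ValueError(f"trait must be one of {VALID_TRAITS}")
        _check_unique(self.coefficients, "clock probe")
        self.intercept = float(self.intercept)
        self.coefficients = {str(k): float(v) for k, v in self.coefficients.items()}
        for label in ("error_medae", "error_mae"):
            val = getattr(self, label)
            if val is not None:
                val = float(val)
                if not (val >= 0.0):
                    raise ValueError(f"{label} must be >= 0")
                setattr(self, label, val)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    @property
    def n_probes(self) -> int:
        return len(self.coefficients)

    def linear_predictor(self, beta_by_probe: Mapping[str, float]) -> float:
        eta = self.intercept
        for probe, coeff in self.coefficients.items():
            eta += coeff * float(beta_by_probe[probe])
        return eta

    def to_dict(self) -> dict:
        out = {
            "name": self.name,
            "trait": self.trait,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "provenance": dict(self.provenance),
        }
        if self.error_medae is not None:
            out["error_medae"] = self.error_medae
        if self.error_mae is not None:
            out["error_mae"] = self.error_mae
        return out


def read_clock_definition(path: str | Path) -> ClockDefinition:
    def _no_dup_pairs(pairs):
        keys = [k for k, _ in pairs]
        if len(keys) != len(set(keys)):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate keys in clock file: {dups}")
        return dict(pairs)

    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh, object_pairs_hook=_no_dup_pairs)
    for key in ("intercept", "coefficients"):
        if key not in raw:
            raise ValueError(f"clock file {path} missing field {key!r}")
    coeffs = raw["coefficients"]
    if not isinstance(coeffs, dict):
        raise ValueError("coefficients must be a probe -> number mapping")
    for probe, val in coeffs.items():
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ValueError(f"non-numeric coefficient for probe {probe}: {val!r}")
    return ClockDefinition(
        name=raw.get("name", Path(path).stem),
        trait=raw.get("trait", "age_linear"),
        intercept=float(raw["intercept"]),
        coefficients=coeffs,
        error_medae=raw.get("error_medae"),
        error_mae=raw.get("error_mae"),
        provenance=raw.get("provenance", {}),
    )


def write_clock_definition(clock: ClockDefinition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(clock.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedDataset:
    """A beta matrix paired with metadata in identical sample order."""

    beta: BetaMatrix
    metadata: pd.DataFrame
    dropped_sample_ids: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.beta.sample_ids

    @property
    def ages(self) -> np.ndarray:
        return self.metadata["age_years"].to_numpy(float)

    @property
    def sex(self) -> list[str]:
        return list(self.metadata["sex"])


def align(beta: BetaMatrix, metadata: pd.DataFrame, strict: bool = True) -> AlignedDataset:
    """Pair a beta matrix with metadata, ordering samples by the beta matrix.

    With ``strict=True`` every beta sample must have metadata; otherwise the
    intersection is used and dropped ids are reported on the result.
    """
    metadata = validate_metadata(metadata)
    meta_ids = set(metadata["sample_id"])
    beta_ids = beta.sample_ids
    missing = [s for s in beta_ids if s not in meta_ids]
    if missing and strict:
        raise ValueError(f"samples lacking metadata: {missing[:5]}")
    kept = [s for s in beta_ids if s in meta_ids]
    if not kept:
        raise ValueError("no samples shared between beta matrix and metadata")
    sub = beta.select_samples(kept) if missing else beta
    meta = (
        metadata.set_index("sample_id")
        .loc[kept]
        .reset_index()
    )
    return AlignedDataset(beta=sub, metadata=meta, dropped_sample_ids=missing)
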