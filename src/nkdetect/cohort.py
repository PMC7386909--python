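"""Cohort container, CSV/XLSX I/O, structural validation and descriptive stats.

A cohort is a feature-by-patient table of flow-cytometry percentages plus a
serum PSA value (ng/ml) and a binary outcome label.  Two tasks are supported:
``detection`` (benign=0 vs cancer=1, PSA restricted below 20 ng/ml) and
``risk`` (D'Amico low/intermediate=0 vs high=1, unrestricted PSA).

The canonical on-disk layout is a UTF-8 CSV with header
``patient_id,label,psa,f01..f32``; a ``layout`` mapping lets spreadsheets with
human-readable headers be ingested without renaming columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import COMPLEMENT_PAIRS, FEATURES, PSA_ID, feature_name

__all__ = [
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "ValidationReport",
    "DescriptiveStats",
    "load_cohort",
    "write_cohort",
    "validate_structure",
    "descriptive_stats",
]


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class CohortValidationError(ValueError):
    """A cell value violates the cohort contract (located by row/column)."""


def canonical_columns(n_features: int = 32) -> list[str]:
    return ["patient_id", "label", "psa"] + [f"f{i:02d}" for i in range(1, n_features + 1)]


@dataclass
class Cohort:
    """In-memory cohort.

    values : (n_patients, m_features) float array of percentages in [0, 100]
    psa    : length-n vector, ng/ml
    labels : length-n 0/1 int vector (positive class = cancer or high risk)
    """

    values: np.ndarray
    psa: np.ndarray
    labels: np.ndarray
    patient_ids: list[str]
    task: str = "detection"
    feature_ids: list[int] = field(default_factory=lambda: list(range(1, 33)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.psa = np.asarray(self.psa, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.values.shape[0]
        if not (len(self.psa) == len(self.labels) == len(self.patient_ids) == n):
            raise ValueError("values, psa, labels and patient_ids disagree on n")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("values width disagrees with feature_ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def _col(self, fid: int) -> int:
        return self.feature_ids.index(fid)

    def predictor_matrix(self, feature_set: list[int]) -> np.ndarray:
        """Assemble an (n, len(feature_set)) predictor matrix.

        ``feature_set`` holds feature ids; the pseudo-id ``PSA_ID`` (0) selects
        the PSA column, min-max rescaled to [0, 100] so that its Euclidean
        contribution is commensurate with the percentage features.
        """
        cols = []
        for fid in feature_set:
            if fid == PSA_ID:
                lo, hi = float(self.psa.min()), float(self.psa.max())
                span = hi - lo if hi > lo else 1.0
                cols.append((self.psa - lo) / span * 100.0)
            else:
                cols.append(self.values[:, self._col(fid)])
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "label": self.labels,
                "psa": self.psa,
            }
        )
        for j, fid in enumerate(self.feature_ids):
            df[f"f{fid:02d}"] = self.values[:, j]
        return df


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def load_cohort(
    path: str | Path,
    layout: dict[str, str] | None = None,
    task: str = "detection",
) -> Cohort:
    """Load a cohort from CSV (or xlsx), enforcing the 32-feature registry.

    ``layout`` maps canonical column names (``patient_id``, ``label``, ``psa``,
    ``f01``..``f32``) to the actual headers in the file.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    layout = layout or {}

    def actual(canon: str) -> str:
        return layout.get(canon, canon)

    missing = [c for c in canonical_columns() if actual(c) not in df.columns]
    if missing:
        names = []
        for c in missing:
            if c.startswith("f"):
                names.append(f"{c} ({feature_name(int(c[1:]))})")
            else:
                names.append(c)
        raise SchemaError(f"missing column(s): {', '.join(names)}")

    sub = df[[actual(c) for c in canonical_columns()]].copy()
    sub.columns = canonical_columns()

    for col in ["psa"] + [f"f{i:02d}" for i in range(1, 33)]:
        parsed = pd.to_numeric(sub[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"unparseable value in column {col!r}, row {row}"
            )
        sub[col] = parsed

    values = sub[[f"f{i:02d}" for i in range(1, 33)]].to_numpy(dtype=float)
    psa = sub["psa"].to_numpy(dtype=float)
    labels = sub["label"].to_numpy()

    out = (values < 0) | (values > 100)
    if out.any():
        r, c = map(int, np.argwhere(out)[0])
        raise CohortValidationError(
            f"feature value out of [0, 100] at row {r}, column f{c + 1:02d} "
            f"({feature_name(c + 1)}): {values[r, c]}"
        )
    if (psa < 0).any():
        r = int(np.flatnonzero(psa < 0)[0])
        raise CohortValidationError(f"negative PSA at row {r}: {psa[r]}")
    if task == "detection" and (psa >= 20).any():
        r = int(np.flatnonzero(psa >= 20)[0])
        raise CohortValidationError(
            f"PSA >= 20 ng/ml at row {r} ({psa[r]}); the detection task is "
            "restricted to PSA < 20"
        )
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise CohortValidationError(f"labels must be binary 0/1, found {sorted(uniq)}")

    return Cohort(
        values=values,
        psa=psa,
        labels=labels.astype(int),
        patient_ids=[str(x) for x in sub["patient_id"]],
        task=task,
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical CSV (full float precision round-trips)."""
    cohort.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class ValidationReport:
    """Report-only structural audit of a cohort."""

    pair_violations: list[tuple[str, tuple[int, int], float]]  # (patient, pair, sum)
    range_violations: list[tuple[str, int, float]]  # (patient, feature id, value)

    @property
    def ok(self) -> bool:
        return not self.pair_violations and not self.range_violations


def validate_structure(cohort: Cohort, tolerance: float = 0.5) -> ValidationReport:
    """Flag complement pairs whose sum deviates from 100 beyond ``tolerance``
    percentage points, and any out-of-range values."""
    pairs, ranges = [], []
    fid_set = set(cohort.feature_ids)
    for a, b in COMPLEMENT_PAIRS:
        if a not in fid_set or b not in fid_set:
            continue
        s = cohort.values[:, cohort._col(a)] + cohort.values[:, cohort._col(b)]
        for i in np.flatnonzero(np.abs(s - 100.0) > tolerance):
            pairs.append((cohort.patient_ids[i], (a, b), float(s[i])))
    out = (cohort.values < 0) | (cohort.values > 100)
    for i, j in np.argwhere(out):
        pairs_fid = cohort.feature_ids[j]
        ranges.append((cohort.patient_ids[i], pairs_fid, float(cohort.values[i, j])))
    return ValidationReport(pair_violations=pairs, range_violations=ranges)


@dataclass
class DescriptiveStats:
    """Per-feature, per-group summary (mirrors the published table layout).

    ``table`` is indexed by feature id (0 = PSA) with columns
    min/max/mean/std/iqr/range per group plus the pooled ``diff`` column,
    where diff = mean(benign) - mean(cancer) (or L/I minus H for risk).
    """

    table: pd.DataFrame
    quartile_convention: str = "linear interpolation (type 7)"

    def diff(self, fid: int) -> float:
        return float(self.table.loc[fid, "diff"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.4g")


def descriptive_stats(cohort: Cohort) -> DescriptiveStats:
    """Group-conditional min/max/mean/std/IQR/range and the between-group
    mean difference for every feature and for PSA.

    std is the sample standard deviation (n-1); IQR uses linearly
    interpolated quartiles (numpy's default percentile convention).
    """
    g0 = cohort.labels == 0  # benign / low-intermediate
    g1 = cohort.labels == 1
    if g0.sum() < 2 or g1.sum() < 2:
        name = "negative (benign / L-I)" if g0.sum() < 2 else "positive (cancer / H)"
        raise ValueError(f"descriptive statistics need >= 2 patients per group; "
                         f"{name} group has too few")

    rows = {}

    def summarize(vec: np.ndarray) -> dict[str, float]:
        q75, q25 = np.percentile(vec, [75, 25])
        return {
            "min": float(vec.min()),
            "max": float(vec.max()),
            "mean": float(vec.mean()),
            "std": float(vec.std(ddof=1)),
            "iqr": float(q75 - q25),
            "range": float(vec.max() - vec.min()),
        }

    columns: dict[int, np.ndarray] = {PSA_ID: cohort.psa}
    for j, fid in enumerate(cohort.feature_ids):
        columns[fid] = cohort.values[:, j]

    for fid, vec in columns.items():
        s0, s1 = summarize(vec[g0]), summarize(vec[g1])
        row = {f"{k}_benign": v for k, v in s0.items()}
        row |= {f"{k}_cancer": v for k, v in s1.items()}
        row["diff"] = s0["mean"] - s1["mean"]
        row["name"] = feature_name(fid)
        rows[fid] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature_id"
    return DescriptiveStats(table=table)
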