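"""Patient-level cohort handling.

Reads and validates cohort tables, aggregates them into per-arm
success/failure counts and a 2x2 table, and runs the descriptive
group comparisons (t / Welch / F / chi-square).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, SchemaError, ValidationError

__all__ = [
    "PatientRecord",
    "ArmCounts",
    "TwoByTwoTable",
    "ArmSummary",
    "ComparisonResult",
    "read_cohort",
    "aggregate_arms",
    "compare_continuous",
    "compare_categorical",
    "summarize_cohort",
    "OUTCOME_ALIASES",
]

#: Accepted spellings of the binary outcome, normalized at read time.
OUTCOME_ALIASES = {
    "1": 1, "yes": 1, "y": 1, "true": 1, "pcr": 1,
    "0": 0, "no": 0, "n": 0, "false": 0, "non-pcr": 0, "nonpcr": 0,
}


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: stratum label, binary outcome, optional covariates."""

    patient_id: str
    stratum: str
    outcome: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValidationError(
                f"outcome must be 0 or 1, got {self.outcome!r} "
                f"(patient {self.patient_id!r})"
            )
        if not self.stratum:
            raise ValidationError(f"missing stratum for patient {self.patient_id!r}")


@dataclass(frozen=True)
class ArmCounts:
    """Successes/failures for one arm: the binomial sufficient statistic."""

    successes: int
    failures: int

    def __post_init__(self) -> None:
        if self.successes < 0 or self.failures < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.successes + self.failures

    @property
    def proportion(self) -> float:
        if self.total == 0:
            raise DataError("proportion undefined for empty arm")
        return self.successes / self.total


@dataclass(frozen=True)
class TwoByTwoTable:
    """Stratum-by-outcome cross tabulation.

    Laid out as (arm1 successes ``a``, arm1 failures ``b``,
    arm2 successes ``c``, arm2 failures ``d``); arm1 is the
    exposed/numerator arm.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("table cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_arms(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.c, self.d, self.a, self.b)

    def swap_outcome(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient summary (n, mean, sd) of a continuous covariate in one arm."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError(f"need n >= 2 per arm, got n={self.n}")
        if not self.sd > 0:
            raise DataError(f"need sd > 0, got sd={self.sd}")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one group-comparison test."""

    test_name: str  # pooled-t | welch-t | f-variance | chi-square
    statistic: float
    df: float
    p_value: float
    variance_test: "ComparisonResult | None" = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


def _normalize_outcome(raw: object, row: int) -> int:
    key = str(raw).strip().lower()
    if key in OUTCOME_ALIASES:
        return OUTCOME_ALIASES[key]
    # integers parsed by pandas come through as "1.0"
    try:
        val = float(key)
    except ValueError:
        raise ValidationError(f"row {row}: unrecognized outcome value {raw!r}")
    if val in (0.0, 1.0):
        return int(val)
    raise ValidationError(f"row {row}: non-binary outcome value {raw!r}")


def read_cohort(path, schema: Mapping[str, object]) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row, comma separated, UTF-8.
    schema
        Column-name mapping with keys ``stratum`` and ``outcome``
        (required), ``patient_id`` (optional; row number used if absent)
        and ``covariates`` (optional list of column names, or mapping of
        record-field name to column name).

    Raises
    ------
    SchemaError
        If a declared column is missing from the file.
    ValidationError
        Listing every malformed row (1-based data-row indices).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key in ("stratum", "outcome"):
        if key not in schema:
            raise SchemaError(f"schema must declare a {key!r} column")
        if schema[key] not in df.columns:
            raise SchemaError(
                f"declared {key} column {schema[key]!r} not in file "
                f"(columns: {list(df.columns)})"
            )
    cov_map: dict[str, str] = {}
    covs = schema.get("covariates", [])
    if isinstance(covs, Mapping):
        cov_map = dict(covs)
    else:
        cov_map = {c: c for c in covs}
    for name, col in cov_map.items():
        if col not in df.columns:
            raise SchemaError(f"declared covariate column {col!r} not in file")

    id_col = schema.get("patient_id")
    records: list[PatientRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        stratum = str(row_d[schema["stratum"]]).strip()
        if not stratum:
            problems.append(f"row {i}: missing stratum")
            continue
        try:
            outcome = _normalize_outcome(row_d[schema["outcome"]], i)
        except ValidationError as exc:
            problems.append(str(exc))
            continue
        pid = str(row_d[id_col]) if id_col else f"row{i}"
        covariates: dict[str, object] = {}
        for name, col in cov_map.items():
            raw = str(row_d[col]).strip()
            if raw == "":
                continue  # missing covariates allowed
            try:
                covariates[name] = float(raw)
            except ValueError:
                covariates[name] = raw
        records.append(PatientRecord(pid, stratum, outcome, covariates))
    if problems:
        raise ValidationError(
            f"{len(problems)} malformed row(s): " + "; ".join(problems)
        )
    return records


def aggregate_arms(
    records: Sequence[PatientRecord],
    stratum_levels: tuple[str, str],
) -> tuple[ArmCounts, ArmCounts, TwoByTwoTable]:
    """Partition a cohort into per-arm counts, arm order as supplied.

    Returns ``(counts_arm1, counts_arm2, table)`` where ``table`` has
    arm1 (the first supplied level) in the top row.
    """
    lvl1, lvl2 = stratum_levels
    seen = {r.stratum for r in records}
    unexpected = sorted(seen - {lvl1, lvl2})
    if unexpected:
        raise DataError(f"unexpected stratum labels: {unexpected}")
    tallies = {lvl1: [0, 0], lvl2: [0, 0]}
    for r in records:
        if r.outcome == 1:
            tallies[r.stratum][0] += 1
        else:
            tallies[r.stratum][1] += 1
    for lvl in (lvl1, lvl2):
        if sum(tallies[lvl]) == 0:
            raise DataError(f"stratum {lvl!r} has no records")
    arm1 = ArmCounts(*tallies[lvl1])
    arm2 = ArmCounts(*tallies[lvl2])
    return arm1, arm2, TwoByTwoTable(arm1.successes, arm1.failures,
                                     arm2.successes, arm2.failures)


def _as_summary(arm) -> ArmSummary:
    if isinstance(arm, ArmSummary):
        return arm
    if isinstance(arm, tuple) and len(arm) == 3:
        return ArmSummary(int(arm[0]), float(arm[1]), float(arm[2]))
    values = np.asarray(arm, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise DataError(f"need at least 2 observations per arm, got {values.size}")
    return ArmSummary(int(values.size), float(values.mean()),
                      float(values.std(ddof=1)))


def compare_continuous(arm1, arm2, *, var_test_alpha: float = 0.05) -> ComparisonResult:
    """Two-sample mean comparison with F-test dispatch.

    Each arm is either a sequence of raw values or an ``(n, mean, sd)``
    summary (tuple or :class:`ArmSummary`); raw data are reduced to
    their summary first, so both input forms give identical results.
    The two-sided F test for variance equality decides between the
    pooled t-test (not rejected at ``var_test_alpha``) and Welch's
    t-test (rejected); the F result rides along in ``variance_test``.
    """
    s1, s2 = _as_summary(arm1), _as_summary(arm2)
    f_stat = s1.sd**2 / s2.sd**2
    df1, df2 = s1.n - 1, s2.n - 1
    f_cdf = stats.f.cdf(f_stat, df1, df2)
    f_p = 2.0 * min(f_cdf, 1.0 - f_cdf)
    f_res = ComparisonResult("f-variance", f_stat, float(df1), min(f_p, 1.0))

    equal_var = f_res.p_value >= var_test_alpha
    t = stats.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=equal_var
    )
    if equal_var:
        name, df = "pooled-t", float(s1.n + s2.n - 2)
    else:
        name = "welch-t"
        # Welch–Satterthwaite df
        v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    return ComparisonResult(name, float(t.statistic), df, float(t.pvalue),
                            variance_test=f_res)


def compare_categorical(table, *, correction: bool = False) -> ComparisonResult:
    """Pearson chi-square test of independence on a 2x2 or r x c table.

    Yates continuity correction is off by default (``correction=True``
    to enable). A zero marginal row or column makes the test undefined
    and raises :class:`DataError`.
    """
    if isinstance(table, TwoByTwoTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValidationError("table cells must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DataError("chi-square undefined: zero marginal row or column")
    res = stats.chi2_contingency(arr, correction=correction)
    return ComparisonResult("chi-square", float(res.statistic),
                            float(res.dof), float(res.pvalue))


def summarize_cohort(
    records: Sequence[PatientRecord],
    stratum_levels: tuple[str, str],
    *,
    correction: bool = False,
) -> dict:
    """Descriptive per-arm table (n, outcome %, covariate mean +/- sd)
    with the matching group-comparison p-values.

    Numeric covariates get the F-dispatched t-test; the outcome gets a
    chi-square. Missing covariate values are dropped pairwise.
    """
    arm1, arm2, table = aggregate_arms(records, stratum_levels)
    lvl1, lvl2 = stratum_levels
    out: dict = {
        "n": {lvl1: arm1.total, lvl2: arm2.total},
        "outcome": {
            lvl1: {"successes": arm1.successes,
                   "percent": round(100 * arm1.proportion, 1)},
            lvl2: {"successes": arm2.successes,
                   "percent": round(100 * arm2.proportion, 1)},
            "test": compare_categorical(table, correction=correction).__dict__,
        },
        "covariates": {},
    }
    names = sorted({k for r in records for k in r.covariates})
    for name in names:
        vals = {lvl: [r.covariates[name] for r in records
                      if r.stratum == lvl and name in r.covariates]
                for lvl in stratum_levels}
        if all(isinstance(v, float) for lvl in stratum_levels for v in vals[lvl]):
            entry = {}
            for lvl in stratum_levels:
                arr = np.asarray(vals[lvl], dtype=float)
                entry[lvl] = {
                    "n": int(arr.size),
                    "mean": float(arr.mean()) if arr.size else math.nan,
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
                }
            try:
                cmp_res = compare_continuous(vals[lvl1], vals[lvl2])
                entry["test"] = {k: v for k, v in cmp_res.__dict__.items()
                                 if k != "variance_test"}
            except DataError:
                entry["test"] = None
            out["covariates"][name] = entry
    return out
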