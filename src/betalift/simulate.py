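"""Synthetic two-stratum cohort generation and parameter-recovery studies.

Generates patient-level cohorts with the statistical structure the
analysis pipeline assumes (Bernoulli stratum assignment, per-stratum
Bernoulli outcome, per-stratum normal or categorical covariates,
optionally logistic-linked covariates driving the outcome), plus a
deterministic fixture cohort matching the reference 2x2 table, and a
replicate-based recovery study for credible-interval coverage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bayes import BetaParams, credible_interval, posterior_update
from .cohort import ArmCounts, PatientRecord, aggregate_arms
from .errors import ConfigError
from .superiority import prob_superior_exact

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "RecoveryReport",
    "generate_cohort",
    "fixed_paper_cohort",
    "paper_default_config",
    "recovery_study",
    "write_cohort_csv",
    "default_schema",
    "REFERENCE_STRATA",
]

#: (reference arm, exposed/"mutation" arm) labels used by the fixture cohort.
REFERENCE_STRATA = ("BRCA1_neg", "BRCA1_pos")

_COVARIATE_KINDS = ("normal-by-stratum", "categorical-by-stratum",
                    "logistic-linked")


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate.

    kind
        ``normal-by-stratum``: params ``mean`` and ``sd`` are pairs
        aligned with ``CohortConfig.stratum_labels``.
        ``categorical-by-stratum``: params ``levels`` (list) and
        ``probs`` (pair of per-stratum probability lists).
        ``logistic-linked``: params ``mean``, ``sd`` (scalars),
        ``intercept``, ``slope``; the cohort outcome is then drawn from
        ``Bernoulli(expit(intercept + slope * x))`` instead of the
        per-stratum probabilities.
    """

    name: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in _COVARIATE_KINDS:
            raise ConfigError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "normal-by-stratum":
            sds = self.params.get("sd", ())
            if len(sds) != 2 or any(not (s > 0) for s in sds):
                raise ConfigError(f"covariate {self.name!r}: need two sd > 0")
        if self.kind == "categorical-by-stratum":
            for probs in self.params.get("probs", ()):
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"covariate {self.name!r}: level probabilities "
                        "must sum to 1 per stratum"
                    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-stratum cohort.

    ``stratum_prevalence`` is the probability of the second (exposed)
    label in ``stratum_labels``; ``p_outcome_by_stratum`` is aligned
    with ``stratum_labels``.
    """

    n_patients: int
    stratum_prevalence: float
    p_outcome_by_stratum: tuple[float, float]
    covariate_specs: tuple[CovariateSpec, ...] = ()
    stratum_labels: tuple[str, str] = REFERENCE_STRATA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not (0.0 <= self.stratum_prevalence <= 1.0):
            raise ConfigError(
                f"stratum_prevalence must be in [0,1], got "
                f"{self.stratum_prevalence}"
            )
        for p in self.p_outcome_by_stratum:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"outcome probability out of [0,1]: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        specs = tuple(
            CovariateSpec(s["name"], s["kind"], dict(s.get("params", {})))
            for s in d.get("covariate_specs", [])
        )
        return cls(
            n_patients=int(d["n_patients"]),
            stratum_prevalence=float(d["stratum_prevalence"]),
            p_outcome_by_stratum=tuple(float(p) for p in d["p_outcome_by_stratum"]),
            covariate_specs=specs,
            stratum_labels=tuple(d.get("stratum_labels", REFERENCE_STRATA)),
            seed=int(d.get("seed", 0)),
        )


def paper_default_config(seed: int = 0) -> CohortConfig:
    """Cohort config matching the reference study's marginal structure:
    143 patients, exposed-stratum prevalence 24/143, per-stratum outcome
    probabilities (0.403, 0.542), and age / Ki-67 normal covariates with
    per-stratum moments."""
    return CohortConfig(
        n_patients=143,
        stratum_prevalence=24 / 143,
        p_outcome_by_stratum=(48 / 119, 13 / 24),
        covariate_specs=(
            CovariateSpec("age", "normal-by-stratum",
                          {"mean": (57.1, 47.0), "sd": (12.5, 12.9)}),
            CovariateSpec("ki67", "normal-by-stratum",
                          {"mean": (64.3, 77.3), "sd": (25.8, 17.6)}),
        ),
        seed=seed,
    )


def generate_cohort(config: CohortConfig, rng=None) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort from ``config``.

    Stratum assignment is Bernoulli(prevalence); the outcome is
    Bernoulli(p of the assigned stratum) unless any logistic-linked
    covariate is present, in which case the outcome is drawn from the
    summed linear predictor of those covariates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    exposed = rng.random(n) < config.stratum_prevalence
    strata = np.where(exposed, config.stratum_labels[1], config.stratum_labels[0])
    cov_values: dict[str, np.ndarray] = {}
    linear_pred = np.zeros(n)
    any_linked = False
    for spec in config.covariate_specs:
        if spec.kind == "normal-by-stratum":
            means = np.where(exposed, spec.params["mean"][1], spec.params["mean"][0])
            sds = np.where(exposed, spec.params["sd"][1], spec.params["sd"][0])
            cov_values[spec.name] = rng.normal(means, sds)
        elif spec.kind == "categorical-by-stratum":
            levels = list(spec.params["levels"])
            draws = np.empty(n, dtype=object)
            for which, probs in zip((False, True), spec.params["probs"]):
                mask = exposed == which
                if mask.any():
                    draws[mask] = rng.choice(levels, size=int(mask.sum()), p=probs)
            cov_values[spec.name] = draws
        else:  # logistic-linked
            x = rng.normal(spec.params["mean"], spec.params["sd"], size=n)
            cov_values[spec.name] = x
            linear_pred += spec.params["intercept"] + spec.params["slope"] * x
            any_linked = True
    if any_linked:
        p = 1.0 / (1.0 + np.exp(-linear_pred))
    else:
        p = np.where(exposed, config.p_outcome_by_stratum[1],
                     config.p_outcome_by_stratum[0])
    outcomes = (rng.random(n) < p).astype(int)
    width = len(str(n))
    records = []
    for i in range(n):
        covs = {}
        for name, vals in cov_values.items():
            v = vals[i]
            covs[name] = float(v) if isinstance(v, (np.floating, float)) else str(v)
        records.append(PatientRecord(
            patient_id=f"S{i + 1:0{width}d}",
            stratum=str(strata[i]),
            outcome=int(outcomes[i]),
            covariates=covs,
        ))
    return records


def fixed_paper_cohort() -> list[PatientRecord]:
    """Deterministic 143-record cohort reproducing the reference 2x2 table.

    Exactly 24 exposed records (13 with outcome 1) and 119 reference
    records (48 with outcome 1), ordered stratum, then outcome, then
    index, so downstream hashes are stable.
    """
    neg, pos = REFERENCE_STRATA
    blocks = [(pos, 1, 13), (pos, 0, 11), (neg, 1, 48), (neg, 0, 71)]
    records = []
    i = 0
    for stratum, outcome, count in blocks:
        for _ in range(count):
            i += 1
            records.append(PatientRecord(f"P{i:03d}", stratum, outcome, {}))
    return records


def default_schema() -> dict:
    """Schema under which :func:`write_cohort_csv` output re-reads."""
    return {"patient_id": "patient_id", "stratum": "stratum",
            "outcome": "outcome"}


def write_cohort_csv(records: Sequence[PatientRecord], path) -> dict:
    """Write records as CSV; returns the schema that reads them back.

    Covariate columns are the union of covariate names across records;
    missing values are left empty.
    """
    cov_names = sorted({k for r in records for k in r.covariates})
    schema = default_schema()
    schema["covariates"] = {c: c for c in cov_names}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "stratum", "outcome", *cov_names])
        for r in records:
            row = [r.patient_id, r.stratum, r.outcome]
            for c in cov_names:
                v = r.covariates.get(c, "")
                row.append(repr(v) if isinstance(v, float) else v)
            writer.writerow(row)
    return schema


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate results of a parameter-recovery study."""

    n_replicates: int
    coverage: tuple[float, float]          # per-arm CI coverage of true p
    mean_abs_error: tuple[float, float]    # per-arm |posterior mean - true p|
    superiority_correct: float             # fraction calling the true ordering
    mean_superiority: float                # mean exact P(exposed > reference)
    level: float
    seed: int


def recovery_study(
    true_config: CohortConfig,
    n_replicates: int,
    *,
    priors: tuple[BetaParams, BetaParams] = (BetaParams(1, 1), BetaParams(1, 1)),
    level: float = 0.95,
    seed: int = 0,
) -> RecoveryReport:
    """Generate-analyze replicates to validate the inference chain.

    Per replicate: draw a cohort, form per-arm posteriors under
    ``priors`` (aligned with ``stratum_labels``), and record whether
    each credible interval covers the true per-arm probability, the
    posterior-mean absolute error, and whether the exact superiority
    probability favours the truly better arm. Defaults to uniform
    priors so coverage is not confounded by prior shrinkage.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    labels = true_config.stratum_labels
    p_ref, p_exp = true_config.p_outcome_by_stratum
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    covered = np.zeros(2)
    abs_err = np.zeros(2)
    correct = 0
    sup_sum = 0.0
    truth_exposed_better = p_exp > p_ref
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        records = generate_cohort(true_config, rng=rng)
        counts = {lbl: [0, 0] for lbl in labels}
        for r in records:
            counts[r.stratum][0 if r.outcome else 1] += 1
        posts = []
        for k, lbl in enumerate(labels):
            arm = ArmCounts(*counts[lbl])
            post = posterior_update(priors[k], arm)
            posts.append(post)
            ci = credible_interval(post, level)
            true_p = (p_ref, p_exp)[k]
            covered[k] += ci.lower <= true_p <= ci.upper
            abs_err[k] += abs(post.mean - true_p)
        p_sup = prob_superior_exact(posts[1], posts[0])
        sup_sum += p_sup
        if p_exp != p_ref:
            correct += (p_sup > 0.5) == truth_exposed_better
    return RecoveryReport(
        n_replicates=n_replicates,
        coverage=tuple(covered / n_replicates),
        mean_abs_error=tuple(abs_err / n_replicates),
        superiority_correct=correct / n_replicates,
        mean_superiority=sup_sum / n_replicates,
        level=level,
        seed=seed,
    )
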