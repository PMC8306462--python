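"""End-to-end analysis: configuration, pipeline, and structured report.

``run_full_analysis`` chains aggregation, the beta-binomial update,
credible intervals, Monte Carlo superiority, the relative-improvement
distribution, the 2x2 odds ratio with profile CI, and the descriptive
group comparisons into one JSON- and markdown-serializable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .association import ORResult, odds_ratio, or_confint_profile, or_confint_wald
from .bayes import (BetaParams, CredibleInterval, credible_interval,
                    likelihood_beta, posterior_update)
from .cohort import (ArmCounts, TwoByTwoTable, aggregate_arms,
                     compare_categorical, read_cohort, summarize_cohort)
from .errors import BetaliftError, ConfigError
from .superiority import (DEFAULT_N_TRIALS, DEFAULT_SEED, RatioSummary,
                          SuperiorityResult, prob_superior, relative_improvement,
                          sample_pair)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "paper_analysis_config"]

logger = logging.getLogger("betalift")


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs of one full analysis.

    Exactly one of ``cohort_csv`` (with ``schema``) or ``counts`` must
    be provided. ``counts`` maps each of the two stratum labels to
    ``{"successes": int, "failures": int}``. ``stratum_levels`` lists
    the exposed/numerator arm first; priors align with that order.
    """

    stratum_levels: tuple[str, str]
    cohort_csv: str | None = None
    schema: Mapping[str, object] | None = None
    counts: Mapping[str, Mapping[str, int]] | None = None
    priors: tuple[BetaParams, BetaParams] = (BetaParams(4, 6), BetaParams(3, 7))
    credible_level: float = 0.95
    n_trials: int = DEFAULT_N_TRIALS
    seed: int = DEFAULT_SEED
    thresholds: tuple[float, ...] = (1.5,)
    percentile_grid: tuple[float, ...] = (25.0, 50.0, 75.0)
    numerator: str = "auto"
    chi_square_correction: bool = False

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.counts is None):
            raise ConfigError(
                "provide exactly one of cohort_csv or inline counts"
            )
        if self.cohort_csv is not None and self.schema is None:
            raise ConfigError("cohort_csv requires a schema")
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (0.0 < self.credible_level < 1.0):
            raise ConfigError("credible_level must be in (0,1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        levels = tuple(d["stratum_levels"])
        if len(levels) != 2:
            raise ConfigError("stratum_levels must list exactly two labels")
        priors_raw = d.get("priors")
        if priors_raw is None:
            priors = (BetaParams(4, 6), BetaParams(3, 7))
        else:
            priors = tuple(
                BetaParams(float(p["alpha"]), float(p["beta"]))
                for p in (priors_raw[levels[0]], priors_raw[levels[1]])
            )
        return cls(
            stratum_levels=levels,
            cohort_csv=d.get("cohort_csv"),
            schema=d.get("schema"),
            counts=d.get("counts"),
            priors=priors,
            credible_level=float(d.get("credible_level", 0.95)),
            n_trials=int(d.get("n_trials", DEFAULT_N_TRIALS)),
            seed=int(d.get("seed", DEFAULT_SEED)),
            thresholds=tuple(float(t) for t in d.get("thresholds", (1.5,))),
            percentile_grid=tuple(float(q) for q in
                                  d.get("percentile_grid", (25.0, 50.0, 75.0))),
            numerator=str(d.get("numerator", "auto")),
            chi_square_correction=bool(d.get("chi_square_correction", False)),
        )

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path!r} must hold a mapping")
        return cls.from_dict(data)

    def canonical_dict(self) -> dict:
        d = {
            "stratum_levels": list(self.stratum_levels),
            "cohort_csv": self.cohort_csv,
            "schema": dict(self.schema) if self.schema else None,
            "counts": {k: dict(v) for k, v in self.counts.items()}
                      if self.counts else None,
            "priors": [[p.alpha, p.beta] for p in self.priors],
            "credible_level": self.credible_level,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "thresholds": list(self.thresholds),
            "percentile_grid": list(self.percentile_grid),
            "numerator": self.numerator,
            "chi_square_correction": self.chi_square_correction,
        }
        return d

    def hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def paper_analysis_config(seed: int = DEFAULT_SEED, **overrides) -> AnalysisConfig:
    """Reference-study analysis on inline counts: exposed arm (13, 11)
    with a Beta(4,6) prior, reference arm (48, 71) with Beta(3,7)."""
    kwargs = dict(
        stratum_levels=("BRCA1_pos", "BRCA1_neg"),
        counts={"BRCA1_pos": {"successes": 13, "failures": 11},
                "BRCA1_neg": {"successes": 48, "failures": 71}},
        priors=(BetaParams(4, 6), BetaParams(3, 7)),
        seed=seed,
    )
    kwargs.update(overrides)
    return AnalysisConfig(**kwargs)


@dataclass(frozen=True)
class AnalysisReport:
    """All results of one pipeline run, serializable to JSON/markdown."""

    config_hash: str
    seed: int
    version: str
    arm_labels: tuple[str, str]
    counts: tuple[ArmCounts, ArmCounts]
    table: TwoByTwoTable
    data_only: "tuple[dict, dict] | None"   # per-arm params/mean/interval
    posterior: tuple[dict, dict]
    superiority: SuperiorityResult
    ratio: RatioSummary
    odds_ratio: ORResult
    odds_ratio_wald: ORResult
    chi_square: dict
    cohort_summary: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
            },
            "arms": {},
            "superiority": {
                "prob_superior": self.superiority.prob_superior,
                "n_trials": self.superiority.n_trials,
                "seed": self.superiority.seed,
                "mc_standard_error": self.superiority.mc_standard_error,
            },
            "ratio": {
                "numerator": self.ratio.numerator,
                "percentiles": {str(q): v
                                for q, v in self.ratio.percentiles.items()},
                "threshold_probs": {str(t): p for t, p in
                                    self.ratio.threshold_probs.items()},
            },
            "odds_ratio": asdict(self.odds_ratio),
            "odds_ratio_wald": asdict(self.odds_ratio_wald),
            "chi_square": self.chi_square,
        }
        for i, label in enumerate(self.arm_labels):
            d["arms"][label] = {
                "successes": self.counts[i].successes,
                "failures": self.counts[i].failures,
                "data_only": self.data_only[i] if self.data_only else None,
                "posterior": self.posterior[i],
            }
        if self.cohort_summary is not None:
            d["cohort_summary"] = self.cohort_summary
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    def to_markdown(self) -> str:
        lines = ["# Beta-binomial A/B analysis", ""]
        lines.append(f"Config `{self.config_hash}`, seed {self.seed}, "
                     f"betalift {self.version}")
        lines.append("")
        lines.append("| arm | successes | failures | posterior | mean | "
                     f"{int(100 * self.posterior[0]['interval']['level'])}% CrI |")
        lines.append("|---|---|---|---|---|---|")
        for i, label in enumerate(self.arm_labels):
            post = self.posterior[i]
            iv = post["interval"]
            lines.append(
                f"| {label} | {self.counts[i].successes} | "
                f"{self.counts[i].failures} | "
                f"Beta({post['alpha']:g}, {post['beta']:g}) | "
                f"{post['mean']:.3f} | "
                f"{100 * iv['lower']:.1f}–{100 * iv['upper']:.1f}% |"
            )
        lines.append("")
        lines.append(
            f"P({self.arm_labels[0]} rate > {self.arm_labels[1]} rate) = "
            f"{self.superiority.prob_superior:.3f} "
            f"(n = {self.superiority.n_trials:,}, "
            f"MC SE = {self.superiority.mc_standard_error:.4f})"
        )
        pct = ", ".join(f"P{q:g} = {v:.2f}"
                        for q, v in sorted(self.ratio.percentiles.items()))
        lines.append(f"Relative-improvement percentiles: {pct}")
        for t, p in sorted(self.ratio.threshold_probs.items()):
            lines.append(f"P(ratio >= {t:g}) = {p:.3f}")
        orr = self.odds_ratio
        lines.append(
            f"Odds ratio {orr.odds_ratio:.2f} "
            f"({orr.ci_lower:.2f}, {orr.ci_upper:.2f}; "
            f"{int(100 * orr.level)}% profile-likelihood CI)"
        )
        chi = self.chi_square
        lines.append(
            f"Chi-square: statistic {chi['statistic']:.3f}, "
            f"df {chi['df']:g}, p = {chi['p_value']:.3f}"
        )
        return "\n".join(lines) + "\n"


def _arm_block(params: BetaParams, interval: CredibleInterval) -> dict:
    return {
        "alpha": params.alpha,
        "beta": params.beta,
        "mean": params.mean,
        "interval": {"lower": interval.lower, "upper": interval.upper,
                     "level": interval.level},
    }


def _counts_from_config(config: AnalysisConfig):
    lvl1, lvl2 = config.stratum_levels
    if config.counts is not None:
        try:
            arms = tuple(
                ArmCounts(int(config.counts[lvl]["successes"]),
                          int(config.counts[lvl]["failures"]))
                for lvl in (lvl1, lvl2)
            )
        except KeyError as exc:
            raise ConfigError(f"counts missing entry for {exc}") from exc
        table = TwoByTwoTable(arms[0].successes, arms[0].failures,
                              arms[1].successes, arms[1].failures)
        return arms, table, None
    records = read_cohort(config.cohort_csv, config.schema)
    arm1, arm2, table = aggregate_arms(records, config.stratum_levels)
    summary = summarize_cohort(records, config.stratum_levels,
                               correction=config.chi_square_correction)
    return (arm1, arm2), table, summary


def _stage(name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except BetaliftError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    logger.info("stage %s done in %.3fs", name, time.perf_counter() - t0)
    return result


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the whole pipeline on a cohort CSV or inline counts.

    Deterministic for a fixed config: two runs with the same seed give
    byte-identical JSON reports. Stage failures propagate with the
    stage name attached.
    """
    (arm1, arm2), table, cohort_summary = _stage(
        "aggregate", _counts_from_config, config)

    data_only = None
    if min(arm1.successes, arm1.failures, arm2.successes, arm2.failures) >= 1:
        lik = (_stage("likelihood", likelihood_beta, arm1),
               _stage("likelihood", likelihood_beta, arm2))
        data_only = tuple(
            _arm_block(p, credible_interval(p, config.credible_level))
            for p in lik
        )
    posts = (
        _stage("posterior", posterior_update, config.priors[0], arm1),
        _stage("posterior", posterior_update, config.priors[1], arm2),
    )
    posterior = tuple(
        _arm_block(p, credible_interval(p, config.credible_level))
        for p in posts
    )
    samples = _stage("sample", sample_pair, posts[0], posts[1],
                     config.n_trials, config.seed)
    sup = _stage("superiority", prob_superior, samples)
    ratio = _stage("ratio", relative_improvement, samples, config.numerator,
                   percentile_grid=config.percentile_grid,
                   thresholds=config.thresholds)
    orr = _stage("odds_ratio", or_confint_profile, table,
                 config.credible_level)
    orr_wald = _stage("odds_ratio_wald", or_confint_wald, table,
                      config.credible_level)
    chi = _stage("chi_square", compare_categorical, table,
                 correction=config.chi_square_correction)
    return AnalysisReport(
        config_hash=config.hash(),
        seed=config.seed,
        version=__version__,
        arm_labels=config.stratum_levels,
        counts=(arm1, arm2),
        table=table,
        data_only=data_only,
        posterior=posterior,
        superiority=sup,
        ratio=ratio,
        odds_ratio=orr,
        odds_ratio_wald=orr_wald,
        chi_square={"statistic": chi.statistic, "df": chi.df,
                    "p_value": chi.p_value},
        cohort_summary=cohort_summary,
    )
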