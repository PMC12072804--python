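"""Synthetic patient cohorts for the jaundice-screening pipeline.

Total bilirubin is modelled per group as a log-normal variate — bilirubin is
a strictly positive, right-skewed laboratory quantity, and a log-normal is the
simplest two-parameter family matching a reported median and interquartile
range.  Defaults reproduce the clinical cohort this package targets: a liver
disease group with median total bilirubin 5.46 mg/dL (IQR 4.18-13.31) and a
control group with median 0.85 mg/dL (IQR 0.63-1.11).  The log-scale sigma is
solved from the IQR ratio: for a log-normal, q75/q25 = exp(2 z_0.75 sigma).

Direct (conjugated) bilirubin is a clipped-Gaussian fraction of total, so the
invariant 0 <= direct <= total holds by construction.  AST/ALT/ALP columns are
generated from the same log-normal recipe purely for table realism; no model
in this package reads them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError

_Z75 = float(norm.ppf(0.75))  # 0.6745, quartile z-score of the standard normal

#: Clinical cutoff for visible scleral icterus, mg/dL total bilirubin.
CLINICAL_THRESHOLD = 3.0


def lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(log-median, log-sigma) of the log-normal matching a median and IQR ratio."""
    if not (0 < q25 < q75) or median <= 0:
        raise ConfigurationError("median and quartiles must be positive with q25 < q75")
    return math.log(median), math.log(q75 / q25) / (2.0 * _Z75)


# Liver-panel log-normal parameters per group, from (median, q25, q75):
_CHEMISTRY = {
    "case": {
        "ast": lognormal_params(110.0, 72.0, 234.0),
        "alt": lognormal_params(35.0, 20.0, 101.0),
        "alp": lognormal_params(136.0, 99.0, 199.0),
    },
    "control": {
        "ast": lognormal_params(39.0, 24.0, 76.0),
        "alt": lognormal_params(41.0, 20.0, 86.0),
        "alp": lognormal_params(83.0, 71.0, 140.0),
    },
}

_CASE_LOGMEDIAN, _CASE_LOGSIGMA = lognormal_params(5.46, 4.18, 13.31)
_CONTROL_LOGMEDIAN, _CONTROL_LOGSIGMA = lognormal_params(0.85, 0.63, 1.11)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's laboratory values and jaundice status."""

    subject_id: str
    group: str  # "case" | "control"
    total_bilirubin: float  # mg/dL, > 0
    direct_bilirubin: float  # mg/dL, 0 <= direct <= total
    jaundice_label: bool  # total_bilirubin > clinical threshold
    ast: float | None = None  # U/L
    alt: float | None = None  # U/L
    alp: float | None = None  # U/L

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.total_bilirubin <= 0:
            raise ConfigurationError("total bilirubin must be > 0")
        if not (0 <= self.direct_bilirubin <= self.total_bilirubin):
            raise ConfigurationError("direct bilirubin must lie in [0, total]")


@dataclass
class CohortConfig:
    """Sampling parameters for a two-group bilirubin cohort.

    Defaults reproduce the target cohort geometry (57 cases, 31 controls) and
    its per-group bilirubin medians/IQRs.
    """

    n_cases: int = 57
    n_controls: int = 31
    case_logmedian: float = _CASE_LOGMEDIAN
    case_logsigma: float = _CASE_LOGSIGMA
    control_logmedian: float = _CONTROL_LOGMEDIAN
    control_logsigma: float = _CONTROL_LOGSIGMA
    direct_fraction_mean: float = 0.5  # conjugated share of total bilirubin
    direct_fraction_sd: float = 0.12
    clinical_threshold: float = CLINICAL_THRESHOLD  # mg/dL
    include_chemistry: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if self.case_logsigma <= 0 or self.control_logsigma <= 0:
            raise ConfigurationError("log-sigma parameters must be > 0")
        if not (0 < self.direct_fraction_mean < 1):
            raise ConfigurationError("direct_fraction_mean must lie in (0, 1)")
        if self.direct_fraction_sd < 0:
            raise ConfigurationError("direct_fraction_sd must be >= 0")

    def group_quartiles(self, group: str) -> tuple[float, float, float]:
        """Theoretical (q25, median, q75) of total bilirubin for a group."""
        mu, sigma = (
            (self.case_logmedian, self.case_logsigma)
            if group == "case"
            else (self.control_logmedian, self.control_logsigma)
        )
        return (
            math.exp(mu - _Z75 * sigma),
            math.exp(mu),
            math.exp(mu + _Z75 * sigma),
        )


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a full cohort; a pure function of the config (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    groups = [("case", config.n_cases, config.case_logmedian, config.case_logsigma)] + [
        ("control", config.n_controls, config.control_logmedian, config.control_logsigma)
    ]
    idx = 0
    for group, n, mu, sigma in groups:
        total = np.exp(mu + sigma * rng.standard_normal(n))
        frac = np.clip(
            rng.normal(config.direct_fraction_mean, config.direct_fraction_sd, n),
            0.0,
            1.0,
        )
        chem = {}
        if config.include_chemistry:
            for name, (cmu, csigma) in _CHEMISTRY[group].items():
                chem[name] = np.exp(cmu + csigma * rng.standard_normal(n))
        for i in range(n):
            idx += 1
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:04d}",
                    group=group,
                    total_bilirubin=float(total[i]),
                    direct_bilirubin=float(frac[i] * total[i]),
                    jaundice_label=bool(total[i] > config.clinical_threshold),
                    ast=float(chem["ast"][i]) if chem else None,
                    alt=float(chem["alt"][i]) if chem else None,
                    alp=float(chem["alp"][i]) if chem else None,
                )
            )
    return records


def cohort_to_frame(cohort: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "total_bilirubin": r.total_bilirubin,
            "direct_bilirubin": r.direct_bilirubin,
            "jaundice_label": r.jaundice_label,
            "ast": r.ast,
            "alt": r.alt,
            "alp": r.alp,
        }
        for r in cohort
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "total_bilirubin",
            "direct_bilirubin",
            "jaundice_label",
            "ast",
            "alt",
            "alp",
        ],
    )


def write_cohort(cohort: Iterable[SubjectRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                total_bilirubin=float(row.total_bilirubin),
                direct_bilirubin=float(row.direct_bilirubin),
                jaundice_label=bool(row.jaundice_label),
                ast=None if pd.isna(getattr(row, "ast", np.nan)) else float(row.ast),
                alt=None if pd.isna(getattr(row, "alt", np.nan)) else float(row.alt),
                alp=None if pd.isna(getattr(row, "alp", np.nan)) else float(row.alp),
            )
        )
    return records
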