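"""Lognormal POD statistics and human-exposure threshold derivation.

For each structural class the adjusted PODs are modeled as lognormal:
log-scale location is the mean of natural logs (so the fitted median
equals the sample geometric mean exactly) and log-scale spread is the
sample standard deviation of natural logs with the n−1 denominator.  The
class threshold chain is

    POD_5% = exp(μ_log + z_0.05 · σ_log),      z_0.05 = −1.6448536269514722
    TDI    = POD_5% × 1000 / UF                [μg/kg bw/day, UF = 100]
    per-person threshold = TDI × body weight   [μg/person/day, 60 kg]

All chaining is done unrounded; rounding is applied only when rendering.
Classes with fewer than a configurable minimum number of substances
(default 30) are flagged unreliable and rendered "NA".
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import (
    AdjustedPOD,
    ClassSummary,
    ClassThreshold,
    CramerClass,
    DatasetReport,
    Z_P05,
)

DEFAULT_UF = 100.0
DEFAULT_BODY_WEIGHT_KG = 60.0
DEFAULT_MIN_N = 30


def fit_lognormal(pods: Sequence[float]) -> tuple[float, float]:
    """Fit (log_mu, log_sigma) to positive POD values.

    log_mu is the mean of natural logs; log_sigma is the n−1 sample
    standard deviation of natural logs.  Requires n ≥ 2 and all values
    positive.
    """
    arr = np.asarray(pods, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two POD values to fit a distribution")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("all POD values must be positive and finite")
    logs = np.log(arr)
    return float(np.mean(logs)), float(np.std(logs, ddof=1))


def lognormal_p5(log_mu: float, log_sigma: float) -> float:
    """5th percentile of a lognormal distribution, in mg/kg bw/day."""
    if log_sigma < 0:
        raise ValueError("log_sigma must be nonnegative")
    return math.exp(log_mu + Z_P05 * log_sigma)


def derive_threshold(
    pod_p5: float,
    n: int,
    min_n: int = DEFAULT_MIN_N,
    uf: float = DEFAULT_UF,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    cramer_class: CramerClass = CramerClass.III,
    log_mu: Optional[float] = None,
    log_sigma: Optional[float] = None,
) -> ClassThreshold:
    """Derive TDI and per-person threshold from a 5th-percentile POD.

    Values are stored unrounded; ``reliable`` is False when the class has
    fewer than ``min_n`` substances.
    """
    if pod_p5 <= 0 or uf <= 0 or body_weight_kg <= 0:
        raise ValueError("pod_p5, uf and body_weight_kg must be positive")
    tdi = pod_p5 * 1000.0 / uf
    return ClassThreshold(
        cramer_class=cramer_class,
        n=n,
        log_mu=log_mu,
        log_sigma=log_sigma,
        pod_p5=pod_p5,
        tdi_ug_kg_day=tdi,
        threshold_ug_person_day=tdi * body_weight_kg,
        reliable=n >= min_n,
    )


def class_summary(
    pods: Sequence[float], cramer_class: CramerClass = CramerClass.III
) -> ClassSummary:
    """Median, geometric mean, and log-POD ECDF of one class."""
    arr = np.asarray(pods, dtype=float)
    if arr.size == 0:
        raise ValueError("empty POD list")
    if np.any(arr <= 0):
        raise ValueError("all POD values must be positive")
    logs = np.sort(np.log(arr))
    n = arr.size
    ecdf = tuple((float(x), float((i + 1) / n)) for i, x in enumerate(logs))
    return ClassSummary(
        cramer_class=cramer_class,
        n=int(n),
        median=float(np.median(arr)),
        geometric_mean=float(math.exp(np.mean(logs))),
        ecdf=ecdf,
    )


def round_sig(x: float, digits: int) -> float:
    """Round to a number of significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def render_threshold(t: ClassThreshold) -> dict[str, str]:
    """Report rendering: TDI at 2 significant figures, per-person value at
    3; unreliable classes render as "NA"."""
    if not t.reliable or t.tdi_ug_kg_day is None:
        return {"tdi_ug_kg_day": "NA", "threshold_ug_person_day": "NA"}
    return {
        "tdi_ug_kg_day": f"{round_sig(t.tdi_ug_kg_day, 2):g}",
        "threshold_ug_person_day": f"{round_sig(t.threshold_ug_person_day, 3):g}",
    }


def run_ttc_analysis(
    groups: Mapping[CramerClass, Sequence[AdjustedPOD]],
    uf: float = DEFAULT_UF,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    min_n: int = DEFAULT_MIN_N,
    exclusion_counts: Optional[dict[str, int]] = None,
    config: Optional[dict] = None,
) -> DatasetReport:
    """Fit every class and assemble the dataset report.

    Classes with n < 2 (no fit possible) or n < min_n carry
    ``reliable=False``; their thresholds render as "NA" but fitted values
    (when computable) are retained at full precision.
    """
    thresholds: list[ClassThreshold] = []
    summaries: list[ClassSummary] = []
    per_substance: list[dict] = []
    duration_counts = {"28-83": 0, "84-179": 0}
    source_counts: dict[str, int] = {}

    for cls in CramerClass:
        adjusted = list(groups.get(cls, []))
        pods = [a.adjusted_pod for a in adjusted]
        n = len(pods)
        if n >= 2:
            log_mu, log_sigma = fit_lognormal(pods)
            p5 = lognormal_p5(log_mu, log_sigma)
            thresholds.append(
                derive_threshold(
                    p5,
                    n,
                    min_n=min_n,
                    uf=uf,
                    body_weight_kg=body_weight_kg,
                    cramer_class=cls,
                    log_mu=log_mu,
                    log_sigma=log_sigma,
                )
            )
        else:
            thresholds.append(ClassThreshold(cramer_class=cls, n=n, reliable=False))
        if n >= 1:
            summaries.append(class_summary(pods, cls))
        for a in adjusted:
            duration_counts[
                "28-83" if a.duration_factor_applied == 6 else "84-179"
            ] += 1
            src = a.study.source.value
            source_counts[src] = source_counts.get(src, 0) + 1
            per_substance.append(
                {
                    "substance_id": a.substance_id,
                    "cramer_class": cls.value,
                    "raw_effect_level": a.raw_effect_level,
                    "effect_level_type": a.study.effect_level_type.value,
                    "duration_days": a.study.duration_days,
                    "loael_factor": a.loael_factor_applied,
                    "duration_factor": a.duration_factor_applied,
                    "adjusted_pod": a.adjusted_pod,
                    "source": a.study.source.value,
                }
            )

    return DatasetReport(
        thresholds=thresholds,
        summaries=summaries,
        exclusion_counts=exclusion_counts or {},
        duration_counts=duration_counts,
        source_counts=source_counts,
        per_substance=per_substance,
        config={
            "uf": uf,
            "body_weight_kg": body_weight_kg,
            "min_n": min_n,
            **(config or {}),
        },
    )


def export_ecdf(summary: ClassSummary) -> "np.ndarray":
    """ECDF as a two-column array (log POD, cumulative fraction)."""
    return np.asarray(summary.ecdf, dtype=float)
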