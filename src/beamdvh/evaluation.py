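"""Prediction-accuracy metrics, plan comparison tables, agreement statistics.

Per-organ accuracy is summarized by δ (mean EUD error over test patients)
and precision by σ (sample standard deviation, n−1).  Per-patient errors are
SIGNED by default — predicted minus true, so a negative δ means systematic
under-prediction — with the absolute variant behind a flag; see the methods
note for why both conventions are offered.

Also provided: Bland-Altman limits of agreement (mean difference ± 1.96 SD)
and the Wilcoxon signed-rank test with an exact small-sample path (full
enumeration of sign assignments, ties handled by average ranks) and a
tie-corrected normal approximation for larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dvh import (
    DVHCurve,
    dose_at_absolute_volume,
    dose_at_relative_volume,
    max_dose,
    mean_dose,
)
from .eud import KRegistry, eud

__all__ = [
    "EvalSummary",
    "eud_errors",
    "summarize",
    "summarize_by_organ",
    "plan_metric_table",
    "limits_of_agreement",
    "paired_signed_rank",
]

#: largest number of informative pairs for which the signed-rank null is
#: enumerated exactly (2^n sign assignments); beyond this the tie-corrected
#: normal approximation is used
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class EvalSummary:
    """δ/σ accuracy summary for one organ over n test patients."""

    delta_gy: float
    sigma_gy: float
    n: int
    signed: bool = True


def eud_errors(
    pred_curves: Dict[Tuple[str, str], DVHCurve],
    true_curves: Dict[Tuple[str, str], DVHCurve],
    registry: KRegistry,
    signed: bool = True,
) -> Dict[Tuple[str, str], float]:
    """Per patient-structure EUD error (predicted − true; |·| if not signed)."""
    missing = sorted(set(pred_curves) ^ set(true_curves))
    if missing:
        raise ValueError(f"unmatched patient/structure pairs: {missing}")
    errors = {}
    for key in sorted(pred_curves):
        k = registry.resolve(key[1])
        err = eud(pred_curves[key], k) - eud(true_curves[key], k)
        errors[key] = err if signed else abs(err)
    return errors


def summarize(errors: Sequence[float], signed: bool = True) -> EvalSummary:
    """δ (mean) and σ (sample SD, n−1) of per-patient errors."""
    e = np.asarray(list(errors), dtype=float)
    n = e.size
    if n < 2:
        raise ValueError("need at least 2 errors for the sample SD")
    return EvalSummary(
        delta_gy=float(e.mean()), sigma_gy=float(e.std(ddof=1)), n=n, signed=signed
    )


def summarize_by_organ(
    errors: Dict[Tuple[str, str], float], signed: bool = True
) -> pd.DataFrame:
    """δ/σ per structure label; bilateral sides are separate structures."""
    rows = []
    by_organ: Dict[str, List[float]] = {}
    for (pid, sid), err in errors.items():
        by_organ.setdefault(sid, []).append(err)
    for sid in sorted(by_organ):
        s = summarize(by_organ[sid], signed=signed)
        rows.append(
            {"structure_id": sid, "delta_gy": s.delta_gy, "sigma_gy": s.sigma_gy, "n": s.n}
        )
    return pd.DataFrame(rows)


DEFAULT_METRICS = ("D98", "Dmax", "Dmean", "D1cc", "EUD")


def plan_metric_table(
    curves: Dict[Tuple[str, str], DVHCurve],
    registry: Optional[KRegistry] = None,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """Dose metrics per (patient, structure): D98, Dmax, Dmean, D1cc, EUD.

    Cells that cannot be computed (missing organ volume for D1cc, no exponent
    for EUD) are NaN with the reason recorded in an ``error`` column; the
    rest of the table is still emitted.
    """
    rows = []
    for (pid, sid), curve in sorted(curves.items()):
        for metric in metrics:
            value, error = np.nan, None
            try:
                if metric.startswith("D") and metric.endswith("cc"):
                    cc = float(metric[1:-2])
                    value = dose_at_absolute_volume(curve, cc)
                elif metric == "Dmax":
                    value = max_dose(curve)
                elif metric == "Dmean":
                    value = mean_dose(curve)
                elif metric == "EUD":
                    if registry is None:
                        raise ValueError("EUD metric requires a registry")
                    value = eud(curve, registry.resolve(sid))
                elif metric.startswith("D"):
                    value = dose_at_relative_volume(curve, float(metric[1:]) / 100.0)
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            except (ValueError, KeyError) as e:
                error = str(e)
            rows.append(
                {
                    "patient_id": pid,
                    "structure_id": sid,
                    "metric": metric,
                    "value_gy": value,
                    "error": error,
                }
            )
    return pd.DataFrame(rows)


class LimitsOfAgreement(NamedTuple):
    mean_diff: float
    lower: float
    upper: float
    frac_within: float


def limits_of_agreement(
    paired_values_a: Sequence[float], paired_values_b: Sequence[float]
) -> LimitsOfAgreement:
    """Bland-Altman limits: mean difference ± 1.96 · sample SD of differences."""
    a = np.asarray(list(paired_values_a), dtype=float)
    b = np.asarray(list(paired_values_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    frac = float(np.mean((d >= lower) & (d <= upper)))
    return LimitsOfAgreement(mean, lower, upper, frac)


def paired_signed_rank(
    paired_values_a: Sequence[float], paired_values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied magnitudes get average ranks.  For up
    to :data:`EXACT_ENUMERATION_LIMIT` informative pairs the null
    distribution of W+ (sum of positive ranks) is enumerated over all 2^n
    sign assignments of the observed ranks; above that, a tie-corrected
    normal approximation (no continuity correction) is used.
    """
    a = np.asarray(list(paired_values_a), dtype=float)
    b = np.asarray(list(paired_values_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("no informative pairs")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n <= EXACT_ENUMERATION_LIMIT:
        # exact: distribution of W+ over all sign assignments of these ranks
        signs = np.array(
            np.meshgrid(*([[0.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        w_null = ranks @ signs  # (2^n,) values of W+
        dev = abs(w_plus - mu)
        p = float(np.mean(np.abs(w_null - mu) >= dev - 1e-12))
    else:
        sigma = np.sqrt(np.sum(ranks ** 2) / 4.0)
        z = (w_plus - mu) / sigma
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(z)))
    return w_plus, min(p, 1.0)
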