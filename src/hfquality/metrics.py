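"""Evaluation statistics for the pipeline and its reference standard.

Everything an evaluation of an information-extraction system against a
human-annotated reference standard needs: 2x2 confusion counting,
sensitivity / specificity / positive predictive value with exact binomial
(Clopper-Pearson) confidence intervals, the F-measure (harmonic mean of
sensitivity and PPV), Cohen's kappa for concordance against structured-data
label vectors, inter-annotator percent agreement, and a five-row
patient-level evaluation report (measure met, LVSF assessed, EF <40%,
ACEI/ARB, reason-no-medication).

Estimates are percentages.  The Clopper-Pearson interval is computed from
beta-distribution quantiles; a Wilson score interval is available behind a
flag for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import beta

from .types import Classification, GoldAnnotation, PatientDeterminations

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (an undefined result is a
    signal, never silently a number)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricResult:
    """A proportion as a percentage with its exact 95% CI and denominator."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    successes: int

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.estimate <= self.ci_high <= 100:
            raise ValueError("CI must bracket the estimate within [0, 100]")

    def display(self, decimals: int = 1) -> str:
        return (
            f"{self.estimate:.{decimals}f} "
            f"({self.ci_low:.{decimals}f}, {self.ci_high:.{decimals}f})"
        )


def confusion_counts(
    predicted: Sequence, gold: Sequence, positive
) -> ConfusionCounts:
    """Standard 2x2 counting of aligned label vectors."""
    if len(predicted) != len(gold):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs {len(gold)} gold"
        )
    tp = fp = tn = fn = 0
    for p, g in zip(predicted, gold):
        if g == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def clopper_pearson_ci(
    successes: int, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact two-sided binomial CI, as percentages.

    Beta-quantile form: the lower bound is 0 when ``successes == 0`` and the
    upper bound is 100 when ``successes == n``.
    """
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    low = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    high = (
        1.0
        if successes == n
        else float(beta.isf(alpha / 2, successes + 1, n - successes))
    )
    return low * 100.0, high * 100.0


def wilson_ci(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval (for comparison with the exact interval)."""
    from statsmodels.stats.proportion import proportion_confint

    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    low, high = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(low) * 100.0, float(high) * 100.0


def _proportion(
    successes: int, n: int, alpha: float, method: str
) -> MetricResult:
    if n == 0:
        raise UndefinedMetricError("empty denominator")
    ci = wilson_ci if method == "wilson" else clopper_pearson_ci
    low, high = ci(successes, n, alpha)
    return MetricResult(
        estimate=successes / n * 100.0,
        ci_low=low,
        ci_high=high,
        n=n,
        successes=successes,
    )


def sensitivity(
    counts: ConfusionCounts, alpha: float = 0.05, ci_method: str = "clopper-pearson"
) -> MetricResult:
    """SN = TP / (TP + FN)."""
    return _proportion(counts.tp, counts.tp + counts.fn, alpha, ci_method)


def specificity(
    counts: ConfusionCounts, alpha: float = 0.05, ci_method: str = "clopper-pearson"
) -> MetricResult:
    """SP = TN / (TN + FP)."""
    return _proportion(counts.tn, counts.tn + counts.fp, alpha, ci_method)


def ppv(
    counts: ConfusionCounts, alpha: float = 0.05, ci_method: str = "clopper-pearson"
) -> MetricResult:
    """PPV = TP / (TP + FP)."""
    return _proportion(counts.tp, counts.tp + counts.fp, alpha, ci_method)


def f_measure(sn: float, ppv_: float) -> float:
    """Harmonic mean of sensitivity and PPV, both given as percentages.

    By convention F = 0 when both inputs are 0 (the harmonic mean's limit).
    """
    if sn < 0 or ppv_ < 0:
        raise ValueError("sensitivity and PPV must be non-negative")
    if sn + ppv_ == 0:
        return 0.0
    return 2.0 * sn * ppv_ / (sn + ppv_)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa over a shared nominal label set.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of marginal label frequencies.  Raises when p_e = 1 (both raters
    constant on the same label), where kappa is undefined.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must be equally long")
    n = len(labels_a)
    if n == 0:
        raise UndefinedMetricError("no observations")
    categories = sorted(set(labels_a) | set(labels_b), key=str)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    p_e = 0.0
    for c in categories:
        p_e += (
            sum(a == c for a in labels_a) / n
        ) * (sum(b == c for b in labels_b) / n)
    if math.isclose(p_e, 1.0):
        raise UndefinedMetricError("expected agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def percent_agreement(annotations_a: Sequence, annotations_b: Sequence) -> float:
    """Inter-annotator agreement: matching decisions / total x 100."""
    if len(annotations_a) != len(annotations_b):
        raise ValueError("annotation vectors must be equally long")
    if not annotations_a:
        raise UndefinedMetricError("no annotations to compare")
    matches = sum(a == b for a, b in zip(annotations_a, annotations_b))
    return matches / len(annotations_a) * 100.0


# --- patient-level evaluation report ---------------------------------------

REPORT_ROWS = [
    ("measure_met", "Measure met"),
    ("lvsf_assessed", "LVSF assessed"),
    ("ef_lt_40", "EF <40%"),
    ("on_acei_arb", "ACEI or ARB"),
    ("rnm_present", "Reason not on medications"),
]


def _row_labels(det: PatientDeterminations) -> dict[str, bool]:
    return {
        "measure_met": det.classification is Classification.MET,
        "lvsf_assessed": det.lvsf_assessed,
        "ef_lt_40": det.ef_lt_40 is True,
        "on_acei_arb": det.on_acei_arb,
        "rnm_present": det.rnm_present,
    }


@dataclass
class EvaluationRow:
    key: str
    label: str
    counts: ConfusionCounts
    sn: Optional[MetricResult]
    sp: Optional[MetricResult]
    ppv: Optional[MetricResult]
    f: Optional[float]

    def to_dict(self) -> dict:
        def mr(r: Optional[MetricResult]):
            return (
                None
                if r is None
                else {
                    "estimate": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n": r.n,
                    "successes": r.successes,
                }
            )

        return {
            "key": self.key,
            "label": self.label,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "sensitivity": mr(self.sn),
            "specificity": mr(self.sp),
            "ppv": mr(self.ppv),
            "f_measure": self.f,
        }


@dataclass
class EvaluationReport:
    rows: list[EvaluationRow]
    n_patients: int
    missing_from_gold: list[str]

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "missing_from_gold": self.missing_from_gold,
            "rows": [r.to_dict() for r in self.rows],
        }

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "classification": r.label,
                    "sensitivity": r.sn.estimate if r.sn else float("nan"),
                    "ppv": r.ppv.estimate if r.ppv else float("nan"),
                    "f_measure": r.f if r.f is not None else float("nan"),
                }
            )
        return pd.DataFrame.from_records(recs)

    def to_text(self) -> str:
        lines = [
            f"Patient-level evaluation (n={self.n_patients})",
            f"{'Classification':<28}{'SN % (95% CI)':<24}{'PPV % (95% CI)':<24}{'F':>6}",
        ]
        for r in self.rows:
            sn = r.sn.display(1) if r.sn else "undefined"
            ppv_ = r.ppv.display(1) if r.ppv else "undefined"
            f = f"{r.f:.1f}" if r.f is not None else "-"
            lines.append(f"{r.label:<28}{sn:<24}{ppv_:<24}{f:>6}")
        if self.missing_from_gold:
            lines.append(
                f"warning: {len(self.missing_from_gold)} predicted patient(s) "
                "missing from gold were excluded"
            )
        return "\n".join(lines)


def evaluate_run(
    predicted: Sequence[PatientDeterminations],
    gold: Sequence[GoldAnnotation] | Sequence[PatientDeterminations],
    alpha: float = 0.05,
) -> EvaluationReport:
    """Compare predicted determinations against gold, row by row.

    Gold may be full gold annotations or bare determinations.  Predicted
    patients absent from gold are listed, excluded, and warned about.
    """
    gold_dets: dict[str, PatientDeterminations] = {}
    for g in gold:
        det = g.determination if isinstance(g, GoldAnnotation) else g
        if det is not None:
            gold_dets[det.patient_id] = det

    missing = [p.patient_id for p in predicted if p.patient_id not in gold_dets]
    if missing:
        log.warning("%d predicted patients missing from gold; excluded", len(missing))
    kept = [p for p in predicted if p.patient_id in gold_dets]

    rows: list[EvaluationRow] = []
    for key, label in REPORT_ROWS:
        pred_vec = [_row_labels(p)[key] for p in kept]
        gold_vec = [_row_labels(gold_dets[p.patient_id])[key] for p in kept]
        counts = confusion_counts(pred_vec, gold_vec, positive=True)

        def safe(fn):
            try:
                return fn(counts, alpha=alpha)
            except UndefinedMetricError:
                return None

        sn = safe(sensitivity)
        sp = safe(specificity)
        ppv_ = safe(ppv)
        f = f_measure(sn.estimate, ppv_.estimate) if sn and ppv_ else None
        rows.append(EvaluationRow(key, label, counts, sn, sp, ppv_, f))
    return EvaluationReport(rows=rows, n_patients=len(kept), missing_from_gold=missing)


def concordance(labels_a: Sequence, labels_b: Sequence) -> dict:
    """Kappa-based concordance between two label vectors (e.g. the pipeline
    output vs. structured pharmacy data), with the cross-tabulation."""
    kappa = cohens_kappa(labels_a, labels_b)
    table = (
        pd.crosstab(
            pd.Series(list(labels_a), name="a"), pd.Series(list(labels_b), name="b")
        )
        .to_dict()
    )
    return {
        "kappa": kappa,
        "percent_agreement": percent_agreement(labels_a, labels_b),
        "n": len(labels_a),
        "crosstab": {str(k): {str(kk): int(vv) for kk, vv in v.items()} for k, v in table.items()},
    }


__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "EvaluationRow",
    "MetricResult",
    "REPORT_ROWS",
    "UndefinedMetricError",
    "clopper_pearson_ci",
    "cohens_kappa",
    "concordance",
    "confusion_counts",
    "evaluate_run",
    "f_measure",
    "percent_agreement",
    "ppv",
    "sensitivity",
    "specificity",
    "wilson_ci",
]
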