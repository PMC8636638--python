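"""Evaluation metrics for count regression: R², RMSE, MAE and totals accounting.

R² is the coefficient of determination ``1 - SS_res / SS_tot`` (with SS_tot
about the label mean), not a squared correlation — for a biased predictor
the two differ, and the coefficient of determination is the one that equals
exactly 0 for the constant mean-label predictor.  Totals accounting compares
the summed predicted count against the summed annotated count, the quantity
an ecological survey ultimately needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MetricReport",
    "compute_metrics",
    "totals_underestimate",
    "export_scatter",
    "read_scatter",
]


@dataclass(frozen=True)
class MetricReport:
    r_squared: float | None  # None when the labels have zero variance
    rmse: float
    mae: float
    n: int
    sum_labels: int
    sum_predictions: float
    totals_percent: float | None  # None when sum_labels is 0

    def as_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "mae": self.mae,
            "n": self.n,
            "sum_labels": self.sum_labels,
            "sum_predictions": self.sum_predictions,
            "totals_percent": self.totals_percent,
        }


def _validate(labels, predictions) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=np.float64).ravel()
    p = np.asarray(predictions, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("labels must be nonempty")
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    if (y < 0).any():
        raise ValueError("labels must be nonnegative counts")
    return y, p


def compute_metrics(
    labels, predictions, round_predictions: bool = False
) -> MetricReport:
    """R², RMSE, MAE and totals for predicted vs annotated counts.

    With ``round_predictions`` the predictions are rounded to the nearest
    integer and clamped at 0 first (a reporting sensitivity option; metrics
    default to the raw continuous predictions).
    """
    y, p = _validate(labels, predictions)
    if round_predictions:
        p = np.maximum(np.rint(p), 0.0)
    resid = p - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    sum_y = int(round(y.sum()))
    sum_p = float(p.sum())
    totals = None if sum_y == 0 else 100.0 * sum_p / sum_y
    return MetricReport(
        r_squared=r2,
        rmse=rmse,
        mae=mae,
        n=int(y.size),
        sum_labels=sum_y,
        sum_predictions=sum_p,
        totals_percent=totals,
    )


def totals_underestimate(report: MetricReport) -> float:
    """Percentage by which the summed prediction falls short of the summed label."""
    if report.sum_labels <= 0:
        raise ValueError("totals underestimate undefined for zero summed labels")
    return 100.0 * (report.sum_labels - report.sum_predictions) / report.sum_labels


def export_scatter(labels, predictions, path) -> Path:
    """Write (label, prediction) pairs for a label-vs-prediction figure.

    The ``reference`` column repeats the label — the y=x identity any perfect
    counter would attain.  The file round-trips losslessly via
    :func:`read_scatter`.
    """
    y, p = _validate(labels, predictions)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "prediction", "reference"])
        for yi, pi in zip(y, p):
            writer.writerow([repr(float(yi)), repr(float(pi)), repr(float(yi))])
    return path


def read_scatter(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    labels = np.array([float(r["label"]) for r in rows])
    preds = np.array([float(r["prediction"]) for r in rows])
    return labels, preds
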