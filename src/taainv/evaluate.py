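"""Evaluation metrics and condition-comparison harness.

The headline metric is the relative L2 error per predicted contributor
field, ``||pred - truth||_2 / ||truth||_2`` per record, aggregated over the
test set as the mean of per-record errors (the pooled-norm aggregate is
also computed and reported for transparency).  Errors can additionally be
restricted to the most-affected region of each lesion (severity template
``theta_star >= 0.5``), which is the part of a prediction a clinician could
plausibly validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MetricError

__all__ = [
    "relative_l2",
    "relative_l2_aggregate",
    "absolute_error_map",
    "filtered_error",
    "EvalReport",
    "compare_conditions",
]


def relative_l2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Per-record relative L2 error over one field."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise MetricError("prediction and truth shapes differ")
    denom = np.linalg.norm(truth.reshape(-1))
    if denom == 0.0:
        raise MetricError("truth field is identically zero")
    return float(np.linalg.norm((pred - truth).reshape(-1)) / denom)


def relative_l2_aggregate(preds: np.ndarray, truths: np.ndarray
                          ) -> tuple[float, float]:
    """Aggregate relative L2 over a batch of records.

    Returns ``(mean_of_records, pooled)`` where the pooled variant divides
    the norm of all stacked errors by the norm of all stacked truths.
    Records with zero-norm truth are excluded from the mean (and counted in
    the pooled norm); if all truths are zero a ``MetricError`` is raised.
    """
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape:
        raise MetricError("prediction and truth shapes differ")
    n = preds.shape[0]
    errs = []
    for i in range(n):
        denom = np.linalg.norm(truths[i].reshape(-1))
        if denom > 0:
            errs.append(np.linalg.norm((preds[i] - truths[i]).reshape(-1))
                        / denom)
    if not errs:
        raise MetricError("all truth fields are identically zero")
    pooled = (np.linalg.norm((preds - truths).reshape(-1))
              / np.linalg.norm(truths.reshape(-1)))
    return float(np.mean(errs)), float(pooled)


def absolute_error_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Signed pointwise error ``pred - truth`` (take ``abs`` on demand)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise MetricError("prediction and truth shapes differ")
    return pred - truth


def filtered_error(pred: np.ndarray, truth: np.ndarray,
                   profile: np.ndarray, threshold: float = 0.5) -> float:
    """Relative L2 restricted to nodes where the severity template is high."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if pred.shape != truth.shape or pred.shape != profile.shape:
        raise MetricError("field shapes differ")
    mask = profile >= threshold
    if not mask.any():
        raise MetricError("severity mask is empty at this threshold")
    return relative_l2(pred[mask], truth[mask])


@dataclass
class EvalReport:
    """Per-condition test-set errors for both contributors."""

    architecture: str
    channels: int
    encoding: str
    e_ce: float  # mean-of-records relative L2, elastic fiber integrity
    e_delta: float  # mean-of-records relative L2, mechanosensing
    e_ce_pooled: float = float("nan")
    e_delta_pooled: float = float("nan")
    e_ce_filtered: float = float("nan")
    e_delta_filtered: float = float("nan")
    per_record_ce: list = field(default_factory=list)
    per_record_delta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.e_ce < 0 or self.e_delta < 0:
            raise MetricError("errors must be non-negative")

    @property
    def condition(self) -> str:
        return f"{self.architecture}/{self.channels}ch/{self.encoding}"


def compare_conditions(reports: list[EvalReport]) -> pd.DataFrame:
    """Tabulate errors, 1-channel/2-channel ratios and the 2-channel ranking.

    Expects, for every (architecture, encoding) cell, reports for both
    channel settings; raises ``MetricError`` listing absent cells.
    """
    by_key = {(r.architecture, r.channels, r.encoding): r for r in reports}
    archs = sorted({r.architecture for r in reports})
    encodings = sorted({r.encoding for r in reports})
    missing = [(a, c, e) for a in archs for c in (1, 2) for e in encodings
               if (a, c, e) not in by_key]
    if missing:
        raise MetricError(f"missing conditions: {missing}")
    rows = []
    for a in archs:
        for e in encodings:
            one, two = by_key[(a, 1, e)], by_key[(a, 2, e)]
            mean1 = 0.5 * (one.e_ce + one.e_delta)
            mean2 = 0.5 * (two.e_ce + two.e_delta)
            rows.append({
                "architecture": a, "encoding": e,
                "e_ce_1ch": one.e_ce, "e_delta_1ch": one.e_delta,
                "e_ce_2ch": two.e_ce, "e_delta_2ch": two.e_delta,
                "e_ce_filtered_2ch": two.e_ce_filtered,
                "e_delta_filtered_2ch": two.e_delta_filtered,
                "ratio_1ch_over_2ch": mean1 / mean2 if mean2 > 0
                else float("inf"),
            })
    df = pd.DataFrame(rows)
    df["rank_2ch"] = (0.5 * (df["e_ce_2ch"] + df["e_delta_2ch"])
                      ).rank(method="min").astype(int)
    return df
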