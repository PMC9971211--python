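"""Potential-DMP selection and learned classification cutoffs.

Per sample and context, sites whose divergence exceeds the fitted
distribution's 95th percentile are *potential* DMPs.  Because controls
are also compared to the reference, control potential DMPs estimate the
background that pure stochasticity produces; an optimal divergence
cutoff separating control from treatment candidates is then learned by a
deterministic sweep over every observed divergence value, maximizing the
Youden index (or accuracy).  Sites above the learned cutoff in a
treatment replicate are that replicate's treatment-associated DMPs;
hypo- and hyper-methylation are treated equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

CRITERIA = ("youden", "accuracy")


@dataclass
class PerformanceMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    fdr: float
    youden: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.accuracy, self.sensitivity, self.specificity,
                self.fdr, self.youden)


@dataclass
class CutoffModel:
    """A learned divergence cutoff for one context, with its metrics."""

    context: str
    cutoff: float
    metric: str
    accuracy: float
    sensitivity: float
    specificity: float
    fdr: float
    youden: float


class ClassBalanceError(ValueError):
    """One of the two label classes is empty; no cutoff can be learned."""


def performance_metrics(labels: Sequence[int], predictions: Sequence[int]) -> PerformanceMetrics:
    """Confusion-matrix metrics for binary labels/predictions.

    FDR is defined as 0 when there are no positive predictions;
    sensitivity as 0 when there are no positive labels.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    if y.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    acc = (tp + tn) / y.size
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    return PerformanceMetrics(acc, sens, spec, fdr, sens + spec - 1.0)


def learn_cutoff(control_values: Sequence[float], treatment_values: Sequence[float],
                 criterion: str = "youden", context: str = "CG") -> CutoffModel:
    """Learn the optimal divergence cutoff separating control from treatment.

    Candidate cutoffs are the sorted unique observed divergences; the
    classification rule is "divergence >= cutoff -> treatment".  The
    cutoff maximizing the criterion is returned, ties broken toward the
    smallest cutoff, with all five performance metrics evaluated there.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    ctl = np.asarray(control_values, dtype=float)
    trt = np.asarray(treatment_values, dtype=float)
    if ctl.size == 0 or trt.size == 0:
        raise ClassBalanceError(
            f"both classes must be non-empty (control n={ctl.size}, treatment n={trt.size})"
        )
    candidates = np.unique(np.concatenate([ctl, trt]))
    ctl_sorted = np.sort(ctl)
    trt_sorted = np.sort(trt)
    # counts >= cutoff via searchsorted on the sorted class arrays
    tp = trt.size - np.searchsorted(trt_sorted, candidates, side="left")
    fp = ctl.size - np.searchsorted(ctl_sorted, candidates, side="left")
    fn = trt.size - tp
    tn = ctl.size - fp
    sens = tp / trt.size
    spec = tn / ctl.size
    youden = sens + spec - 1.0
    accuracy = (tp + tn) / (ctl.size + trt.size)
    score = youden if criterion == "youden" else accuracy
    # smallest cutoff within float tolerance of the maximum score
    best = int(np.flatnonzero(score >= score.max() - 1e-12)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = float(fp[best] / (fp[best] + tp[best])) if (fp[best] + tp[best]) else 0.0
    return CutoffModel(
        context=context, cutoff=float(candidates[best]), metric=criterion,
        accuracy=float(accuracy[best]), sensitivity=float(sens[best]),
        specificity=float(spec[best]), fdr=fdr, youden=float(youden[best]),
    )


def potential_dmps(records: pd.DataFrame, model, prob: float = 0.95,
                   min_tv: float | None = None,
                   divergence_column: str = "hdiv_w") -> pd.DataFrame:
    """Sites of one sample x context whose divergence exceeds the model percentile.

    ``model`` is a fitted divergence model (any object with a
    ``quantile`` method).  When ``min_tv`` is set, candidates must also
    satisfy tv >= min_tv.  Candidates are retained for controls and
    treatments alike — control candidates feed the cutoff learner.
    """
    if not (0.0 < prob < 1.0):
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    threshold = model.quantile(prob)
    keep = records[divergence_column] > threshold
    if min_tv is not None:
        keep &= records["tv"] >= min_tv
    return records.loc[keep].reset_index(drop=True)


def call_dmps(records: pd.DataFrame, cutoff_model: CutoffModel,
              divergence_column: str = "hdiv_w") -> pd.DataFrame:
    """Apply a learned cutoff to one sample's candidate records.

    Returns the records at or above the cutoff with a ``direction``
    column: "hyper" where the sample level exceeds the reference level,
    "hypo" otherwise.  Both directions are retained equally.
    """
    if "context" in records.columns and len(records):
        ctx = records["context"].unique()
        if len(ctx) > 1 or ctx[0] != cutoff_model.context:
            raise ValueError(
                f"records context {list(ctx)} does not match cutoff context "
                f"{cutoff_model.context!r}"
            )
    keep = records[divergence_column] >= cutoff_model.cutoff
    out = records.loc[keep].reset_index(drop=True).copy()
    out["direction"] = np.where(out["p_smp"] >= out["p_ref"], "hyper", "hypo")
    return out
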