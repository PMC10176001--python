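"""Facilitator / depressor / nonresponder classification.

Interindividual variability in corticomotor reorganization is summarized by
labelling each experimental participant, per map metric (volume, area),
against a reference band built from the control group's changes: the mean and
SD of the controls' absolute percent changes define a symmetric band
``±(mean_abs + k * sd_abs)`` (default k = 1).  A signed change above the band
is facilitation, at or below its negative is depression, anything else is a
nonresponse.  Controls are nonresponders by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ControlReference",
    "ResponderLabel",
    "control_reference",
    "classify",
    "classify_cohort",
    "summarize_labels",
    "round_half_away",
]

METRICS = ("volume", "area")
_DELTA_COLS = {"volume": "delta_volume_pct", "area": "delta_area_pct"}


@dataclass(frozen=True)
class ControlReference:
    """Mean and sample SD of control-group absolute percent changes."""

    metric: str
    mean_abs_delta: float
    sd_abs_delta: float
    n_control: int = 0
    band_multiplier: float = 1.0

    @property
    def band(self) -> float:
        """Half-width of the nonresponse band: mean_abs + k * sd_abs."""
        return self.mean_abs_delta + self.band_multiplier * self.sd_abs_delta


@dataclass(frozen=True)
class ResponderLabel:
    participant_id: str
    metric: str
    delta_pct: float
    label: str  # facilitator | depressor | nonresponder


def control_reference(
    control_deltas, metric: str = "volume", band_multiplier: float = 1.0
) -> ControlReference:
    """Reference band from control-group signed percent changes.

    Mean and sample SD (n-1 denominator) are taken over the absolute values;
    at least two controls are required.
    """
    deltas = np.asarray(list(control_deltas), dtype=float)
    if len(deltas) < 2:
        raise ValueError("control reference requires >= 2 control participants")
    if not np.all(np.isfinite(deltas)):
        raise ValueError("control deltas must be finite")
    abs_d = np.abs(deltas)
    return ControlReference(
        metric=metric,
        mean_abs_delta=float(abs_d.mean()),
        sd_abs_delta=float(abs_d.std(ddof=1)),
        n_control=len(deltas),
        band_multiplier=band_multiplier,
    )


def classify(
    delta_pct: float, ref: ControlReference, participant_id: str = ""
) -> ResponderLabel:
    """Label one signed percent change against the control band.

    Facilitator strictly above ``+band``; depressor at or below ``-band``
    (the depression criterion is inclusive); otherwise nonresponder — so an
    exact hit on the facilitation boundary is a nonresponse.
    """
    if not math.isfinite(delta_pct):
        raise ValueError("delta_pct must be finite")
    band = ref.band
    if delta_pct > band:
        label = "facilitator"
    elif delta_pct <= -band:
        label = "depressor"
    else:
        label = "nonresponder"
    return ResponderLabel(
        participant_id=participant_id, metric=ref.metric,
        delta_pct=float(delta_pct), label=label,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def classify_cohort(
    changes: pd.DataFrame,
    refs: dict[str, ControlReference],
    metrics=METRICS,
) -> pd.DataFrame:
    """Label every experimental participant on each map metric.

    ``changes`` must hold one row per participant with columns
    ``participant`` and ``delta_volume_pct`` / ``delta_area_pct``.  Rows with
    a missing delta are flagged ``excluded`` with reason instead of labelled.
    """
    rows = []
    for _, row in changes.iterrows():
        pid = str(row["participant"])
        for metric in metrics:
            col = _DELTA_COLS[metric]
            value = row.get(col, np.nan)
            if value is None or not math.isfinite(float(value)):
                rows.append(
                    {"participant": pid, "metric": metric, "delta_pct": np.nan,
                     "label": "excluded", "reason": f"missing {col}"}
                )
                continue
            lab = classify(float(value), refs[metric], participant_id=pid)
            rows.append(
                {"participant": pid, "metric": metric, "delta_pct": lab.delta_pct,
                 "label": lab.label, "reason": ""}
            )
    return pd.DataFrame(rows, columns=["participant", "metric", "delta_pct", "label", "reason"])


def summarize_labels(labels: pd.DataFrame, refs: dict[str, ControlReference]) -> dict:
    """Counts, integer percentages, and reference bands, per metric.

    Percentages use round-half-away-from-zero, matching the convention of
    reporting 12 of 26 as 46%.
    """
    summary: dict = {}
    for metric, grp in labels[labels["label"] != "excluded"].groupby("metric"):
        n = len(grp)
        counts = grp["label"].value_counts().to_dict()
        entry = {"n": n, "counts": {}, "percent": {}}
        for label in ("facilitator", "depressor", "nonresponder"):
            c = int(counts.get(label, 0))
            entry["counts"][label] = c
            entry["percent"][label] = round_half_away(100.0 * c / n) if n else 0
        ref = refs.get(metric)
        if ref is not None:
            entry["reference"] = {
                "mean_abs_delta_pct": ref.mean_abs_delta,
                "sd_abs_delta_pct": ref.sd_abs_delta,
                "band_pct": ref.band,
                "n_control": ref.n_control,
            }
        summary[metric] = entry
    n_excluded = int((labels["label"] == "excluded").sum())
    if n_excluded:
        summary["excluded"] = n_excluded
    return summary
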