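"""Assay-trace metrics: glucose-curve AUC and mito-stress respiration.

Respiration metrics follow the standard mito-stress conventions on an
oxygen-consumption-rate (OCR) trace partitioned by the injection phases
baseline -> oligomycin -> FCCP -> rotenone/antimycin A:

    non_mito   = min(rot_aa)
    basal      = last(baseline) - non_mito
    atp_linked = last(baseline) - min(oligomycin)
    maximal    = max(fccp) - non_mito
    spare      = maximal - basal
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import OCR_PHASES


def auc_trapezoid(times, values, baseline_subtract: bool = False) -> float:
    """Trapezoidal area under a time series (units x minutes).

    With ``baseline_subtract`` the first value is treated as baseline and
    subtracted before integration (incremental AUC; may be negative).
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if baseline_subtract:
        v = v - v[0]
    return float(np.trapezoid(v, t))


@dataclass(frozen=True)
class RespirationMetrics:
    non_mito: float
    basal: float
    atp_linked: float
    maximal: float
    spare: float


def respiration_metrics(
    trace: pd.DataFrame, protein_content: float = 1.0
) -> RespirationMetrics:
    """Mito-stress respiration metrics from a phase-labelled OCR trace.

    ``trace`` needs columns ``value`` and ``phase``; phases must appear
    contiguously in injection order with at least one measurement each.
    ``protein_content`` optionally normalizes OCR per well (scalar divide).
    """
    if "phase" not in trace.columns or "value" not in trace.columns:
        raise ValueError("trace needs 'value' and 'phase' columns")
    if protein_content <= 0:
        raise ValueError("protein_content must be positive")
    phases = trace["phase"].tolist()
    for ph in OCR_PHASES:
        if ph not in phases:
            raise ValueError(f"missing phase {ph!r} in OCR trace")
    order = [ph for ph, _ in _runs(phases)]
    if order != list(OCR_PHASES):
        raise ValueError(
            f"phases must be contiguous in injection order {OCR_PHASES}, got {order}"
        )
    v = trace["value"].to_numpy(float) / protein_content
    by = {ph: v[[i for i, p in enumerate(phases) if p == ph]] for ph in OCR_PHASES}
    non_mito = float(by["rot_aa"].min())
    basal = float(by["baseline"][-1] - non_mito)
    atp_linked = float(by["baseline"][-1] - by["oligomycin"].min())
    maximal = float(by["fccp"].max() - non_mito)
    return RespirationMetrics(
        non_mito=non_mito,
        basal=basal,
        atp_linked=atp_linked,
        maximal=maximal,
        spare=maximal - basal,
    )


def _runs(labels: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for lab in labels:
        if not out or out[-1][0] != lab:
            out.append((lab, 1))
        else:
            out[-1] = (lab, out[-1][1] + 1)
    return out
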