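"""Per-peptide differential abundance between vehicle and compound.

The test is a two-sided Welch two-sample t on log2 intensities with
Welch-Satterthwaite degrees of freedom, followed by Benjamini-Hochberg
adjustment across all tested peptides in one batch. Peptides are labelled
``up`` / ``down`` only when both the adjusted p-value clears ``alpha`` and
the absolute log2 fold change clears ``lfc_min``; everything else is ``ns``.

Missing replicates are handled pairwise-complete per peptide; a peptide
with fewer than two usable replicates in either condition is excluded from
testing (and logged), never emitted as NaN.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intensities import PeptideIntensityTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 1.0


def normalize_intensities(table: PeptideIntensityTable) -> PeptideIntensityTable:
    """Log2-transform a linear-scale table and median-centre each sample.

    Every sample's median log2 intensity is mapped to the global median
    (the median over all measurements pooled), removing per-sample loading
    differences while preserving the overall intensity scale.
    """
    if table.scale != "linear":
        raise ValueError("normalize_intensities expects a linear-scale table")
    cols = table.all_intensity_columns()
    df = table.df.copy()
    mat = df[cols].to_numpy(float)
    with np.errstate(invalid="ignore"):
        if (mat <= 0).any():
            bad = df.loc[(mat <= 0).any(axis=1), "peptide_id"].tolist()
            raise ValueError(f"non-positive intensities in rows {bad}")
    log = np.log2(mat)
    global_med = np.nanmedian(log)
    sample_med = np.nanmedian(log, axis=0)
    df[cols] = log - sample_med[None, :] + global_med
    return PeptideIntensityTable(df, scale="log2", conditions=table.conditions)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p for the
    difference mean(y) - mean(x).

    Degenerate convention: when both groups have zero variance, p is the
    limit value (0 for unequal means, 1 for equal) and the result is
    flagged degenerate.
    """
    n1, n2 = len(x), len(y)
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    diff = m2 - m1
    se = np.sqrt(v1 + v2)
    if se == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0, True
        return float(np.sign(diff)) * np.inf, float(n1 + n2 - 2), 0.0, True
    t = diff / se
    # scale-invariant Welch-Satterthwaite form (robust to tiny variances)
    w1, w2 = v1 / (v1 + v2), v2 / (v1 + v2)
    df = 1.0 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p), False


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1 and returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_peptides(
    table: PeptideIntensityTable,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Differential abundance for every peptide in a log2-scale table.

    Returns a DataFrame with columns ``peptide_id, sequence, log2fc, t, df,
    p, q, direction, n_vehicle, n_compound, degenerate``. ``log2fc`` is the
    compound-minus-vehicle mean log2 intensity. Peptides with fewer than two
    usable replicates in either condition are dropped with a warning.
    """
    if table.scale != "log2":
        raise ValueError("test_peptides expects a log2-scale table")
    cond_v, cond_c = table.conditions[0], table.conditions[1]
    veh = table.df[table.columns(cond_v)].to_numpy(float)
    cmp_ = table.df[table.columns(cond_c)].to_numpy(float)

    n_v = np.sum(~np.isnan(veh), axis=1)
    n_c = np.sum(~np.isnan(cmp_), axis=1)
    usable = (n_v >= 2) & (n_c >= 2)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "excluding %d peptide(s) with <2 usable replicates in a condition",
            n_dropped,
        )

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # all-NaN rows are legitimate here; they are filtered below
        _warnings.simplefilter("ignore", RuntimeWarning)
        m_v = np.nanmean(veh, axis=1)
        m_c = np.nanmean(cmp_, axis=1)
        v_v = np.nanvar(veh, axis=1, ddof=1) / n_v
        v_c = np.nanvar(cmp_, axis=1, ddof=1) / n_c
        diff = m_c - m_v
        se = np.sqrt(v_v + v_c)
        t = np.where(se > 0, diff / se, np.sign(diff) * np.inf)
        t = np.where((se == 0) & (diff == 0), 0.0, t)
        w_v = v_v / (v_v + v_c)
        w_c = v_c / (v_v + v_c)
        dof = np.where(
            se > 0,
            1.0 / (w_v**2 / (n_v - 1) + w_c**2 / (n_c - 1)),
            n_v + n_c - 2.0,
        )
        p = np.where(
            se > 0,
            2.0 * sps.t.sf(np.abs(t), dof),
            np.where(diff == 0, 1.0, 0.0),
        )
    degenerate = usable & (se == 0)

    out = pd.DataFrame(
        {
            "peptide_id": table.df["peptide_id"],
            "sequence": table.df["sequence"],
            "log2fc": diff,
            "t": t,
            "df": dof,
            "p": p,
            "n_vehicle": n_v,
            "n_compound": n_c,
            "degenerate": degenerate,
        }
    )[usable].reset_index(drop=True)

    out["q"] = bh_adjust(out["p"].to_numpy())
    direction = np.full(len(out), "ns", dtype=object)
    sig = (out["q"].to_numpy() <= alpha) & (np.abs(out["log2fc"].to_numpy()) >= lfc_min)
    direction[sig & (out["log2fc"].to_numpy() > 0)] = "up"
    direction[sig & (out["log2fc"].to_numpy() < 0)] = "down"
    out["direction"] = direction
    return out[
        [
            "peptide_id",
            "sequence",
            "log2fc",
            "t",
            "df",
            "p",
            "q",
            "direction",
            "n_vehicle",
            "n_compound",
            "degenerate",
        ]
    ]
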