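"""Test-retest reliability of DVs and attenuation correction of model fit.

Reliability bounds the variance any model can explain: a DV that does not
correlate with itself across sessions carries irreducible noise, and the
communality a factor model achieves for it must be judged against that
noise ceiling. Two per-DV statistics are computed from a two-session retest
(Pearson r across sessions; ICC(3,k), the two-way mixed-model consistency
ICC for k = 2 averaged sessions), and communalities are attenuation-corrected
by dividing by the squared retest correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import BatteryError, RetestPair


@dataclass
class ReliabilityTable:
    """Per-DV retest reliability (one row per DV present in both sessions)."""

    table: pd.DataFrame  # index dv_name; columns pearson_r, icc3k, n_retest

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "dv_name"
        out.to_csv(path)


def _session_arrays(pair: RetestPair) -> tuple[np.ndarray, np.ndarray]:
    a, b = pair.aligned_values()
    if a.shape[0] < 3:
        raise BatteryError("need at least 3 retest participants")
    return a, b


def retest_pearson(pair: RetestPair) -> ReliabilityTable:
    """Per-DV Pearson correlation between the two sessions.

    A constant column in either session makes r undefined; it is reported as
    NaN with a ``degenerate`` flag rather than silently dropped.
    """
    a, b = _session_arrays(pair)
    n = a.shape[0]
    sa = a.std(axis=0, ddof=1)
    sb = b.std(axis=0, ddof=1)
    degenerate = ~((sa > 0) & (sb > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        az = a - a.mean(axis=0)
        bz = b - b.mean(axis=0)
        r = (az * bz).sum(axis=0) / ((n - 1) * sa * sb)
    r = np.where(degenerate, np.nan, r)
    tab = pd.DataFrame(
        {
            "pearson_r": r,
            "icc3k": np.nan,
            "n_retest": n,
            "degenerate": degenerate,
        },
        index=pair.t1.dv_names,
    )
    return ReliabilityTable(tab)


def icc3k(pair: RetestPair) -> ReliabilityTable:
    """ICC(3,k): two-way mixed, consistency, average of k = 2 sessions.

    ICC(3,k) = (MS_rows - MS_error) / MS_rows from the participants x
    sessions ANOVA. Can be negative for anti-reliable DVs; reported as
    computed.
    """
    a, b = _session_arrays(pair)
    n = a.shape[0]
    k = 2
    vals = np.stack([a, b], axis=2)  # n x m x k
    grand = vals.mean(axis=(0, 2))
    row_mean = vals.mean(axis=2)  # n x m
    col_mean = vals.mean(axis=0)  # m x k
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand[:, None]) ** 2).sum(axis=1)
    ss_tot = ((vals - grand[None, :, None]) ** 2).sum(axis=(0, 2))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (ms_rows - ms_err) / ms_rows
    degenerate = ~(ms_rows > 0)
    icc = np.where(degenerate, np.nan, icc)
    tab = pd.DataFrame(
        {
            "pearson_r": np.nan,
            "icc3k": icc,
            "n_retest": n,
            "degenerate": degenerate,
        },
        index=pair.t1.dv_names,
    )
    return ReliabilityTable(tab)


def reliability_table(pair: RetestPair) -> ReliabilityTable:
    """Both reliability statistics in one table."""
    r = retest_pearson(pair).table
    i = icc3k(pair).table
    r["icc3k"] = i["icc3k"]
    r["degenerate"] = r["degenerate"] | i["degenerate"]
    return ReliabilityTable(r)


def attenuation_correct(h2: float | np.ndarray, r: float | np.ndarray):
    """Adjusted variance explained: communality divided by squared retest r.

    Only defined for positive reliability. Raw values may exceed 1 (the
    correction is unbounded); callers aggregating across DVs should clip
    (see ``communality_reliability_corr``).
    """
    h2 = np.asarray(h2, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise BatteryError("attenuation correction undefined for r <= 0")
    adj = h2 / r**2
    return adj if adj.ndim else float(adj)


def communality_reliability_corr(
    communalities: pd.Series,
    reliab: ReliabilityTable,
    r_min: float = 0.2,
) -> dict:
    """Relate model communality to retest reliability across DVs.

    Keeps DVs with retest r > ``r_min``, then reports the Pearson
    correlation between communality and reliability over the survivors,
    the mean adjusted (attenuation-corrected) variance explained — clipped
    at 1 per DV for the aggregate, raw per-DV values alongside — and the
    unadjusted mean communality.
    """
    r = reliab.table["pearson_r"].reindex(communalities.index)
    keep = r > r_min
    if keep.sum() < 3:
        raise BatteryError(
            f"fewer than 3 DVs with retest r > {r_min}; cannot correlate"
        )
    h2 = communalities[keep].to_numpy(dtype=float)
    rr = r[keep].to_numpy(dtype=float)
    corr = float(np.corrcoef(h2, rr)[0, 1])
    adj_raw = h2 / rr**2
    adj_clipped = np.minimum(adj_raw, 1.0)
    per_dv = pd.DataFrame(
        {
            "communality": h2,
            "retest_r": rr,
            "adjusted_raw": adj_raw,
            "adjusted_clipped": adj_clipped,
            "clipped_flag": adj_raw > 1.0,
        },
        index=communalities.index[keep],
    )
    return {
        "correlation": corr,
        "mean_communality": float(h2.mean()),
        "mean_adjusted": float(adj_clipped.mean()),
        "n_kept": int(keep.sum()),
        "per_dv": per_dv,
    }
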