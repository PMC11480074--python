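"""Surrogate evaluation: RMSE per output group, pooled regression
summaries, and moment-error statistics.

All RMSE and regression metrics operate in the transformed target space
(the space the training loss is defined in).  The output groups follow the
network head: group ``"zmax"`` is the single z_max output, group
``"spectral"`` pools the 20 density outputs.  Moment errors compare
midpoint-rule moments of predicted spectra against the paired Monte Carlo
spectra, as per-record percent differences summarised by mean, standard
deviation and a percentile-based 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from alphamicro.spectra import SingleEventSpectrum, moments_from_spectrum

__all__ = [
    "RegressionSummary",
    "rmse",
    "regression_summary",
    "moment_error_table",
    "metrics_report",
]

_GROUPS = {"zmax": np.s_[:, :1], "spectral": np.s_[:, 1:], "all": np.s_[:, :]}


def _group_values(arr: np.ndarray, group: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    try:
        return arr[_GROUPS[group]]
    except KeyError:
        raise ValueError(f"unknown output group {group!r}") from None


def rmse(predictions, targets, group: str = "all") -> float:
    """Root-mean-square residual over an output group."""
    p = _group_values(predictions, group)
    t = _group_values(targets, group)
    if p.size == 0:
        raise ValueError("empty partition")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of predicted on actual values, pooled over a group."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    partition: str = ""
    group: str = "all"


def regression_summary(predictions, targets, partition: str = "",
                       group: str = "all") -> RegressionSummary:
    """Least-squares regression of predicted (y) on actual (x) values.

    R^2 is the squared Pearson correlation, which for a univariate OLS fit
    with intercept equals the coefficient of determination.
    """
    y = _group_values(predictions, group).ravel()
    x = _group_values(targets, group).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance targets")
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return RegressionSummary(slope=float(slope), intercept=float(intercept),
                             r_squared=float(r**2), n=int(x.size),
                             partition=partition, group=group)


def moment_error_table(predicted_spectra: list[SingleEventSpectrum],
                       mc_spectra: list[SingleEventSpectrum],
                       partitions) -> pd.DataFrame:
    """Percent-error statistics of <z1> and <z1^2> per partition.

    Both moment sets use the midpoint rule on the 20-bin densities so that
    the comparison probes the surrogate, not the binning.  Rows: one per
    (partition, moment); columns: mean, sd, percentile 95% interval, n.
    Records with a zero MC moment are excluded.
    """
    parts = np.asarray(partitions)
    if not (len(predicted_spectra) == len(mc_spectra) == parts.size):
        raise ValueError("spectra lists and partitions must align")
    errs = {"z1_mean": [], "z1_sq": []}
    for pred, mc in zip(predicted_spectra, mc_spectra):
        mp, mm = moments_from_spectrum(pred), moments_from_spectrum(mc)
        errs["z1_mean"].append(
            100.0 * (mp.z1_mean - mm.z1_mean) / mm.z1_mean if mm.z1_mean else np.nan
        )
        errs["z1_sq"].append(
            100.0 * (mp.z1_sq - mm.z1_sq) / mm.z1_sq if mm.z1_sq else np.nan
        )
    rows = []
    for part in ("train", "val", "test"):
        mask = parts == part
        if not mask.any():
            continue
        for moment in ("z1_mean", "z1_sq"):
            e = np.asarray(errs[moment])[mask]
            e = e[np.isfinite(e)]
            rows.append({
                "partition": part,
                "moment": moment,
                "mean_pct": float(np.mean(e)) if e.size else np.nan,
                "sd_pct": float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
                "ci_lo_pct": float(np.percentile(e, 2.5)),
                "ci_hi_pct": float(np.percentile(e, 97.5)),
                "n": int(e.size),
            })
    return pd.DataFrame(rows)


def metrics_report(predictions: np.ndarray, targets: np.ndarray,
                   partitions) -> pd.DataFrame:
    """RMSE and pooled regression per partition and output group."""
    parts = np.asarray(partitions)
    rows = []
    for part in ("train", "val", "test"):
        mask = parts == part
        if not mask.any():
            continue
        for group in ("zmax", "spectral"):
            reg = regression_summary(predictions[mask], targets[mask],
                                     partition=part, group=group)
            rows.append({
                "partition": part,
                "group": group,
                "rmse": rmse(predictions[mask], targets[mask], group),
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "n": reg.n,
            })
    return pd.DataFrame(rows)
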