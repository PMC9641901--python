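"""Post-processing summaries and validation helpers.

Pure functions of a :class:`~aedespop.simulation.SimulationResult`:

* :func:`psi` — proportion of iterations with a viable population at a
  date (the establishment-probability estimate); a population is viable
  when its total count across all stages (and cells, unless per-cell) is
  positive;
* :func:`adci` — per-day abundance quantiles across iterations for each
  life stage (inter-quartile range by default);
* :func:`icci` — per-day quantiles of the invaded (occupied) cell count;
* :func:`dici` — invaded area in km² (local scale);
* :func:`establishment_map` — per-cell psi plus a binary classification at
  a configurable threshold (default 1%);
* :func:`validate_ranking` — rank-based ROC AUC (ties get half credit)
  with a DeLong normal-approximation confidence interval, sensitivity /
  specificity at an operating threshold, and the >= 1% establishment
  sensitivity metric;
* :func:`compare_series` — Spearman rank correlation between aggregated
  simulated series and periodic field observations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .dispersal import dispersed_area_km2
from .errors import ConfigurationError
from .simulation import SimulationResult

__all__ = [
    "psi",
    "adci",
    "icci",
    "dici",
    "establishment_map",
    "validate_ranking",
    "compare_series",
    "extract_eggs_laid",
    "extract_host_seeking",
]

DEFAULT_QUANTILES = (0.25, 0.5, 0.75)


def psi(result: SimulationResult, date, per_cell: bool = False):
    """Proportion of iterations with a viable population at ``date``.

    Viable means total count > 0 across all stages (and across cells,
    unless ``per_cell``).  Returns a float, or a per-cell ``pandas.Series``
    indexed by cell id.
    """
    d = result.day_index(date)
    day = result.counts[:, d]  # (iterations, cells, stages)
    if per_cell:
        viable = (day.sum(axis=2) > 0).mean(axis=0)
        return pd.Series(viable, index=result.cell_ids, name="psi")
    return float((day.sum(axis=(1, 2)) > 0).mean())


def adci(
    result: SimulationResult,
    quantiles=DEFAULT_QUANTILES,
    stage: str | None = None,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Per-day abundance quantiles across iterations for each life stage."""
    if result.n_iterations == 0 or result.counts.size == 0:
        raise ValueError("empty simulation result")
    q = np.asarray(quantiles, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    stages = [stage] if stage else list(result.stage_names)
    frames = []
    for s in stages:
        si = result.stage_names.index(s)
        if per_cell:
            arr = result.counts[:, :, :, si]  # (it, days, cells)
            qs = np.quantile(arr, q, axis=0)  # (q, days, cells)
            for ci, cid in enumerate(result.cell_ids):
                df = pd.DataFrame(
                    qs[:, :, ci].T, index=result.dates,
                    columns=[f"q{int(round(x * 100))}" for x in q],
                )
                df.insert(0, "stage", s)
                df.insert(1, "cell", cid)
                frames.append(df)
        else:
            arr = result.counts[:, :, :, si].sum(axis=2)  # (it, days)
            qs = np.quantile(arr, q, axis=0)
            df = pd.DataFrame(
                qs.T, index=result.dates,
                columns=[f"q{int(round(x * 100))}" for x in q],
            )
            df.insert(0, "stage", s)
            frames.append(df)
    out = pd.concat(frames)
    out.index.name = "date"
    return out


def icci(result: SimulationResult, quantiles=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Per-day quantiles (across iterations) of the invaded-cell count."""
    if not result.is_spatial:
        raise ConfigurationError("icci requires a spatial (lc/rg) result")
    occupied = (result.counts.sum(axis=3) > 0).sum(axis=2)  # (it, days)
    q = np.asarray(quantiles, dtype=float)
    qs = np.quantile(occupied, q, axis=0)
    out = pd.DataFrame(
        qs.T, index=result.dates,
        columns=[f"q{int(round(x * 100))}" for x in q],
    )
    out.index.name = "date"
    return out


def dici(result: SimulationResult, quantiles=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Per-day quantiles of the invaded area (km²); local scale only."""
    if result.config.scale != "lc":
        raise ConfigurationError(
            "dici is defined only for local-scale (lc) results, the only "
            "scale with dispersal"
        )
    occupied = (result.counts.sum(axis=3) > 0).sum(axis=2)
    areas = dispersed_area_km2(occupied, result.config.cellsize)
    q = np.asarray(quantiles, dtype=float)
    qs = np.quantile(areas, q, axis=0)
    out = pd.DataFrame(
        qs.T, index=result.dates,
        columns=[f"q{int(round(x * 100))}" for x in q],
    )
    out.index.name = "date"
    return out


def establishment_map(
    result: SimulationResult, date=None, threshold: float = 0.01
) -> pd.DataFrame:
    """Per-cell establishment probability with a binary classification.

    ``psi`` per cell at ``date`` (default: last simulated day) and a
    ``positive`` flag at the given threshold (default 1%: at least one
    viable iteration in 100).
    """
    if not result.is_spatial:
        raise ConfigurationError("establishment map requires a spatial result")
    if date is None:
        date = result.dates[-1]
    per_cell = psi(result, date, per_cell=True)
    return pd.DataFrame(
        {"psi": per_cell, "positive": per_cell >= threshold}
    ).rename_axis("cell")


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the empirical AUC (placement values)."""
    # V10: placement of each positive among negatives; V01: vice versa
    v10 = np.array([
        ((p > neg).sum() + 0.5 * (p == neg).sum()) / neg.size for p in pos
    ])
    v01 = np.array([
        ((pos > n).sum() + 0.5 * (pos == n).sum()) / pos.size for n in neg
    ])
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return s10 / pos.size + s01 / neg.size


def validate_ranking(
    predicted,
    labels,
    operating_threshold: float = 0.01,
    ci_level: float = 0.95,
) -> dict:
    """ROC validation of per-unit establishment scores against presence labels.

    AUC is the probability that a randomly chosen positive unit scores
    higher than a randomly chosen negative one (ties half credit),
    computed from ranks.  The confidence interval is the DeLong normal
    approximation, clipped to [0, 1].  Sensitivity/specificity are taken
    at ``operating_threshold``; ``sensitivity_at_1pct`` is the fraction of
    positive units with predicted establishment probability >= 1%.
    """
    scores = np.asarray(predicted, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("predicted and labels must have the same length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative unit")
    ranks = stats.rankdata(scores)  # average ranks: ties get half credit
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    var = _delong_variance(scores[y], scores[~y], auc)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(var)
    sens = float((scores[y] >= operating_threshold).mean())
    spec = float((scores[~y] < operating_threshold).mean())
    return {
        "auc": float(auc),
        "auc_ci": (max(0.0, auc - half), min(1.0, auc + half)),
        "ci_method": "delong-normal",
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_at_1pct": float((scores[y] >= 0.01).mean()),
        "n_positive": n_pos,
        "n_negative": n_neg,
    }


def compare_series(
    simulated: pd.Series,
    observed: pd.Series,
    aggregation: str = "weekly",
    catch_rate: float = 1.0,
) -> dict:
    """Spearman rank correlation between simulated and observed series.

    The daily simulated series is scaled by ``catch_rate`` (e.g. a trap
    catching rate) and summed per period (week or month); observations are
    averaged per period; the correlation uses periods present in both.
    Also returns the max-ratio rescaling factor used for overlay plots.
    """
    freq = {"weekly": "W", "monthly": "MS"}.get(aggregation)
    if freq is None:
        raise ValueError("aggregation must be 'weekly' or 'monthly'")
    sim = (simulated.astype(float) * catch_rate).resample(freq).sum()
    obs = observed.astype(float).resample(freq).mean()
    paired = pd.concat([sim, obs], axis=1, join="inner", keys=["sim", "obs"]).dropna()
    if len(paired) < 3:
        raise ValueError(
            f"insufficient overlap after {aggregation} aggregation: "
            f"{len(paired)} paired periods (need >= 3)"
        )
    rho, pval = stats.spearmanr(paired["sim"], paired["obs"])
    sim_max = float(paired["sim"].max())
    rescale = float(paired["obs"].max()) / sim_max if sim_max > 0 else float("nan")
    return {
        "rho": float(rho),
        "p_value": float(pval),
        "n_periods": int(len(paired)),
        "aggregation": aggregation,
        "catch_rate": catch_rate,
        "plot_rescale_ratio": rescale,
    }


def extract_eggs_laid(result: SimulationResult, iteration=None) -> pd.Series | pd.DataFrame:
    """Daily newly-laid eggs summed over cells (median across iterations
    unless a specific iteration is requested)."""
    total = result.eggs_laid.sum(axis=2)  # (it, days)
    if iteration is not None:
        return pd.Series(total[iteration], index=result.dates, name="eggs_laid")
    return pd.Series(
        np.median(total, axis=0), index=result.dates, name="eggs_laid_median"
    )


def extract_host_seeking(result: SimulationResult, iteration=None):
    """Daily gonotrophically competent (host-seeking) females over cells."""
    total = result.host_seeking.sum(axis=2)
    if iteration is not None:
        return pd.Series(total[iteration], index=result.dates, name="host_seeking")
    return pd.Series(
        np.median(total, axis=0), index=result.dates, name="host_seeking_median"
    )
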