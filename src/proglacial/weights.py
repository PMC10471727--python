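"""Hierarchical downweighting and weighted agreement statistics.

Unequal sampling across regions, glaciers (or station clusters) and snow-cover
conditions can inflate naive agreement scores.  Observations are therefore
downweighted so that each region's observations sum to 1, each group (glacier
or cluster) within a region sums to 1/G, and each snow-free-day-frequency
category within a group sums to 1/(G*M), with G the groups in the region and M
the non-empty sfd categories of that group.  Agreement between observed and
predicted values is then summarized by the coefficient of determination of a
weighted linear regression (wR2), the weighted mean absolute error (wMAE) and
the weighted root-mean-square error (wRMSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Decile edges classifying sfd (0-100%) into 10 categories.
SFD_CATEGORY_EDGES = tuple(np.arange(10.0, 100.0, 10.0))


@dataclass
class WeightScheme:
    weights: np.ndarray  # one positive weight per observation
    region: np.ndarray
    group: np.ndarray
    category: np.ndarray


@dataclass
class AgreementStats:
    wr2: float
    wmae: float
    wrmse: float


def sfd_category(sfd: np.ndarray) -> np.ndarray:
    """Classify sfd (%) into 10 decile intervals of [0, 100]."""
    return np.digitize(np.asarray(sfd, dtype=float), SFD_CATEGORY_EDGES)


def build_weights(region, group, sfd=None, category=None) -> WeightScheme:
    """Per-observation weights 1 / (G_region * M_group * n_cell).

    Either raw ``sfd`` values (classified into deciles) or precomputed
    ``category`` labels must be given.  Empty categories carry no mass: M
    counts only the non-empty sfd categories of each group.
    """
    region = np.asarray(region)
    group = np.asarray(group)
    if category is None:
        if sfd is None:
            raise ValueError("either sfd values or category labels are required")
        category = sfd_category(sfd)
    category = np.asarray(category)
    for name, arr in (("region", region), ("group", group), ("category", category)):
        bad = pd.isna(arr)
        if bad.any():
            raise ValueError(f"observation {int(np.flatnonzero(bad)[0])} has missing {name} label")
    df = pd.DataFrame({"region": region, "group": group, "category": category})
    g_per_region = df.groupby("region")["group"].transform("nunique")
    m_per_group = df.groupby(["region", "group"])["category"].transform("nunique")
    n_per_cell = df.groupby(["region", "group", "category"])["category"].transform("size")
    weights = 1.0 / (g_per_region * m_per_group * n_per_cell)
    return WeightScheme(
        weights=weights.to_numpy(), region=region, group=group, category=category
    )


def weighted_stats(observed, predicted, weights) -> AgreementStats:
    """wR2 (weighted regression of observed on predicted), wMAE and wRMSE."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(observed) == len(predicted) == len(weights)):
        raise ValueError("observed, predicted and weights must have equal length")
    if len(observed) < 3:
        raise ValueError("need at least 3 observations")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    err = observed - predicted
    wsum = weights.sum()
    wmae = float(np.sum(weights * np.abs(err)) / wsum)
    wrmse = float(np.sqrt(np.sum(weights * err**2) / wsum))
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        wr2 = float("nan")  # regression with a constant side is undefined
    else:
        fit = sm.WLS(observed, sm.add_constant(predicted), weights=weights).fit()
        wr2 = float(fit.rsquared)
    return AgreementStats(wr2=wr2, wmae=wmae, wrmse=wrmse)
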