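"""Stability and genotype-x-environment interaction statistics.

Two complementary views of consistency across a multi-environment trial:

* the coefficient of variation (CV, %) of replicate plots within each
  genotype-location-year group — within-group consistency;
* Wricke's ecovalence W_i — each entry's contribution to the two-way
  genotype-x-environment interaction sum of squares,

      W_i = sum_j (x_ij - xbar_i. - xbar_.j + xbar_..)^2 ,

  the squared residuals of the double-centered cell-means table.  Smaller
  W_i means the entry deviates less from additivity, i.e. is more stable.
  Summed over entries, W_i recovers the interaction SS exactly.

The entry/environment axes of the ecovalence table are configurable; the
default reproduces the genotype-year x location layout of the source
trial's stability panels, with genotype x (location-year) as the common
alternative.  Ecovalence is computed on cell means (it is defined on the
two-way means table), never on plot values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

__all__ = [
    "cv_percent",
    "cv_by_group",
    "gxe_table",
    "wricke_ecovalence",
    "interaction_series",
    "stability_result",
    "StabilityResult",
]

logger = logging.getLogger(__name__)

DEFAULT_ENTRY_AXIS = ("genotype", "year")
DEFAULT_ENV_AXIS = ("location",)
DEFAULT_CV_GROUPS = ("genotype", "location", "year")


def cv_percent(values) -> float:
    """Coefficient of variation, percent: 100 * sample sd / mean.

    Requires n >= 2; a zero mean makes the ratio undefined and returns NaN
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("CV needs >= 2 values")
    if np.any(~np.isfinite(v)):
        raise ValidationError("CV input contains non-finite values")
    if v.max() == v.min():  # exactly constant; avoids eps-level sd from summation
        return 0.0
    mean = v.mean()
    if mean == 0:
        logger.warning("zero mean; CV undefined, returning NaN")
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def cv_by_group(
    df: pd.DataFrame, trait: str, by: tuple[str, ...] = DEFAULT_CV_GROUPS
) -> pd.Series:
    """Replicate CV per factor group (default genotype-location-year)."""
    if trait not in df.columns:
        raise ValidationError(f"trait {trait!r} not in table")
    return df.groupby(list(by), observed=True)[trait].apply(cv_percent).rename("cv")


def gxe_table(
    df: pd.DataFrame,
    trait: str,
    entry_axis: tuple[str, ...] = DEFAULT_ENTRY_AXIS,
    env_axis: tuple[str, ...] = DEFAULT_ENV_AXIS,
) -> pd.DataFrame:
    """Complete entries x environments table of cell means.

    Composite axes (e.g. genotype-year entries) are labelled by joining
    their levels with '-'.
    """
    for ax in (*entry_axis, *env_axis):
        if ax not in df.columns:
            raise ValidationError(f"axis column {ax!r} not in table")
    means = df.groupby([*entry_axis, *env_axis], observed=True)[trait].mean().reset_index()
    means["_entry"] = means[list(entry_axis)].astype(str).agg("-".join, axis=1)
    means["_env"] = means[list(env_axis)].astype(str).agg("-".join, axis=1)
    table = means.pivot(index="_entry", columns="_env", values=trait)
    table.index.name = "entry"
    table.columns.name = "environment"
    _validate_gxe(table)
    return table


def _validate_gxe(table: pd.DataFrame) -> None:
    if table.isna().any().any():
        raise DesignError("incomplete entries x environments table (missing cells)")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DesignError(f"need >= 2 entries and >= 2 environments, got {table.shape}")


def wricke_ecovalence(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Ecovalence W_i and its share of the interaction SS, per entry.

    Returns ``(wi, wi_share)``; ``wi.sum()`` equals the two-way interaction
    SS of the table, and the shares sum to 1 whenever that SS is positive
    (all-NaN shares otherwise).
    """
    _validate_gxe(table)
    x = table.to_numpy(dtype=float)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    wi = pd.Series((resid ** 2).sum(axis=1), index=table.index, name="wi")
    total = wi.sum()
    # an additive table has zero interaction; centering leaves only rounding
    # noise there, so shares below the floating floor are meaningless
    if total <= 1e-20 * max(1.0, float((x ** 2).sum())):
        wi[:] = 0.0
        total = 0.0
    if total > 0:
        share = (wi / total).rename("wi_share")
    else:
        share = pd.Series(np.nan, index=table.index, name="wi_share")
    return wi, share


def interaction_series(
    df: pd.DataFrame,
    trait: str,
    entry_axis: tuple[str, ...] = ("genotype",),
    env_axis: tuple[str, ...] = ("location", "year"),
    env_order: list[str] | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Per-entry mean trajectories across an ordered environment axis.

    Returns a tidy frame (entry, environment, mean) plus a flag that is True
    when any two entry series cross between consecutive environments — the
    signature of qualitative (rank-changing) genotype-x-environment
    interaction.
    """
    table = gxe_table(df, trait, entry_axis, env_axis)
    if env_order is not None:
        unknown = [e for e in env_order if e not in table.columns]
        if unknown:
            raise ValidationError(f"unknown environment label(s) {unknown}")
        table = table[env_order]
    crossing = False
    x = table.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(x.shape[0]), 2):
        d = x[i] - x[j]
        if np.any(d[:-1] * d[1:] < 0):
            crossing = True
            break
    tidy = (
        table.reset_index()
        .melt(id_vars="entry", var_name="environment", value_name="mean")
        .sort_values(["entry", "environment"], kind="stable")
        .reset_index(drop=True)
    )
    return tidy, crossing


@dataclass
class StabilityResult:
    """CV per replicate group and ecovalence per entry for one trait."""

    trait: str
    cv_by_group: pd.Series
    wi_by_entry: pd.Series
    wi_share: pd.Series

    @property
    def interaction_ss(self) -> float:
        return float(self.wi_by_entry.sum())


def stability_result(
    df: pd.DataFrame,
    trait: str,
    entry_axis: tuple[str, ...] = DEFAULT_ENTRY_AXIS,
    env_axis: tuple[str, ...] = DEFAULT_ENV_AXIS,
    cv_groups: tuple[str, ...] = DEFAULT_CV_GROUPS,
) -> StabilityResult:
    """Bundle CV and ecovalence for one trait under the given axes."""
    wi, share = wricke_ecovalence(gxe_table(df, trait, entry_axis, env_axis))
    return StabilityResult(
        trait=trait,
        cv_by_group=cv_by_group(df, trait, cv_groups),
        wi_by_entry=wi,
        wi_share=share,
    )
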