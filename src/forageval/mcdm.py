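"""Multi-criteria ranking of trial treatments: entropy + AHP weighted TOPSIS.

The comprehensive evaluation scores every genotype-location-year treatment
on a decision matrix of yield, quality and stability criteria:

* **Entropy weights** (objective): criteria that discriminate more between
  alternatives carry more information and receive more weight.  With
  direction-aligned, min-max scaled values x', the column distribution
  p_ij = x'_ij / sum_i x'_ij has entropy e_j = -(1/ln m) sum_i p_ij ln p_ij
  (0 ln 0 := 0); weights are proportional to the divergence d_j = 1 - e_j.
* **AHP weights** (expert): a positive reciprocal pairwise-judgment matrix
  on the Saaty 1-9 scale is reduced to its normalized principal eigenvector
  (power iteration); consistency is checked via CR = CI / RI(n) with
  CI = (lambda_max - n)/(n - 1), accepted when CR < 0.1.
* **Combination**: the default hierarchical scheme lets AHP allocate weight
  across the yield / quality / stability criterion *groups* (the level at
  which the expert judgments exist) and entropy allocate within each group;
  a multiplicative scheme (w_j proportional to entropy_j * expert_j) is
  available when per-criterion expert weights are given.
* **TOPSIS**: alternatives are ranked by relative closeness
  c = d^- / (d^+ + d^-) to the ideal solution, using vector-normalized
  weighted values and Euclidean distances; benefit criteria are maximized
  at the ideal, cost criteria (fiber fractions, CV, ecovalence) minimized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stability as _stab
from .errors import ConfigError, ValidationError

__all__ = [
    "Criterion",
    "DecisionMatrix",
    "AhpResult",
    "entropy_weights",
    "pairwise_from_judgments",
    "ahp_weights",
    "combine_weights",
    "topsis_rank",
    "build_decision_matrix",
    "default_criteria",
    "SAATY_RI",
]

logger = logging.getLogger(__name__)

#: Saaty's random consistency index, n = 1..9.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

CRITERION_GROUPS = ("yield", "quality", "stability")


@dataclass(frozen=True)
class Criterion:
    """One decision criterion: a trait (or stability statistic) with its
    optimization direction and hierarchy group."""

    name: str
    direction: str  # "benefit" or "cost"
    group: str      # "yield", "quality" or "stability"

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise ConfigError(f"criterion {self.name!r}: bad direction {self.direction!r}")
        if self.group not in CRITERION_GROUPS:
            raise ConfigError(
                f"criterion {self.name!r}: group must be one of {CRITERION_GROUPS}"
            )


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values plus per-criterion metadata."""

    values: pd.DataFrame                  # index = alternatives, columns = criteria
    directions: dict[str, str]            # criterion -> benefit/cost
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2:
            raise ValidationError("need >= 2 alternatives")
        if self.values.shape[1] < 1:
            raise ValidationError("need >= 1 criterion")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValidationError("decision matrix contains non-finite values")
        missing = [c for c in self.values.columns if c not in self.directions]
        if missing:
            raise ValidationError(f"criteria missing a benefit/cost direction: {missing}")

    def drop_constant_columns(self) -> "DecisionMatrix":
        """Remove criteria that take a single value across all alternatives.

        A constant criterion cannot discriminate (its entropy weight is 0)
        and an all-zero one has no TOPSIS vector norm, so degenerate runs
        (e.g. noiseless data where CV and ecovalence vanish) drop them with
        a warning instead of failing.
        """
        x = self.values.astype(float)
        span = x.max() - x.min()
        tol = 1e-9 * np.maximum(1.0, x.abs().max())  # near-constant = rounding noise
        keep = [c for c in x.columns if span[c] > tol[c]]
        dropped = [c for c in self.values.columns if c not in keep]
        if dropped:
            logger.warning("dropping constant criterion column(s): %s", dropped)
        if not keep:
            raise ValidationError("all criterion columns are constant")
        return DecisionMatrix(
            values=self.values[keep].copy(),
            directions={c: self.directions[c] for c in keep},
            groups={c: g for c, g in self.groups.items() if c in keep},
        )


def _align_directions(m: DecisionMatrix) -> pd.DataFrame:
    """Min-max scale each column to [0, 1] with cost criteria inverted.

    Constant columns map to all-ones (they then carry zero entropy weight
    rather than a division error).
    """
    x = m.values.astype(float)
    out = {}
    for c in x.columns:
        col = x[c].to_numpy()
        lo, hi = col.min(), col.max()
        if hi == lo:
            out[c] = np.ones_like(col)
        elif m.directions[c] == "benefit":
            out[c] = (col - lo) / (hi - lo)
        else:
            out[c] = (hi - col) / (hi - lo)
    return pd.DataFrame(out, index=x.index)


def entropy_weights(m: DecisionMatrix) -> pd.Series:
    """Objective criterion weights from Shannon entropy of the aligned matrix.

    Constant criteria get weight 0.  If every criterion is constant the
    weights fall back to uniform with a warning (no information anywhere).
    """
    aligned = _align_directions(m)
    n_alt = aligned.shape[0]
    col_sum = aligned.sum(axis=0)
    if np.any(col_sum.to_numpy() == 0):
        bad = list(col_sum.index[col_sum == 0])
        raise ValidationError(f"criterion column(s) sum to zero after alignment: {bad}")
    p = aligned / col_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n_alt)
    d = 1.0 - e
    d = pd.Series(np.clip(d, 0.0, None), index=aligned.columns)
    const = (aligned.max(axis=0) - aligned.min(axis=0)) == 0
    d[const] = 0.0  # constant column: zero divergence exactly, not 1 ulp off
    if d.sum() == 0:
        logger.warning("all criteria constant; falling back to uniform entropy weights")
        return pd.Series(1.0 / len(d), index=d.index, name="weight")
    return (d / d.sum()).rename("weight")


def pairwise_from_judgments(upper: list[float], labels: list[str] | None = None) -> pd.DataFrame:
    """Build an n x n reciprocal matrix from its upper triangle (row-major).

    ``upper`` lists a_12, a_13, ..., a_1n, a_23, ... on the Saaty scale; the
    default three judgments (3, 5, 3) encode yield vs quality = 3, yield vs
    stability = 5, quality vs stability = 3.
    """
    k = len(upper)
    n = int((1 + np.sqrt(1 + 8 * k)) / 2)
    if n * (n - 1) // 2 != k:
        raise ValidationError(f"{k} judgments do not fill an upper triangle")
    a = np.eye(n)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            v = float(upper[idx])
            if v <= 0:
                raise ValidationError("pairwise judgments must be positive")
            a[i, j] = v
            a[j, i] = 1.0 / v
            idx += 1
    if labels is None:
        labels = list(CRITERION_GROUPS) if n == 3 else [f"c{i+1}" for i in range(n)]
    return pd.DataFrame(a, index=labels, columns=labels)


@dataclass
class AhpResult:
    """Principal-eigenvector weights and consistency diagnostics."""

    weights: pd.Series
    lambda_max: float
    ci: float
    cr: float

    @property
    def consistent(self) -> bool:
        """The CR < 0.1 reliability gate on the expert judgments."""
        return self.cr < 0.1


def ahp_weights(pairwise: pd.DataFrame, tol: float = 1e-12, max_iter: int = 10_000) -> AhpResult:
    """AHP weights via power iteration on a positive reciprocal matrix.

    lambda_max is the principal eigenvalue (Rayleigh quotient at
    convergence); CI = (lambda_max - n)/(n - 1) and CR = CI/RI(n) with
    Saaty's random index.  RI(1) = RI(2) = 0, so CR is 0 by convention
    there.
    """
    a = np.asarray(pairwise, dtype=float)
    n = a.shape[0]
    if a.shape[0] != a.shape[1]:
        raise ValidationError("pairwise matrix must be square")
    if n < 2 or n > max(SAATY_RI):
        raise ValidationError(f"matrix order {n} outside the random-index table (2..{max(SAATY_RI)})")
    if np.any(a <= 0):
        raise ValidationError("pairwise matrix entries must be positive")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise ValidationError("pairwise matrix diagonal must be 1")
    if not np.allclose(a * a.T, 1.0, atol=1e-10):
        raise ValidationError("pairwise matrix is not reciprocal (a_ij * a_ji != 1)")

    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = a @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lambda_max = float(np.mean((a @ w) / w))
    ci = (lambda_max - n) / (n - 1)
    ri = SAATY_RI[n]
    cr = 0.0 if ri == 0 else ci / ri
    labels = list(pairwise.index) if isinstance(pairwise, pd.DataFrame) else list(range(n))
    return AhpResult(
        weights=pd.Series(w, index=labels, name="weight"),
        lambda_max=lambda_max, ci=float(ci), cr=float(cr),
    )


def combine_weights(
    entropy: pd.Series,
    expert: pd.Series,
    scheme: str = "hierarchical",
    groups: dict[str, str] | None = None,
) -> pd.Series:
    """Blend objective (entropy) and expert weights into one vector.

    hierarchical (default)
        ``expert`` holds one weight per criterion *group*; within each group
        the entropy weights are renormalized so the group sums to its expert
        weight.  If a group carries no entropy information its expert weight
        is spread uniformly over the group's criteria; a group with no
        criteria has its weight redistributed proportionally over the rest.
    multiplicative
        ``expert`` holds one weight per criterion; w_j is proportional to
        entropy_j * expert_j.
    """
    if scheme == "multiplicative":
        if set(expert.index) != set(entropy.index):
            raise ValidationError("multiplicative scheme needs per-criterion expert weights")
        w = entropy * expert.reindex(entropy.index)
        if w.sum() == 0:
            raise ValidationError("entropy and expert weights have disjoint support")
        return (w / w.sum()).rename("weight")
    if scheme != "hierarchical":
        raise ConfigError(f"unknown combination scheme {scheme!r}")
    if groups is None:
        raise ConfigError("hierarchical scheme requires a criterion->group mapping")
    untagged = [c for c in entropy.index if c not in groups]
    if untagged:
        raise ConfigError(f"criteria missing a group tag: {untagged}")

    present = [g for g in expert.index if any(groups[c] == g for c in entropy.index)]
    if not present:
        raise ValidationError("no criterion belongs to any expert group")
    g_w = expert.loc[present]
    g_w = g_w / g_w.sum()  # redistribute weight of empty groups

    out = pd.Series(0.0, index=entropy.index, name="weight")
    for g in present:
        members = [c for c in entropy.index if groups[c] == g]
        e = entropy.loc[members]
        if e.sum() > 0:
            out.loc[members] = g_w[g] * e / e.sum()
        else:
            logger.warning("group %r has no entropy information; uniform within group", g)
            out.loc[members] = g_w[g] / len(members)
    return out / out.sum()


@dataclass
class TopsisResult:
    """Distances to the ideal/anti-ideal, closeness and dense ranks."""

    table: pd.DataFrame          # d_plus, d_minus, closeness, rank per alternative
    ideal: pd.Series
    anti_ideal: pd.Series
    weights: pd.Series

    @property
    def ranking(self) -> pd.Index:
        return self.table.sort_values(["rank", "closeness"], ascending=[True, False]).index


def topsis_rank(m: DecisionMatrix, weights: pd.Series) -> TopsisResult:
    """Rank alternatives by relative closeness to the ideal solution.

    Columns are vector-normalized (r_ij = x_ij / ||x_.j||) and weighted;
    the ideal takes the column max for benefit criteria and min for cost
    (anti-ideal reversed); d+/- are Euclidean distances and closeness is
    d^- / (d^+ + d^-).  Ranks are dense on descending closeness; ties share
    a rank and are logged.  A zero-norm column with positive weight is an
    error (its direction would be meaningless); with zero weight it is
    inert and allowed.
    """
    w = weights.reindex(m.values.columns)
    if w.isna().any():
        raise ValidationError(
            f"weights missing for criteria: {list(m.values.columns[w.isna()])}"
        )
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValidationError(f"weights must sum to 1, got {w.sum()}")
    x = m.values.to_numpy(dtype=float)
    norms = np.sqrt((x ** 2).sum(axis=0))
    zero = norms == 0
    if np.any(zero & (w.to_numpy() > 0)):
        bad = list(m.values.columns[zero & (w.to_numpy() > 0)])
        raise ValidationError(f"zero-norm criterion column(s) with positive weight: {bad}")
    norms[zero] = 1.0
    v = (x / norms) * w.to_numpy()

    is_benefit = np.array([m.directions[c] == "benefit" for c in m.values.columns])
    ideal = np.where(is_benefit, v.max(axis=0), v.min(axis=0))
    anti = np.where(is_benefit, v.min(axis=0), v.max(axis=0))
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    closeness = np.where(denom > 0, d_minus / denom, 0.5)  # all-equal alternatives

    table = pd.DataFrame(
        {"d_plus": d_plus, "d_minus": d_minus, "closeness": closeness},
        index=m.values.index,
    )
    table["rank"] = table["closeness"].rank(method="dense", ascending=False).astype(int)
    if table["closeness"].duplicated().any():
        logger.warning("ties in TOPSIS closeness; tied alternatives share a rank")
    return TopsisResult(
        table=table,
        ideal=pd.Series(ideal, index=m.values.columns),
        anti_ideal=pd.Series(anti, index=m.values.columns),
        weights=w,
    )


def default_criteria() -> list[Criterion]:
    """Default criterion set for the comprehensive treatment ranking.

    Six agronomic/nutritional benefit criteria — thousand-grain weight,
    grain yield, fresh and dry forage yield (yield group), starch and
    protein (quality group) — plus two cost stability criteria (replicate
    CV and ecovalence share).
    """
    return [
        Criterion("TGW", "benefit", "yield"),
        Criterion("GY", "benefit", "yield"),
        Criterion("FY", "benefit", "yield"),
        Criterion("DY", "benefit", "yield"),
        Criterion("starch", "benefit", "quality"),
        Criterion("protein", "benefit", "quality"),
        Criterion("CV", "cost", "stability"),
        Criterion("Wi", "cost", "stability"),
    ]


def build_decision_matrix(
    df: pd.DataFrame, criteria: list[Criterion] | None = None
) -> DecisionMatrix:
    """Assemble the treatment x criterion matrix from a plot-level table.

    Alternatives are the genotype-location-year treatments (labelled
    ``G-L-Y``); trait criteria enter as cell means over replicates.  Two
    stability criteria are recognised by name:

    ``CV``
        mean replicate CV (%) over the trait criteria, per treatment cell;
    ``Wi``
        mean ecovalence *share* over the trait criteria for the treatment's
        genotype-year entry (shares are unitless, so they can be averaged
        across traits of different scales).

    Both are cost criteria: smaller means more stable.
    """
    if criteria is None:
        criteria = default_criteria()
    trait_crit = [c for c in criteria if c.name not in ("CV", "Wi")]
    stab_crit = [c for c in criteria if c.name in ("CV", "Wi")]
    available = [c for c in df.columns if c not in ("genotype", "location", "year", "replicate")]
    missing = [c.name for c in trait_crit if c.name not in df.columns]
    if missing:
        raise ValidationError(
            f"trait criterion/criteria {missing} not in table; available: {available}"
        )
    if not trait_crit:
        raise ValidationError("need at least one trait criterion")

    keys = ["genotype", "location", "year"]
    cell = df.groupby(keys, observed=True)[[c.name for c in trait_crit]].mean()

    values = cell.copy()
    if any(c.name == "CV" for c in stab_crit):
        cvs = pd.concat(
            [_stab.cv_by_group(df, c.name) for c in trait_crit], axis=1
        )
        values["CV"] = cvs.mean(axis=1).reindex(cell.index)
    if any(c.name == "Wi" for c in stab_crit):
        shares = []
        for c in trait_crit:
            _, share = _stab.wricke_ecovalence(_stab.gxe_table(df, c.name))
            shares.append(share)
        share_mean = pd.concat(shares, axis=1).mean(axis=1)
        wi_col = [
            share_mean.get(f"{g}-{y}", np.nan) for g, _, y in cell.index
        ]
        values["Wi"] = wi_col
        if values["Wi"].isna().any():
            values["Wi"] = values["Wi"].fillna(0.0)

    values.index = ["-".join(map(str, k)) for k in values.index]
    values.index.name = "treatment"
    return DecisionMatrix(
        values=values,
        directions={c.name: c.direction for c in criteria if c.name in values.columns},
        groups={c.name: c.group for c in criteria if c.name in values.columns},
    )
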