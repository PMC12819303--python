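"""Factorial analysis of balanced multi-environment trials.

Fixed-effects ANOVA for a balanced complete factorial (all main effects and
interactions), computed by the classical marginal-means decomposition: for a
term T (a subset of the factors) the subset sum of squares is

    S(T) = n_T * sum over level combos of (mean_T - grand mean)^2

with ``n_T`` observations per combo, and the term sum of squares follows by
inclusion-exclusion over sub-terms, SS(T) = sum_{S<=T} (-1)^{|T\\S|} S(S).
In a balanced design this coincides with Type I/II/III projections and with
the fixed-effects F-tests of the obvious mixed-model formulations.  F is
MS(term)/MS(residual); p is the upper tail of the F distribution.

Also provides per-environment one-way genotype ANOVA (an environment being
one location-year combination), Tukey HSD multiple comparisons with a
compact letter display, and per-cell mean/SE/CV summaries.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ValidationError

__all__ = [
    "anova_factorial",
    "anova_three_way",
    "anova_per_environment",
    "tukey_hsd",
    "compact_letter_display",
    "summarize_cells",
    "significance_stars",
    "TukeyResult",
]

logger = logging.getLogger(__name__)

THREE_WAY_FACTORS = ("genotype", "location", "year")


def _check_balance(df: pd.DataFrame, factors: tuple[str, ...]) -> int:
    """Return replicates per cell; raise if the design is unbalanced/incomplete."""
    counts = df.groupby(list(factors), observed=True).size()
    n_levels = [df[f].nunique() for f in factors]
    expected_cells = int(np.prod(n_levels))
    if len(counts) != expected_cells or counts.nunique() != 1:
        raise DesignError(
            f"unbalanced or incomplete design over {factors}: "
            f"{len(counts)} of {expected_cells} cells present, "
            f"cell sizes {sorted(counts.unique())}"
        )
    return int(counts.iloc[0])


def anova_factorial(df: pd.DataFrame, trait: str, factors: tuple[str, ...]) -> pd.DataFrame:
    """Balanced fixed-effects factorial ANOVA table for one trait.

    Returns a DataFrame indexed by term (factor names joined by ':', plus
    'Residual') with columns ``ss, df, ms, F, p``.  Degenerate inputs (all
    observations identical, or a term with zero residual MS) report NaN for
    F and p rather than failing.
    """
    if trait not in df.columns:
        raise ValidationError(f"trait {trait!r} not in table")
    factors = tuple(factors)
    reps = _check_balance(df, factors)
    if reps < 2:
        raise DesignError("need >= 2 replicates per cell for a residual term")

    y = df[trait].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValidationError(f"trait {trait!r} contains non-finite values")
    n = len(y)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    n_levels = {f: df[f].nunique() for f in factors}

    # subset sums of squares S(T) for every non-empty subset of factors
    subset_ss: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(factors) + 1):
        for T in itertools.combinations(factors, r):
            means = df.groupby(list(T), observed=True)[trait].mean().to_numpy()
            n_per = n // means.size
            subset_ss[frozenset(T)] = float(n_per * np.sum((means - grand) ** 2))

    rows = []
    ss_model = 0.0
    for r in range(1, len(factors) + 1):
        for T in itertools.combinations(factors, r):
            ss_t = 0.0
            for k in range(len(T) + 1):
                for S in itertools.combinations(T, k):
                    ss_t += (-1) ** (len(T) - k) * subset_ss[frozenset(S)]
            ss_t = max(ss_t, 0.0)  # guard tiny negative rounding
            df_t = int(np.prod([n_levels[f] - 1 for f in T]))
            rows.append({"term": ":".join(T), "ss": ss_t, "df": df_t})
            ss_model += ss_t

    df_model = sum(r["df"] for r in rows)
    ss_resid = max(ss_total - ss_model, 0.0)
    df_resid = n - 1 - df_model
    rows.append({"term": "Residual", "ss": ss_resid, "df": df_resid})

    table = pd.DataFrame(rows).set_index("term")
    table["ms"] = table["ss"] / table["df"]
    ms_resid = table.loc["Residual", "ms"]
    if ms_resid > 0:
        table["F"] = table["ms"] / ms_resid
        table["p"] = stats.f.sf(table["F"], table["df"], df_resid)
    else:
        table["F"] = np.nan
        table["p"] = np.nan
    table.loc["Residual", ["F", "p"]] = np.nan
    return table


def anova_three_way(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Combined genotype x location x year ANOVA with all interactions."""
    return anova_factorial(df, trait, THREE_WAY_FACTORS)


def anova_per_environment(df: pd.DataFrame, trait: str) -> dict[str, pd.DataFrame]:
    """One-way genotype ANOVA within each location-year environment.

    Environments are labelled ``"{location}-{year}"``.  Strata with fewer
    than two genotypes are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for (loc, yr), sub in df.groupby(["location", "year"], observed=True):
        env = f"{loc}-{yr}"
        if sub["genotype"].nunique() < 2:
            logger.warning("environment %s has < 2 genotypes; skipped", env)
            continue
        out[env] = anova_factorial(sub, trait, ("genotype",))
    return out


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD comparisons plus a compact letter display."""

    pairs: pd.DataFrame        # group1, group2, diff, se, q, p, significant
    letters: dict[str, str]    # group -> letter string (shared letter = not distinguishable)
    ms_within: float
    df_within: int
    alpha: float


def tukey_hsd(groups: dict[str, np.ndarray | list], alpha: float = 0.05) -> TukeyResult:
    """Tukey(-Kramer) HSD over labelled groups with a pooled error term.

    p-values come from the studentized range distribution with k groups and
    the pooled within-group df.  For k = 2 the test reduces to the pooled
    two-sample two-sided t-test (q = t * sqrt(2)).
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    labels = list(groups)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValidationError(f"group {g!r} needs >= 2 values")
    k = len(labels)
    n_tot = sum(a.size for a in arrays.values())
    df_w = n_tot - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    means = {g: a.mean() for g, a in arrays.items()}

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        diff = means[g1] - means[g2]
        n1, n2 = arrays[g1].size, arrays[g2].size
        se = np.sqrt(ms_w / 2.0 * (1.0 / n1 + 1.0 / n2))
        if se > 0:
            q = abs(diff) / se
            p = np.nan  # filled by one vectorized sf call below
        else:  # zero pooled variance: identical means are p=1, distinct are p=0
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        rows.append({"group1": g1, "group2": g2, "diff": diff, "se": se, "q": q, "p": p})
    pending = [i for i, r in enumerate(rows) if np.isnan(r["p"])]
    if pending:
        ps = stats.studentized_range.sf([rows[i]["q"] for i in pending], k, df_w)
        for i, p in zip(pending, np.atleast_1d(ps)):
            rows[i]["p"] = float(p)
    sig_pairs: set[frozenset] = set()
    for r in rows:
        r["significant"] = r["p"] < alpha
        if r["significant"]:
            sig_pairs.add(frozenset((r["group1"], r["group2"])))
    letters = compact_letter_display(means, sig_pairs)
    return TukeyResult(
        pairs=pd.DataFrame(rows), letters=letters, ms_within=float(ms_w),
        df_within=df_w, alpha=alpha,
    )


def compact_letter_display(
    means: dict[str, float], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Letters are
    assigned in descending order of group mean ('a' = best), the convention
    of agronomy trial reports.
    """
    order = sorted(means, key=lambda g: -means[g])
    letter_sets: list[set[str]] = [set(order)]
    for pair in significant_pairs:
        g1, g2 = tuple(pair)
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                a, b = s - {g1}, s - {g2}
                # absorb: only keep sets not contained in an existing one
                for new in (a, b):
                    if not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    letter_sets = [s for s in letter_sets if s]
    # order letters by the best mean they cover
    letter_sets.sort(key=lambda s: -max(means[g] for g in s))
    alphabet = string.ascii_lowercase
    out = {g: "" for g in order}
    for i, s in enumerate(letter_sets):
        ch = alphabet[i] if i < 26 else f"l{i}"
        for g in order:
            if g in s:
                out[g] += ch
    return out


def summarize_cells(
    df: pd.DataFrame, trait: str, by: tuple[str, ...] = THREE_WAY_FACTORS
) -> pd.DataFrame:
    """Mean, SE and CV per factor cell.

    SE = sd/sqrt(n) and CV = 100*sd/mean with the sample (n-1) sd.  Cells
    with zero mean get CV = NaN with a warning (the ratio is undefined).
    """
    if trait not in df.columns:
        raise ValidationError(f"trait {trait!r} not in table")
    rows = []
    for key, sub in df.groupby(list(by), observed=True):
        v = sub[trait].to_numpy(dtype=float)
        if v.size < 2:
            raise DesignError(f"cell {key} has < 2 replicates")
        mean = v.mean()
        sd = 0.0 if v.max() == v.min() else v.std(ddof=1)
        if mean == 0:
            logger.warning("cell %s has zero mean; CV undefined", key)
            cv = np.nan
        else:
            cv = 100.0 * sd / mean
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(by, key)) | {"mean": mean, "se": sd / np.sqrt(v.size), "cv": cv,
                                          "n": v.size})
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Trial-report convention: ns > 0.05, * <= .05, ** <= .01, *** <= .001, **** <= .0001."""
    if np.isnan(p):
        return "NA"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
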