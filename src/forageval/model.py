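"""Model/Results interface for the full trial evaluation.

:class:`ForageTrial` wraps a plot-level trait table (long format: genotype,
location, year, replicate, one column per trait) and ``fit()`` runs the
whole evaluation chain — feeding-value indices, per-environment and
combined factorial ANOVA with Tukey comparisons, CV/ecovalence stability,
and the entropy+AHP-weighted TOPSIS ranking — returning a
:class:`ForageTrialResults` that carries every table and a ``summary()``.

Example
-------
>>> from forageval import ForageTrial, synthetic
>>> design, specs = synthetic.stay_green_preset()
>>> data = synthetic.generate_trial(design, specs, seed=7)
>>> res = ForageTrial(data).fit()
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anova as _anova
from . import feeding as _feeding
from . import mcdm as _mcdm
from . import stability as _stab
from . import synthetic as _syn
from .errors import ValidationError

__all__ = ["ForageTrial", "ForageTrialResults"]

_DEFAULT_JUDGMENTS = (3.0, 5.0, 3.0)  # yield:quality, yield:stability, quality:stability


class ForageTrial:
    """A balanced multi-environment forage trial ready for evaluation.

    Parameters
    ----------
    data
        Long-format plot table with columns ``genotype, location, year,
        replicate`` plus numeric trait columns.
    traits
        Trait columns to analyse (default: every non-factor column).
    add_feeding
        Derive DMI/DDM/TDN/RFV/RFQ from ADF and NDF columns when present
        and not already in the table.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        traits: list[str] | None = None,
        add_feeding: bool = True,
    ) -> None:
        missing = [c for c in _syn.FACTOR_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"data is missing factor column(s) {missing}")
        data = data.copy()
        for c in ("genotype", "location", "year"):
            data[c] = data[c].astype(str)
        if (
            add_feeding
            and {"ADF", "NDF"} <= set(data.columns)
            and not set(_feeding.FEEDING_INDEX_COLUMNS) <= set(data.columns)
        ):
            data = _feeding.add_feeding_values(data, overwrite=True)
        self.data = data
        self.traits = list(traits) if traits is not None else _syn.trait_columns(data)
        absent = [t for t in self.traits if t not in data.columns]
        if absent:
            raise ValidationError(f"trait(s) {absent} not in data")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ForageTrial":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ForageTrial":
        return cls(_syn.read_trial_csv(path), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        criteria: list[_mcdm.Criterion] | None = None,
        ahp_judgments: tuple[float, ...] = _DEFAULT_JUDGMENTS,
        weight_scheme: str = "hierarchical",
        entry_axis: tuple[str, ...] = _stab.DEFAULT_ENTRY_AXIS,
        env_axis: tuple[str, ...] = _stab.DEFAULT_ENV_AXIS,
        run_tukey: bool = True,
    ) -> "ForageTrialResults":
        """Run the full evaluation and return the results object.

        ``run_tukey=False`` skips the studentized-range comparisons (the
        slowest stage), useful inside simulation loops.
        """
        if not 0 < alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        anova_tables = {t: _anova.anova_three_way(self.data, t) for t in self.traits}
        env_tables = {t: _anova.anova_per_environment(self.data, t) for t in self.traits}
        summaries = pd.concat(
            [_anova.summarize_cells(self.data, t).assign(trait=t) for t in self.traits],
            ignore_index=True,
        )
        tukey = {}
        if run_tukey:
            groups_by_cell = {
                "-".join(k): g
                for k, g in self.data.groupby(["genotype", "location", "year"], observed=True)
            }
            tukey = {
                t: _anova.tukey_hsd(
                    {cell: g[t].to_numpy() for cell, g in groups_by_cell.items()}, alpha=alpha
                )
                for t in self.traits
            }
        stab = {
            t: _stab.stability_result(self.data, t, entry_axis=entry_axis, env_axis=env_axis)
            for t in self.traits
        }

        matrix = _mcdm.build_decision_matrix(self.data, criteria).drop_constant_columns()
        entropy_w = _mcdm.entropy_weights(matrix)
        ahp = _mcdm.ahp_weights(_mcdm.pairwise_from_judgments(list(ahp_judgments)))
        combined = _mcdm.combine_weights(
            entropy_w, ahp.weights, scheme=weight_scheme, groups=matrix.groups
        )
        topsis = _mcdm.topsis_rank(matrix, combined)

        return ForageTrialResults(
            model=self,
            alpha=alpha,
            anova_tables=anova_tables,
            env_anova_tables=env_tables,
            cell_summary=summaries,
            tukey=tukey,
            stability=stab,
            decision_matrix=matrix,
            entropy_weights=entropy_w,
            ahp=ahp,
            combined_weights=combined,
            topsis=topsis,
        )


@dataclass
class ForageTrialResults:
    """Everything the evaluation computed, with a text ``summary()``."""

    model: ForageTrial
    alpha: float
    anova_tables: dict[str, pd.DataFrame]
    env_anova_tables: dict[str, dict[str, pd.DataFrame]]
    cell_summary: pd.DataFrame
    tukey: dict[str, _anova.TukeyResult]
    stability: dict[str, _stab.StabilityResult]
    decision_matrix: _mcdm.DecisionMatrix
    entropy_weights: pd.Series
    ahp: _mcdm.AhpResult
    combined_weights: pd.Series
    topsis: _mcdm.TopsisResult
    _extra: dict = field(default_factory=dict)

    @property
    def ranking(self) -> pd.DataFrame:
        """TOPSIS table sorted by rank (best treatment first)."""
        return self.topsis.table.sort_values(["rank", "closeness"], ascending=[True, False])

    def anova_pvalues(self) -> pd.DataFrame:
        """Matrix of combined-ANOVA p-values: traits x model terms."""
        rows = {}
        for t, tab in self.anova_tables.items():
            rows[t] = tab["p"].drop("Residual")
        return pd.DataFrame(rows).T

    def summary(self, top: int = 5) -> str:
        d = self.model.data
        lines = [
            "Multi-environment forage trial evaluation",
            "=" * 57,
            f"plots: {len(d)}   genotypes: {sorted(d.genotype.unique())}   "
            f"locations: {sorted(d.location.unique())}   years: {sorted(d.year.unique())}",
            f"traits analysed: {len(self.model.traits)}",
            "",
            f"Combined three-way ANOVA (alpha = {self.alpha:g}):",
        ]
        pv = self.anova_pvalues()
        abbrev = {"genotype": "G", "location": "L", "year": "Y"}
        pv.columns = [
            "x".join(abbrev.get(f, f) for f in t.split(":")) for t in pv.columns
        ]
        hdr = "  {:<10}".format("trait") + "".join(f"{t:>8}" for t in pv.columns)
        lines.append(hdr)
        for t, row in pv.iterrows():
            stars = [
                _anova.significance_stars(v) if np.isfinite(v) else "NA" for v in row.to_numpy()
            ]
            lines.append("  {:<10}".format(t) + "".join(f"{s:>8}" for s in stars))
        lines += [
            "",
            "Criterion weights (entropy within AHP groups, "
            f"CR = {self.ahp.cr:.4f} {'< 0.1: consistent' if self.ahp.consistent else '>= 0.1: NOT consistent'}):",
        ]
        for c, w in self.combined_weights.items():
            lines.append(f"  {c:<10} {w:8.4f}  ({self.decision_matrix.groups.get(c, '?')}, "
                         f"{self.decision_matrix.directions[c]})")
        lines += ["", f"TOPSIS ranking (top {top}):"]
        rk = self.ranking.head(top)
        for name, row in rk.iterrows():
            lines.append(
                f"  rank {int(row['rank']):>2}  {name:<14} closeness = {row['closeness']:.4f}"
            )
        return "\n".join(lines)
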