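"""Synthetic multi-environment trial generator.

Emulates a balanced randomized-complete-block (RCBD) forage oat trial:
every genotype appears in every replicate block of every location-year
environment, one measured value per plot and trait.  Trait values are
drawn as

    value = baseline + g(genotype) + l(location) + y(year)
            + interaction(level tuple) + block + N(0, residual_sd)

with all effects additive and plot-level noise independent Gaussian.
Ground-truth effects are known, so downstream analyses (factorial ANOVA,
stability statistics, TOPSIS ranking) can be checked by recovery tests.

The default study conditions mirror a two-genotype (conventional control
CK vs its stay-green mutant SG), two-location (high-altitude plateau HZ
vs warm dry-hot valley YM), two-year, three-replicate dual-purpose oat
trial; see :func:`stay_green_preset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "TrialDesign",
    "TraitSpec",
    "generate_trial",
    "stay_green_preset",
    "design_to_dict",
    "design_from_dict",
    "specs_to_dict",
    "specs_from_dict",
    "write_trial_csv",
    "read_trial_csv",
    "FACTOR_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Factor columns of the long-format plot table, in canonical order.
FACTOR_COLUMNS = ("genotype", "location", "year", "replicate")


@dataclass(frozen=True)
class TrialDesign:
    """Factorial layout of a balanced multi-environment trial.

    Parameters
    ----------
    genotypes, locations, years
        Non-empty, duplicate-free label lists.
    replicates
        Replicate plots per genotype x location x year cell; at least 2
        (within-cell variance is needed for CV and the ANOVA residual).
    """

    genotypes: tuple[str, ...] = ("CK", "SG")
    locations: tuple[str, ...] = ("HZ", "YM")
    years: tuple[str, ...] = ("2023", "2024")
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("genotypes", "locations", "years"):
            levels = tuple(str(v) for v in getattr(self, name))
            object.__setattr__(self, name, levels)
            if not levels:
                raise ConfigError(f"design.{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ConfigError(f"design.{name} contains duplicate labels: {levels}")
        if self.replicates < 2:
            raise ConfigError("design.replicates must be >= 2")

    @property
    def n_cells(self) -> int:
        return len(self.genotypes) * len(self.locations) * len(self.years)

    @property
    def n_plots(self) -> int:
        return self.n_cells * self.replicates

    def levels(self, factor: str) -> tuple[str, ...]:
        return {"genotype": self.genotypes, "location": self.locations, "year": self.years}[factor]


@dataclass(frozen=True)
class TraitSpec:
    """Generative description of one measured trait.

    ``direction`` records whether larger values are agronomically better
    (``"benefit"``, e.g. yields, protein) or worse (``"cost"``, e.g. the
    fiber fractions ADF/NDF); the multi-criteria ranking stage relies on it.
    ``lower_bound`` truncates the Gaussian draw (e.g. 0 for percentages);
    clipping is logged.
    """

    name: str
    baseline: float
    genotype_effects: Mapping[str, float] = field(default_factory=dict)
    location_effects: Mapping[str, float] = field(default_factory=dict)
    year_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, ...], float] = field(default_factory=dict)
    residual_sd: float = 1.0
    direction: str = "benefit"
    lower_bound: float | None = None

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ConfigError(f"trait {self.name!r}: residual_sd must be >= 0")
        if self.direction not in ("benefit", "cost"):
            raise ConfigError(
                f"trait {self.name!r}: direction must be 'benefit' or 'cost', got {self.direction!r}"
            )

    def expected_value(self, genotype: str, location: str, year: str) -> float:
        """Noise-free cell expectation: baseline plus summed effects."""
        v = (
            self.baseline
            + self.genotype_effects.get(genotype, 0.0)
            + self.location_effects.get(location, 0.0)
            + self.year_effects.get(year, 0.0)
        )
        levels = {genotype, location, year}
        for combo, eff in self.interaction_effects.items():
            if set(combo) <= levels:
                v += eff
        return v


def _check_effect_levels(spec: TraitSpec, design: TrialDesign) -> None:
    known = set(design.genotypes) | set(design.locations) | set(design.years)
    for attr, pool in (
        ("genotype_effects", design.genotypes),
        ("location_effects", design.locations),
        ("year_effects", design.years),
    ):
        for level in getattr(spec, attr):
            if level not in pool:
                raise ConfigError(
                    f"trait {spec.name!r}: {attr} references unknown level {level!r} "
                    f"(known: {list(pool)})"
                )
    for combo in spec.interaction_effects:
        for level in combo:
            if level not in known:
                raise ConfigError(
                    f"trait {spec.name!r}: interaction_effects references unknown level {level!r}"
                )


def generate_trial(
    design: TrialDesign,
    specs: Sequence[TraitSpec],
    seed: int,
    block_sd: float = 0.0,
) -> pd.DataFrame:
    """Generate one balanced plot-level trial table.

    Returns a long-format DataFrame with one row per plot: the factor
    columns ``genotype, location, year, replicate`` followed by one column
    per trait.  Output is deterministic in ``(design, specs, seed)``.

    ``block_sd`` adds an optional shared Gaussian replicate-block effect
    within each environment (default 0: the source trial reports no block
    variance).
    """
    if not specs:
        raise ConfigError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate trait names in specs: {names}")
    for spec in specs:
        _check_effect_levels(spec, design)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for g in design.genotypes:
        for l in design.locations:
            for y in design.years:
                for r in range(1, design.replicates + 1):
                    rows.append({"genotype": g, "location": l, "year": y, "replicate": r})
    df = pd.DataFrame(rows)

    # per-environment block effects, shared across genotypes within a block
    block_eff: dict[tuple[str, str, int], float] = {}
    if block_sd > 0:
        for l in design.locations:
            for y in design.years:
                for r in range(1, design.replicates + 1):
                    block_eff[(l, y, r)] = float(rng.normal(0.0, block_sd))

    for spec in specs:
        mean = np.array(
            [spec.expected_value(g, l, y) for g, l, y in zip(df.genotype, df.location, df.year)]
        )
        if block_sd > 0:
            mean = mean + np.array(
                [block_eff[(l, y, r)] for l, y, r in zip(df.location, df.year, df.replicate)]
            )
        noise = rng.normal(0.0, spec.residual_sd, size=len(df)) if spec.residual_sd > 0 else 0.0
        values = mean + noise
        if spec.lower_bound is not None:
            n_clip = int(np.sum(values < spec.lower_bound))
            if n_clip:
                logger.warning(
                    "trait %s: clipped %d value(s) at lower bound %g",
                    spec.name, n_clip, spec.lower_bound,
                )
                values = np.clip(values, spec.lower_bound, None)
        df[spec.name] = values
    return df


def stay_green_preset(residual_scale: float = 1.0) -> tuple[TrialDesign, list[TraitSpec]]:
    """Default study conditions: stay-green mutant (SG) vs control (CK).

    Encodes the qualitative effect structure of a two-year, two-location
    dual-purpose oat trial comparing a stay-green mutant with its parent:

    * SG exceeds CK in every yield and nutritional-quality trait and has
      *lower* fiber fractions (ADF, NDF) — a genotype main effect of two
      within-cell residual SDs on every trait;
    * the warm low-latitude site YM gives higher yields, the cool
      high-altitude site HZ better quality (higher protein/starch/fat,
      lower ADF/NDF, hence higher feeding value);
    * yields are higher in 2024, protein/fat and feeding quality in 2023.

    ``residual_scale`` scales every trait's residual SD (0 gives the exact
    noiseless cell means); effect sizes are untouched, so the signal-to-noise
    ratio changes accordingly.
    """
    design = TrialDesign()

    def t(name, baseline, sd, sg, ym, y2024, direction="benefit", lower=0.0):
        return TraitSpec(
            name=name,
            baseline=baseline,
            genotype_effects={"SG": sg},
            location_effects={"YM": ym},
            year_effects={"2024": y2024},
            residual_sd=sd * residual_scale,
            direction=direction,
            lower_bound=lower,
        )

    specs = [
        # yields: SG +2sd, YM above HZ, 2024 above 2023
        t("FW", 40.0, 2.0, +4.0, +5.0, +2.0),      # single-plant fresh weight, g
        t("DW", 15.0, 1.0, +2.0, +2.0, +1.0),      # single-plant dry weight, g
        t("FY", 30.0, 1.5, +3.0, +4.0, +1.5),      # fresh forage yield, t/ha
        t("DY", 10.0, 0.5, +1.0, +1.5, +0.5),      # dry forage yield, t/ha
        t("SGW", 2.5, 0.15, +0.3, +0.2, +0.1),     # single-plant grain weight, g
        t("GY", 4.5, 0.25, +0.5, +0.6, +0.25),     # plot-level grain yield, t/ha
        t("TGW", 24.0, 0.8, +1.6, +1.0, +0.5),     # thousand-grain weight, g
        # nutritional composition: SG +2sd, HZ above YM, 2023 above 2024
        t("starch", 38.0, 1.0, +2.0, -1.0, -0.5),
        t("WSC", 12.0, 0.6, +1.2, -0.6, -0.3),
        t("protein", 11.0, 0.5, +1.0, -0.5, -0.4),
        t("fat", 3.5, 0.2, +0.4, -0.2, -0.1),
        # fiber fractions (cost): SG -2sd, lower in HZ, lower in 2023
        t("ADF", 32.0, 1.0, -2.0, +1.5, +0.5, direction="cost"),
        t("NDF", 52.0, 1.2, -2.4, +2.0, +0.6, direction="cost"),
    ]
    return design, specs


# ---------------------------------------------------------------------------
# serialization: YAML/JSON mirror of the design + trait specs, and the
# long-format CSV dialect used by every downstream stage.

def design_to_dict(design: TrialDesign) -> dict:
    return {
        "genotypes": list(design.genotypes),
        "locations": list(design.locations),
        "years": list(design.years),
        "replicates": design.replicates,
    }


def design_from_dict(d: Mapping) -> TrialDesign:
    return TrialDesign(
        genotypes=tuple(str(x) for x in d.get("genotypes", ("CK", "SG"))),
        locations=tuple(str(x) for x in d.get("locations", ("HZ", "YM"))),
        years=tuple(str(x) for x in d.get("years", ("2023", "2024"))),
        replicates=int(d.get("replicates", 3)),
    )


def specs_to_dict(specs: Iterable[TraitSpec]) -> list[dict]:
    out = []
    for s in specs:
        out.append(
            {
                "name": s.name,
                "baseline": s.baseline,
                "genotype_effects": dict(s.genotype_effects),
                "location_effects": dict(s.location_effects),
                "year_effects": dict(s.year_effects),
                "interaction_effects": {"|".join(k): v for k, v in s.interaction_effects.items()},
                "residual_sd": s.residual_sd,
                "direction": s.direction,
                "lower_bound": s.lower_bound,
            }
        )
    return out


def specs_from_dict(items: Iterable[Mapping]) -> list[TraitSpec]:
    specs = []
    for d in items:
        inter = {
            tuple(k.split("|")): float(v)
            for k, v in dict(d.get("interaction_effects", {})).items()
        }
        specs.append(
            TraitSpec(
                name=str(d["name"]),
                baseline=float(d["baseline"]),
                genotype_effects={str(k): float(v) for k, v in dict(d.get("genotype_effects", {})).items()},
                location_effects={str(k): float(v) for k, v in dict(d.get("location_effects", {})).items()},
                year_effects={str(k): float(v) for k, v in dict(d.get("year_effects", {})).items()},
                interaction_effects=inter,
                residual_sd=float(d.get("residual_sd", 1.0)),
                direction=str(d.get("direction", "benefit")),
                lower_bound=(None if d.get("lower_bound") is None else float(d["lower_bound"])),
            )
        )
    return specs


def write_spec_yaml(path, design: TrialDesign, specs: Sequence[TraitSpec]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"design": design_to_dict(design), "traits": specs_to_dict(specs)}, fh)


def read_spec_yaml(path) -> tuple[TrialDesign, list[TraitSpec]]:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    return design_from_dict(d.get("design", {})), specs_from_dict(d.get("traits", []))


def write_trial_csv(df: pd.DataFrame, path) -> None:
    """Write the long-format plot table (UTF-8, '.' decimal, full precision)."""
    df.to_csv(path, index=False, encoding="utf-8")


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype": str, "location": str, "year": str})
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trial CSV is missing factor column(s) {missing}")
    return df


def trait_columns(df: pd.DataFrame) -> list[str]:
    """Numeric trait columns of a long-format plot table."""
    return [c for c in df.columns if c not in FACTOR_COLUMNS]
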