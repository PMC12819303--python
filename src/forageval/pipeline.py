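"""End-to-end pipeline: generate or load data, evaluate, write a report.

``run_pipeline`` drives :class:`~forageval.model.ForageTrial` from a
:class:`RunConfig`, writes every stage's tables as CSV (full float
precision) plus a human-readable summary, and returns a JSON-serializable
manifest (config echo, seed, package versions, output paths and SHA-256
digests) from which an identical re-run can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import mcdm as _mcdm
from . import synthetic as _syn
from .errors import ConfigError
from .model import ForageTrial

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (a long-format plot table) or a synthetic run
    (``synthetic=True`` with a mandatory ``seed``) must be given.
    """

    out_dir: str | Path = "forageval_out"
    input_csv: str | Path | None = None
    synthetic: bool = True
    seed: int | None = None
    residual_scale: float = 1.0
    traits: list[str] | None = None
    alpha: float = 0.05
    ahp_judgments: tuple[float, ...] = (3.0, 5.0, 3.0)
    criteria: list[_mcdm.Criterion] | None = None
    run_stats: bool = True
    run_stability: bool = True
    run_mcdm: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.input_csv is None:
            if not self.synthetic:
                raise ConfigError("either input_csv or synthetic=True is required")
            if self.seed is None:
                raise ConfigError("seed is mandatory for a synthetic run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        crit = raw.pop("criteria", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if crit is not None:
            cfg.criteria = [
                _mcdm.Criterion(c["name"], c["direction"], c["group"]) for c in crit
            ]
        if "ahp_judgments" in raw:
            cfg.ahp_judgments = tuple(float(x) for x in raw["ahp_judgments"])
        return cfg

    def echo(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "input_csv": None if self.input_csv is None else str(self.input_csv),
            "synthetic": self.synthetic,
            "seed": self.seed,
            "residual_scale": self.residual_scale,
            "traits": self.traits,
            "alpha": self.alpha,
            "ahp_judgments": list(self.ahp_judgments),
            "criteria": None
            if self.criteria is None
            else [{"name": c.name, "direction": c.direction, "group": c.group} for c in self.criteria],
            "run_stats": self.run_stats,
            "run_stability": self.run_stability,
            "run_mcdm": self.run_mcdm,
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, index=index, encoding="utf-8")
        written.append(p)

    try:
        stage = "data"
        if config.input_csv is not None:
            data = _syn.read_trial_csv(config.input_csv)
        else:
            design, specs = _syn.stay_green_preset(residual_scale=config.residual_scale)
            data = _syn.generate_trial(design, specs, seed=int(config.seed))
        _syn.write_trial_csv(data, out / "data.csv")
        written.append(out / "data.csv")

        stage = "model"
        trial = ForageTrial(data, traits=config.traits)
        if set(("DMI", "DDM", "TDN", "RFV", "RFQ")) <= set(trial.data.columns):
            save(trial.data, "feeding_values.csv")
        res = trial.fit(
            alpha=config.alpha,
            criteria=config.criteria,
            ahp_judgments=config.ahp_judgments,
        )

        if config.run_stats:
            stage = "stats"
            combined = pd.concat(
                [t.assign(trait=k).reset_index() for k, t in res.anova_tables.items()],
                ignore_index=True,
            )
            save(combined, "anova_combined.csv")
            per_env = pd.concat(
                [
                    t.assign(trait=k, environment=env).reset_index()
                    for k, envs in res.env_anova_tables.items()
                    for env, t in envs.items()
                ],
                ignore_index=True,
            )
            save(per_env, "anova_by_environment.csv")
            save(res.cell_summary, "cell_summary.csv")
            tukey = pd.concat(
                [r.pairs.assign(trait=k) for k, r in res.tukey.items()], ignore_index=True
            )
            save(tukey, "tukey_pairs.csv")
            letters = pd.DataFrame(
                [
                    {"trait": k, "group": g, "letters": s}
                    for k, r in res.tukey.items()
                    for g, s in r.letters.items()
                ]
            )
            save(letters, "tukey_letters.csv")

        if config.run_stability:
            stage = "stability"
            cv = pd.concat(
                [r.cv_by_group.rename("cv").reset_index().assign(trait=k)
                 for k, r in res.stability.items()],
                ignore_index=True,
            )
            save(cv, "stability_cv.csv")
            wi = pd.concat(
                [
                    pd.DataFrame({"wi": r.wi_by_entry, "wi_share": r.wi_share})
                    .reset_index()
                    .assign(trait=k)
                    for k, r in res.stability.items()
                ],
                ignore_index=True,
            )
            save(wi, "stability_wi.csv")
            series = []
            from . import stability as _stab

            for k in res.stability:
                tidy, crossing = _stab.interaction_series(trial.data, k)
                series.append(tidy.assign(trait=k, crossover=crossing))
            save(pd.concat(series, ignore_index=True), "interaction_series.csv")

        if config.run_mcdm:
            stage = "mcdm"
            save(res.decision_matrix.values, "decision_matrix.csv", index=True)
            weights = pd.DataFrame(
                {
                    "entropy": res.entropy_weights,
                    "combined": res.combined_weights,
                    "group": pd.Series(res.decision_matrix.groups),
                    "direction": pd.Series(res.decision_matrix.directions),
                }
            )
            save(weights, "weights.csv", index=True)
            ahp_path = out / "ahp.json"
            ahp_path.write_text(
                json.dumps(
                    {
                        "weights": res.ahp.weights.to_dict(),
                        "lambda_max": res.ahp.lambda_max,
                        "ci": res.ahp.ci,
                        "cr": res.ahp.cr,
                        "consistent": res.ahp.consistent,
                    },
                    indent=2,
                    sort_keys=True,
                ),
                encoding="utf-8",
            )
            written.append(ahp_path)
            save(res.topsis.table, "topsis.csv", index=True)

        report = out / "report.txt"
        report.write_text(res.summary() + "\n", encoding="utf-8")
        written.append(report)
    except Exception as exc:  # annotate which stage broke, then re-raise
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "forageval",
        "version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "config": config.echo(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "pandas": pd.__version__}
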