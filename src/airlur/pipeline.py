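"""End-to-end study orchestration.

One call — :func:`run_study` — takes a validated :class:`StudyConfig` and a
seed and produces the full study bundle: the synthetic scene, placed sites,
simulated campaign, QA summaries, reference-adjusted concentrations, the
predictor matrix, one selected model per pollutant x scope (4 pollutants x
annual/summer/winter = 12 by default), and report tables in the standard
layouts (descriptive statistics per pollutant/season; per-model coefficient
tables with Season, Predictors, Unit, R², LOOCV, df, Beta, SE, t, p).

Spring measurements are simulated and summarized in the descriptive table
but no spring models are built by default, which is what keeps the default
model count at 12.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import ConfigurationError
from .exposure_predict import rasterize
from .geo_predictors import build_predictor_matrix, default_predictor_grid
from .lur_model import LurModel, supervised_forward_select
from .qa_adjust import adjust_all, apply_qa
from .scene import POLLUTANTS
from .synthetic_city import (
    CampaignSchedule,
    SceneConfig,
    TruthModel,
    default_truth_model,
    generate_city,
    place_sites,
    simulate_campaign,
)

MODEL_TABLE_COLUMNS = [
    "Pollutant", "Season", "Predictors", "Unit", "R2", "LOOCV", "df",
    "Beta", "Standard Error", "t", "p",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce a study end to end."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    truth: TruthModel = field(default_factory=default_truth_model)
    schedule: CampaignSchedule = field(default_factory=CampaignSchedule)
    n_gas: int = 41
    n_pm: int = 21
    dropout_rate: float = 0.025
    exclude_below_lod: bool = False
    pollutants: tuple[str, ...] = POLLUTANTS
    scopes: tuple[str, ...] = ("annual", "summer", "winter")
    gain: float = 0.01
    p_max: float = 0.1
    vif_max: float = 5.0
    quad_segs: int = 256  # circle fidelity for area/population buffers
    seed: int = 1

    def validate(self):
        self.scene.validate()
        if self.n_pm > self.n_gas:
            raise ConfigurationError("n_pm cannot exceed n_gas")
        bad = [p for p in self.pollutants if p not in self.truth.pollutants]
        if bad:
            raise ConfigurationError(f"pollutants without truth parameters: {bad}")
        for s in self.scopes:
            if s not in ("annual", "summer", "winter", "spring"):
                raise ConfigurationError(f"unknown scope {s!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        """Strict construction from plain data (e.g. parsed YAML); unknown
        keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "scene" in kwargs and isinstance(kwargs["scene"], dict):
            scene_known = {f.name for f in dataclasses.fields(SceneConfig)}
            bad = set(kwargs["scene"]) - scene_known
            if bad:
                raise ConfigurationError(f"unknown scene keys: {sorted(bad)}")
            sc = dict(kwargs["scene"])
            if "bounds" in sc:
                sc["bounds"] = tuple(sc["bounds"])
            kwargs["scene"] = SceneConfig(**sc)
        for key in ("pollutants", "scopes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load and validate a study configuration from a YAML file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (tuple, list, frozenset, set)):
                return [enc(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "isoformat"):
                return o.isoformat()
            return o

        payload = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    config: StudyConfig
    scene: object
    sites: list
    campaign: object
    qa: dict
    adjusted: pd.DataFrame
    matrix: object
    models: dict  # (pollutant, scope) -> LurModel
    descriptive_table: pd.DataFrame
    model_table: pd.DataFrame
    provenance: dict


def descriptive_statistics(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Adjusted concentrations summarized per pollutant and scope: N, mean,
    SD, min, max — the standard campaign summary layout."""
    rows = []
    scope_order = ["annual", "summer", "winter", "spring"]
    for pollutant in adjusted["pollutant"].unique():
        sub = adjusted[adjusted["pollutant"] == pollutant]
        for scope in scope_order:
            vals = sub.loc[sub["scope"] == scope, "value_ugm3"].to_numpy()
            if len(vals) == 0:
                continue
            rows.append(
                (
                    pollutant,
                    scope,
                    len(vals),
                    float(np.mean(vals)),
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    float(np.min(vals)),
                    float(np.max(vals)),
                )
            )
    return pd.DataFrame(
        rows, columns=["Pollutant", "Season", "N", "Mean", "SD", "Min", "Max"]
    )


def model_report(models: dict) -> pd.DataFrame:
    """Coefficient tables for a set of models, one block per model: the
    intercept row carries the model-level statistics (R², LOOCV R², residual
    df), coefficient rows follow in selection order."""
    rows = []
    for (pollutant, scope), m in models.items():
        unit_by_name = {s.name: s.units for s in m.specs}
        rows.append(
            {
                "Pollutant": pollutant,
                "Season": scope,
                "Predictors": "Intercept",
                "Unit": "-",
                "R2": round(float(m.fit.r2), 3) if np.isfinite(m.fit.r2) else np.nan,
                "LOOCV": round(float(m.loocv_r2), 3) if np.isfinite(m.loocv_r2) else np.nan,
                "df": m.fit.df_resid,
                "Beta": m.intercept,
                "Standard Error": float(m.fit.bse["const"]),
                "t": float(m.fit.tvalues["const"]),
                "p": float(m.fit.pvalues["const"]),
            }
        )
        for name in m.predictor_names:
            rows.append(
                {
                    "Pollutant": pollutant,
                    "Season": scope,
                    "Predictors": name,
                    "Unit": unit_by_name.get(name, ""),
                    "R2": np.nan,
                    "LOOCV": np.nan,
                    "df": np.nan,
                    "Beta": float(m.fit.params[name]),
                    "Standard Error": float(m.fit.bse[name]),
                    "t": float(m.fit.tvalues[name]),
                    "p": float(m.fit.pvalues[name]),
                }
            )
    return pd.DataFrame(rows, columns=MODEL_TABLE_COLUMNS)


def report_tables(models: dict, adjusted: pd.DataFrame):
    """Formatted outputs: (descriptive statistics, model coefficient table)."""
    return descriptive_statistics(adjusted), model_report(models)


def run_study(config: StudyConfig | None = None, seed: int | None = None,
              out_dir: str | Path | None = None) -> StudyResult:
    """Run the complete study and (optionally) write its outputs.

    Stages: synthetic scene -> site placement -> campaign simulation -> QA ->
    reference adjustment -> predictor matrix -> supervised selection per
    pollutant x scope -> report tables. Deterministic for fixed (config,
    seed).
    """
    config = config or StudyConfig()
    config.validate()
    seed = config.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    s_sites, s_campaign = ss.spawn(2)

    scene = generate_city(config.scene, seed)
    sites = place_sites(scene, config.n_gas, config.n_pm, seed=np.random.default_rng(s_sites).integers(2**31))
    campaign = simulate_campaign(
        scene,
        config.truth,
        sites,
        schedule=config.schedule,
        seed=s_campaign,
        dropout_rate=config.dropout_rate,
    )
    cleaned, qa = apply_qa(campaign.records, exclude_below_lod=config.exclude_below_lod)
    # table scopes always include spring for the campaign summary
    table_scopes = tuple(dict.fromkeys(tuple(config.scopes) + ("spring",)))
    adjusted = adjust_all(cleaned, campaign.references, scopes=table_scopes)

    matrix = build_predictor_matrix(sites, scene, default_predictor_grid(),
                                    quad_segs=config.quad_segs)

    models: dict[tuple[str, str], LurModel] = {}
    for pollutant in config.pollutants:
        for scope in config.scopes:
            sub = adjusted[(adjusted["pollutant"] == pollutant) & (adjusted["scope"] == scope)]
            sub = sub.set_index("site_id").reindex(matrix.data.index).dropna(subset=["value_ugm3"])
            X = matrix.data.loc[sub.index]
            from .geo_predictors import PredictorMatrix

            sub_matrix = PredictorMatrix(X, matrix.specs, dict(matrix.provenance))
            models[(pollutant, scope)] = supervised_forward_select(
                sub["value_ugm3"].to_numpy(),
                sub_matrix,
                gain=config.gain,
                p_max=config.p_max,
                vif_max=config.vif_max,
                pollutant=pollutant,
                scope=scope,
            )

    descriptive, model_table = report_tables(models, adjusted)
    provenance = {
        "config_hash": config.hash(),
        "seed": seed,
        "version": _pkg_version,
        "n_sites_gas": sum(1 for s in sites if "gas" in s.measures),
        "n_sites_pm": sum(1 for s in sites if "pm" in s.measures),
        "excluded": {p: q.excluded for p, q in qa.items()},
    }
    result = StudyResult(
        config, scene, sites, campaign, qa, adjusted, matrix, models,
        descriptive, model_table, provenance,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: StudyResult, out_dir: Path):
    """Write the study bundle as plain-text files, each stamped with the
    config hash and seed so outputs are traceable to their inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"# airlur {result.provenance['version']} config={result.provenance['config_hash']} seed={result.provenance['seed']}\n"

    def write_csv(df: pd.DataFrame, name: str, **kw):
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, index=False, **kw)

    write_csv(result.adjusted, "adjusted_concentrations.csv")
    write_csv(result.descriptive_table, "descriptive_statistics.csv")
    write_csv(result.model_table, "model_tables.csv")
    mdf = result.matrix.data.reset_index()
    write_csv(mdf, "predictor_matrix.csv")
    specs = [dataclasses.asdict(s) for s in result.matrix.specs]
    (out_dir / "predictor_specs.json").write_text(json.dumps(specs, indent=1))
    (out_dir / "qa.json").write_text(
        json.dumps({p: q.to_dict() for p, q in result.qa.items()}, indent=1)
    )
    with open(out_dir / "selection_log.jsonl", "w") as fh:
        for key, m in result.models.items():
            for entry in m.selection_log:
                fh.write(json.dumps({"model": list(key), **entry}, default=str) + "\n")
    (out_dir / "provenance.json").write_text(json.dumps(result.provenance, indent=1))


def predict_surfaces(result: StudyResult, cell_size: float = 1000.0,
                     scopes=("annual",)) -> dict:
    """Exposure surfaces for every model in the study at a given resolution."""
    out = {}
    for (pollutant, scope), m in result.models.items():
        if scope not in scopes:
            continue
        out[(pollutant, scope)] = rasterize(
            m, result.scene, cell_size, quad_segs=result.config.quad_segs
        )
    return out
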