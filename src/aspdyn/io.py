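"""Shared CSV schema validation, run configuration and pipeline dispatch.

CSV is the single interchange format (the instruments export tabular
data): UTF-8, mandatory header row, units embedded in the column names
(time_h, concentration_uM, ...).  Every pipeline run writes a provenance
record (config plus package version) beside its outputs so results can be
traced back to their inputs and parameters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("aspdyn")

__all__ = ["SCHEMAS", "RunConfig", "validate_schema", "run_pipeline", "write_provenance"]


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    non_negative: bool = False


#: Registered CSV schemas: required columns and basic value constraints.
SCHEMAS: dict[str, list[ColumnSpec]] = {
    "biosensor": [
        ColumnSpec("well_id"),
        ColumnSpec("condition"),
        ColumnSpec("time_h"),
        ColumnSpec("gfp", non_negative=True),
        ColumnSpec("rfp", non_negative=True),
        ColumnSpec("nuclei", non_negative=True),
    ],
    "media": [
        ColumnSpec("time_h"),
        ColumnSpec("concentration_uM", non_negative=True),
        ColumnSpec("media_volume_ml", non_negative=True),
    ],
    "growth": [
        ColumnSpec("time_h"),
        ColumnSpec("cell_volume_ul", non_negative=True),
    ],
    "composition": [
        ColumnSpec("compound"),
        ColumnSpec("concentration_mM", non_negative=True),
        ColumnSpec("pool_type"),
    ],
    "isotopologue": [
        ColumnSpec("compound"),
        ColumnSpec("tracer"),
        ColumnSpec("m_index", non_negative=True),
        ColumnSpec("fraction", non_negative=True),
    ],
    "calibration": [
        ColumnSpec("compound"),
        ColumnSpec("concentration_uM", non_negative=True),
        ColumnSpec("response_ratio", non_negative=True),
    ],
    "quant": [
        ColumnSpec("compound"),
        ColumnSpec("area", non_negative=True),
        ColumnSpec("is_area", non_negative=True),
    ],
}

_TEXT_COLUMNS = {"well_id", "condition", "compound", "pool_type", "tracer"}


class SchemaError(ValueError):
    """A CSV file violates its registered schema."""


def validate_schema(path, schema: str) -> pd.DataFrame:
    """Read a CSV and check it against a registered schema.

    Checks column presence, numeric parsability of value columns, and
    non-negativity where the schema requires it; errors cite the offending
    column and row numbers (1-based, excluding the header).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; registered: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    problems: list[str] = []
    for col in SCHEMAS[schema]:
        if col.name not in frame.columns:
            problems.append(f"missing column {col.name!r}")
            continue
        if col.name in _TEXT_COLUMNS:
            continue
        values = pd.to_numeric(frame[col.name], errors="coerce")
        bad = frame.index[values.isna() & frame[col.name].notna()]
        if len(bad):
            problems.append(f"column {col.name!r}: non-numeric values at rows {_rows(bad)}")
            continue
        frame[col.name] = values
        if col.non_negative:
            neg = frame.index[values < 0]
            if len(neg):
                problems.append(f"column {col.name!r}: negative values at rows {_rows(neg)}")
    if problems:
        raise SchemaError(f"{path.name} failed schema {schema!r}: " + "; ".join(problems))
    return frame


def _rows(index) -> str:
    shown = [str(i + 1) for i in list(index)[:5]]
    suffix = ", ..." if len(index) > 5 else ""
    return ", ".join(shown) + suffix


# ---------------------------------------------------------------------------
# Pipeline configuration and dispatch

_STAGES = ("simulate", "fit-rates", "flux", "budget", "tracing", "quantify", "synth")
_CONFIG_KEYS = {"stage", "inputs", "out_dir", "params", "seed", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation: a stage, its inputs and parameter overrides."""

    stage: str
    out_dir: str = "."
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; available: {', '.join(_STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_provenance(out_dir: Path, config: RunConfig, extra: dict | None = None) -> Path:
    from . import __version__

    record = {
        "package": "aspdyn",
        "version": __version__,
        "config": asdict(config),
        **(extra or {}),
    }
    path = Path(out_dir) / f"{config.stage.replace('-', '_')}_provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: RunConfig) -> list[Path]:
    """Dispatch a stage and return the paths of the artifacts written.

    Deterministic: identical configs and inputs produce byte-identical
    outputs.  Stage timings are logged at INFO level.
    """
    logging.basicConfig(level=config.log_level.upper(), format="%(name)s %(levelname)s %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    runner = _STAGE_RUNNERS[config.stage]
    artifacts = runner(config, out_dir)
    artifacts.append(write_provenance(out_dir, config))
    logger.info("stage %s finished in %.2f s", config.stage, time.perf_counter() - t_start)
    return artifacts


def _float_params(config: RunConfig, **defaults) -> dict:
    out = dict(defaults)
    for key, value in config.params.items():
        if key not in defaults:
            raise ValueError(f"unknown parameter {key!r} for stage {config.stage!r}")
        out[key] = type(defaults[key])(value) if defaults[key] is not None else value
    return out


def _write_csv(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def _run_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    from .model import ModelParams, simulate

    opts = dict(config.params)
    preset = opts.pop("preset", "vehicle")
    t_end = float(opts.pop("t_end", 72.0))
    dt_report = float(opts.pop("dt_report", 0.5))
    params = ModelParams().with_overrides(**{k: float(v) for k, v in opts.items()})
    traj = simulate(params, preset, t_end=t_end, dt_report=dt_report)
    return [_write_csv(traj.to_frame(), out_dir / f"trajectory_{preset}.csv")]


def _run_fit_rates(config: RunConfig, out_dir: Path) -> list[Path]:
    from .timecourse import (
        characterize_rebound,
        normalize_trace,
        read_biosensor_csv,
        traces_to_frame,
        windowed_rates,
    )

    opts = _float_params(config, window_h=6.0, pretreat_norm=1.0, smooth_width=3.0)
    validate_schema(config.inputs["biosensor"], "biosensor")
    traces = read_biosensor_csv(config.inputs["biosensor"])
    normalized, rate_rows, rebound_rows = [], [], []
    for trace in traces:
        tr = normalize_trace(trace, pretreat_norm=bool(opts["pretreat_norm"]))
        normalized.append(tr)
        rates = windowed_rates(tr, window_h=opts["window_h"])
        for start, rate in zip(rates.window_starts, rates.rates):
            rate_rows.append(
                {"well_id": tr.well_id, "condition": tr.condition,
                 "window_start_h": start, "rate_doublings_per_day": rate}
            )
        desc = characterize_rebound(tr.times, tr.ratio_norm, smooth_width=int(opts["smooth_width"]))
        rebound_rows.append(
            {"well_id": tr.well_id, "condition": tr.condition, "t_nadir_h": desc.t_nadir,
             "nadir_value": desc.nadir_value, "rebound_fraction": desc.rebound_fraction,
             "monotonic": desc.monotonic}
        )
    return [
        _write_csv(traces_to_frame(normalized), out_dir / "biosensor_normalized.csv"),
        _write_csv(pd.DataFrame(rate_rows), out_dir / "windowed_rates.csv"),
        _write_csv(pd.DataFrame(rebound_rows), out_dir / "rebound_descriptors.csv"),
    ]


def _run_flux(config: RunConfig, out_dir: Path) -> list[Path]:
    from .exchange import MediaSeries, estimate_exchange_flux, fit_growth

    opts = _float_params(config, initial_rate=0.0)
    media_frame = validate_schema(config.inputs["media"], "media")
    growth_frame = validate_schema(config.inputs["growth"], "growth")
    growth = fit_growth(growth_frame["time_h"], growth_frame["cell_volume_ul"])
    media = MediaSeries(
        times=media_frame["time_h"].to_numpy(),
        concentration=media_frame["concentration_uM"].to_numpy(),
        media_volume=media_frame["media_volume_ml"].to_numpy(),
    )
    flux = estimate_exchange_flux(media, growth, initial_rate=bool(opts["initial_rate"]))
    result = pd.DataFrame(
        [{"flux_mM_per_h_uptake_positive": flux, "mu_per_h": growth.mu, "V0_uL": growth.V0}]
    )
    return [_write_csv(result, out_dir / "exchange_flux.csv")]


def _run_budget(config: RunConfig, out_dir: Path) -> list[Path]:
    from .budget import CompositionTable, build_budget

    opts = _float_params(
        config, K_per_day=1.0, asn_prot_flux=0.0, asn_efflux=0.0, purine_rule=1.0
    )
    comp = CompositionTable(validate_schema(config.inputs["composition"], "composition"))
    result = build_budget(
        comp,
        K_per_h=opts["K_per_day"] / 24.0,
        asn_prot_flux=opts["asn_prot_flux"],
        asn_efflux=opts["asn_efflux"],
        purine_rule=bool(opts["purine_rule"]),
    )
    series = result.as_series()
    logger.info("aspartate fate budget (mM/h, uptake-positive):\n%s", series.to_string())
    return [_write_csv(series.rename_axis("fate").reset_index(), out_dir / "fate_budget.csv")]


def _run_tracing(config: RunConfig, out_dir: Path) -> list[Path]:
    from .isotopes import (
        IsotopologueDistribution,
        guanine_salvage_fraction,
        purine_salvage_fraction_atp,
    )

    frame = validate_schema(config.inputs["isotopologue"], "isotopologue")
    rows = []
    for (compound, tracer), grp in frame.groupby(["compound", "tracer"]):
        grp = grp.sort_values("m_index")
        dist = IsotopologueDistribution(
            compound=compound, tracer=tracer, fractions=grp["fraction"].to_numpy()
        )
        if tracer != "amide-15N-Gln":
            continue
        if compound.upper() == "GTP":
            rows.append({"compound": compound, "estimator": "guanine_salvage",
                         "salvage_fraction": guanine_salvage_fraction(dist)})
        elif compound.upper() == "ATP":
            rows.append({"compound": compound, "estimator": "purine_salvage",
                         "salvage_fraction": purine_salvage_fraction_atp(dist)})
    if not rows:
        raise ValueError("no GTP/ATP rows under the amide-15N-Gln tracer in the input")
    return [_write_csv(pd.DataFrame(rows), out_dir / "salvage_fractions.csv")]


def _run_quantify(config: RunConfig, out_dir: Path) -> list[Path]:
    from .isotopes import fit_calibration, quantify

    opts = _float_params(config, reconstitution_volume_uL=40.0, total_cell_volume_uL=1.0)
    calib = validate_schema(config.inputs["calibration"], "calibration")
    quant = validate_schema(config.inputs["quant"], "quant")
    curves = {
        compound: fit_calibration(grp["concentration_uM"], grp["response_ratio"])
        for compound, grp in calib.groupby("compound")
    }
    rows = []
    for _, row in quant.iterrows():
        compound = row["compound"]
        if compound not in curves:
            raise ValueError(f"no calibration curve for compound {compound!r}")
        res = quantify(
            row["area"], row["is_area"], curves[compound],
            reconstitution_volume_uL=opts["reconstitution_volume_uL"],
            total_cell_volume_uL=opts["total_cell_volume_uL"],
        )
        rows.append({"compound": compound, "model": curves[compound].model,
                     "vial_concentration_uM": res.vial_concentration_uM,
                     "intracellular_mM": res.intracellular_mM, "in_range": res.in_range})
    return [_write_csv(pd.DataFrame(rows), out_dir / "quantification.csv")]


def _run_synth(config: RunConfig, out_dir: Path) -> list[Path]:
    from .isotopes import CalibrationCurve
    from .model import simulate
    from .synth import (
        GeneratorSpec,
        gen_biosensor,
        gen_calibration,
        gen_composition,
        gen_isotopologues,
        gen_media_series,
    )
    from .timecourse import traces_to_frame

    what = config.params.get("what", "biosensor")
    spec = GeneratorSpec(seed=config.seed)
    if what == "biosensor":
        traj = simulate(scenario="aa5")
        frame = traces_to_frame(gen_biosensor(traj, spec, condition="aa5"))
        return [_write_csv(frame, out_dir / "synthetic_biosensor.csv")]
    if what == "media":
        series, growth = gen_media_series(
            true_flux=2.0, mu=np.log(2) / 24.0, evaporation_rate=0.01,
            times=np.array([0.0, 8.0, 16.0, 24.0]), spec=spec,
        )
        frames = []
        for i, ms in enumerate(series):
            frames.append(pd.DataFrame({"replicate": i + 1, "time_h": ms.times,
                                        "concentration_uM": ms.concentration,
                                        "media_volume_ml": ms.media_volume}))
        growth_frame = pd.DataFrame(
            {"time_h": [0.0, 24.0], "cell_volume_ul": [growth.V0, growth.volume(24.0)]}
        )
        return [
            _write_csv(pd.concat(frames, ignore_index=True), out_dir / "synthetic_media.csv"),
            _write_csv(growth_frame, out_dir / "synthetic_growth.csv"),
        ]
    if what == "tracing":
        rows = []
        for compound, salvage in (("GTP", 0.25), ("ATP", 0.3)):
            dist = gen_isotopologues(salvage, "amide-15N-Gln", compound, 10**5, spec)
            for m, frac in enumerate(dist.fractions):
                rows.append({"compound": compound, "tracer": dist.tracer,
                             "m_index": m, "fraction": frac})
        return [_write_csv(pd.DataFrame(rows), out_dir / "synthetic_isotopologues.csv")]
    if what == "calibration":
        truth = CalibrationCurve(model="linear", params=(0.1, 0.0), valid_range=(0.244, 500.0))
        frame = gen_calibration(truth, spec)
        frame.insert(0, "compound", "aspartate")
        return [_write_csv(frame, out_dir / "synthetic_calibration.csv")]
    if what == "composition":
        comp, truth = gen_composition(10.0, 1.0 / 24.0, spec)
        path = _write_csv(comp.table, out_dir / "synthetic_composition.csv")
        truth_path = out_dir / "synthetic_composition_truth.json"
        truth_path.write_text(json.dumps(truth, indent=2) + "\n")
        return [path, truth_path]
    raise ValueError(f"unknown synth target {what!r}")


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "fit-rates": _run_fit_rates,
    "flux": _run_flux,
    "budget": _run_budget,
    "tracing": _run_tracing,
    "quantify": _run_quantify,
    "synth": _run_synth,
}
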