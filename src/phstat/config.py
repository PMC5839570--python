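"""Experiment configuration: one YAML file describes a complete run.

Sections: ``ocr`` (threshold + digit geometry), ``pump`` (exactly one
active dosing pump with its calibration), ``control`` (setpoint and
dosing parameters), ``plant`` (simulation scenario; hardware transports
would go here instead), plus output path and seed.  Defaults mirror the
reference operating point (setpoint 10.55, 2 ml unit volume, 5 s
interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .controller import ControlConfig
from .exceptions import ConfigError
from .ocr import OcrCalibration, SegmentGeometry
from .pumps import PeristalticPumpSpec, SyringePumpSpec

__all__ = ["ExperimentConfig", "load_config", "default_config_dict"]


@dataclass
class ExperimentConfig:
    ocr: OcrCalibration
    pump_type: str
    pump_spec: SyringePumpSpec | PeristalticPumpSpec
    control: ControlConfig
    scenario: str
    scenario_options: dict
    reagent_molarity: float = 0.5
    duration_s: float = 10800.0
    seed: int = 0
    output: str = "phstat_log.csv"


def default_config_dict() -> dict:
    """A complete example configuration (the reference simulation)."""
    return {
        "seed": 0,
        "duration_s": 10800,
        "output": "phstat_log.csv",
        "ocr": {
            "threshold": 128,
            "on_fraction": 0.5,
            "geometry": {
                "anchor_row": 4, "anchor_col": 4,
                "digit_width": 12, "digit_height": 20, "digit_pitch": 17,
                "n_digits": 5, "decimal_index": 2,
            },
        },
        "pump": {
            "type": "peristaltic",
            "reagent_molarity": 0.5,
            "spec": {"coefficient": 8.167e-4, "dead_time": 0.0,
                     "min_reliable_dose": 0.5, "supply_voltage_tag": "12V"},
        },
        "control": {
            "setpoint": 10.55, "initial_unit_volume": 2.0,
            "min_interval": 5.0, "unit_volume_floor": 0.5,
            "interval_cap": 60.0, "stale_timeout": 10.0, "log_period": 1.0,
        },
        "plant": {"scenario": "tempo_default", "options": {}},
    }


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing {key!r} in {where}")
    return mapping[key]


def _build(cls, payload: dict, where: str):
    try:
        return cls(**payload)
    except TypeError as e:
        raise ConfigError(f"bad {where}: {e}") from None
    except ValueError as e:
        raise ConfigError(f"invalid {where}: {e}") from None


def parse_config(doc: dict) -> ExperimentConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")

    ocr_doc = dict(_require(doc, "ocr", "configuration"))
    geo = _build(SegmentGeometry, _require(ocr_doc, "geometry", "ocr"),
                 "ocr.geometry")
    cal = _build(OcrCalibration,
                 {"threshold": _require(ocr_doc, "threshold", "ocr"),
                  "geometry": geo,
                  "on_fraction": ocr_doc.get("on_fraction", 0.5)}, "ocr")

    pump_doc = dict(_require(doc, "pump", "configuration"))
    pump_type = _require(pump_doc, "type", "pump")
    spec_doc = _require(pump_doc, "spec", "pump")
    if pump_type == "peristaltic":
        spec = _build(PeristalticPumpSpec, spec_doc, "pump.spec")
    elif pump_type == "syringe":
        spec = _build(SyringePumpSpec, spec_doc, "pump.spec")
    else:
        raise ConfigError(f"unknown pump type {pump_type!r}; exactly one "
                          "of 'peristaltic' or 'syringe' must be active")

    control = _build(ControlConfig, doc.get("control", {}), "control")

    plant_doc = dict(doc.get("plant", {"scenario": "tempo_default"}))
    scenario = _require(plant_doc, "scenario", "plant")

    return ExperimentConfig(
        ocr=cal,
        pump_type=pump_type,
        pump_spec=spec,
        control=control,
        scenario=scenario,
        scenario_options=dict(plant_doc.get("options", {})),
        reagent_molarity=float(pump_doc.get("reagent_molarity", 0.5)),
        duration_s=float(doc.get("duration_s", 10800.0)),
        seed=int(doc.get("seed", 0)),
        output=str(doc.get("output", "phstat_log.csv")),
    )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)
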