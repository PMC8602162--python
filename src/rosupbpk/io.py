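"""Configuration loading/validation and tabular I/O.

Model configuration is a single YAML document with blocks ``physiology`` /
``compound`` / ``processes``; perpetrator configuration holds per-drug ``pk``
and ``inhibition`` blocks.  All numeric keys carry explicit units in their
names (snake_case); unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .compound import ActiveProcess, CompoundParams
from .ddi import InhibitionSpec, PerpetratorModel
from .model import PBPKModel
from .physiology import Physiology

OBSERVATION_COLUMNS = [
    "subject_id", "study_id", "arm", "time_h", "conc_ng_per_ml", "dose_mg", "route",
]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed, context: str):
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {context} (expected one of {sorted(allowed)})")


def _build(cls, block: dict, context: str, extra_allowed=()):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, fields | set(extra_allowed), context)
    kwargs = {k: v for k, v in block.items() if k in fields}
    for k, v in list(kwargs.items()):
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_model_config(path) -> PBPKModel:
    """Assemble a PBPK model from a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("model configuration must be a mapping")
    _check_keys(raw, {"physiology", "compound", "processes", "metadata"}, "model config")
    for block in ("physiology", "compound", "processes"):
        if block not in raw:
            raise ConfigError(f"missing required block {block!r}")
    physiology = _build(Physiology, raw["physiology"], "physiology block")
    compound = _build(CompoundParams, raw["compound"], "compound block")
    processes = []
    for i, p in enumerate(raw["processes"]):
        context = f"process #{i + 1} ({p.get('name', '?')})"
        for required in ("name", "kind", "organ_site", "km_umol_per_l", "vmax_scaled_umol_per_h"):
            if required not in p:
                raise ConfigError(f"{context}: missing key {required!r}")
        processes.append(_build(ActiveProcess, p, context, extra_allowed=("provenance",)))
    return PBPKModel(physiology, compound, tuple(processes))


def dump_model_config(model: PBPKModel, path) -> None:
    def clean(obj):
        d = dataclasses.asdict(obj)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    doc = {
        "physiology": clean(model.physiology),
        "compound": clean(model.compound),
        "processes": [clean(p) for p in model.processes],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_perpetrator_config(path):
    """Load perpetrator PK models and their inhibition specs.

    Returns ``(perpetrators, specs)`` where ``perpetrators`` maps drug name to
    :class:`PerpetratorModel` and ``specs`` maps drug name to the list of
    :class:`InhibitionSpec` entries for that drug and its linked metabolite.
    """
    raw = yaml.safe_load(Path(path).read_text())
    perpetrators, specs = {}, {}
    for name, block in raw.items():
        _check_keys(block, {"pk", "inhibition"}, f"perpetrator {name!r}")
        pk = dict(block.get("pk", {}))
        pk.setdefault("name", name)
        perpetrators[name] = _build(PerpetratorModel, pk, f"perpetrator {name!r} pk")
        entries = []
        for e in block.get("inhibition", []):
            _check_keys(
                e, {"perpetrator", "target_process", "ki_umol_per_l", "provenance"},
                f"inhibition entry of {name!r}",
            )
            entries.append(
                InhibitionSpec(
                    e.get("perpetrator", name), e["target_process"], e["ki_umol_per_l"]
                )
            )
        specs[name] = entries
    return perpetrators, specs


# --------------------------------------------------------------------------
# Packaged defaults
# --------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("rosupbpk.data") / filename


def load_default_model() -> PBPKModel:
    """The shipped calibrated rosuvastatin model."""
    with resources.as_file(_data_path("rosuvastatin.yaml")) as p:
        return load_model_config(p)


def load_default_perpetrators():
    with resources.as_file(_data_path("perpetrators.yaml")) as p:
        return load_perpetrator_config(p)


# --------------------------------------------------------------------------
# Observation tables
# --------------------------------------------------------------------------

def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"observations file missing columns: {missing}")
    return df


def write_observations(records_or_frame, path) -> None:
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
    else:
        from .synthetic import records_to_frame

        df = records_to_frame(records_or_frame)
    df.to_csv(path, index=False)
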