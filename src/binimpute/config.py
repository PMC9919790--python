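"""YAML configuration for the CLI: synth, experiment and imputer sections."""

from __future__ import annotations

import datetime as _dt

import yaml

from .binning import TOTAL
from .evaluation import ExperimentConfig
from .synthetic import SynthConfig


def _parse_bins(bins):
    out = []
    for b in bins:
        if isinstance(b, str) and b.strip().lower() == TOTAL:
            out.append(TOTAL)
        else:
            out.append(int(b))
    return out


def synth_config_from_dict(d: dict) -> SynthConfig:
    d = dict(d or {})
    for key in ("sleep_window", "active_window"):
        if key in d:
            d[key] = tuple(int(x) for x in d[key])
    if "start_date" in d and not isinstance(d["start_date"], _dt.date):
        d["start_date"] = _dt.date.fromisoformat(str(d["start_date"]))
    return SynthConfig(**d)


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d or {})
    if "frames" in d:
        d["frames"] = [tuple(int(x) for x in f) for f in d["frames"]]
    if "bins" in d:
        d["bins"] = _parse_bins(d["bins"])
    if "imputers" in d:  # accept both spellings
        d["imputer_options"] = d.pop("imputers")
    return ExperimentConfig(**d)


def load_config(path):
    """Read a YAML config file into (SynthConfig, ExperimentConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return (
        synth_config_from_dict(raw.get("synth", {})),
        experiment_config_from_dict(raw.get("experiment", {})),
    )
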