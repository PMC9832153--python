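"""Validated readers and writers for the package's plain-text tables.

Everything is delimited text (CSV with a header, ISO-8601 dates) or
JSON/YAML structured documents, so all artifacts diff cleanly and round-trip
losslessly at documented precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import PanelValidationError
from .estimator import validate_panel, WithinDayProfile
from .synth import SyntheticConfig, TruthRecord
from .timeshift import DailyQuantityCurve

PANEL_FLOAT_FORMAT = "%.6g"


def read_panel(path: str | Path, covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read and schema-validate a VisitPanel table."""
    path = Path(path)
    panel = pd.read_csv(path)
    if "date" not in panel.columns:
        raise PanelValidationError("panel file lacks a 'date' column")
    panel["date"] = pd.to_datetime(panel["date"])
    validate_panel(panel, covariates)
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=PANEL_FLOAT_FORMAT)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(truth.to_dict(), sort_keys=True))
    return path


def load_synth_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SyntheticConfig.from_dict(data)


def dump_synth_config(config: SyntheticConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def write_profile(profile: WithinDayProfile, path: str | Path) -> Path:
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    return path


def read_profile(path: str | Path) -> WithinDayProfile:
    return WithinDayProfile.from_frame(pd.read_csv(path))


def write_quantity_curve(curve: DailyQuantityCurve, path: str | Path) -> Path:
    return write_json(curve.to_dict(), path)


def read_quantity_curve(path: str | Path) -> DailyQuantityCurve:
    return DailyQuantityCurve.from_dict(read_json(path))


def read_deltas(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"model", "cell", "month", "delta"} - set(df.columns)
    if missing:
        raise PanelValidationError(f"delta table missing columns {sorted(missing)}")
    return df


def read_baseline(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell", "month", "hour", "temperature"} - set(df.columns)
    if missing:
        raise PanelValidationError(f"baseline table missing columns {sorted(missing)}")
    return df
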