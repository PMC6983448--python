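"""Reading and writing the package's delimited-text tables and YAML configs.

All tables are UTF-8 comma-separated with a header row: the condition catalog
(one condition per row), populations (one enrollee per row, condition
indicators as wide 0/1 columns named by condition id) and matched sets (long
form, one member per row).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .config import GeneratorConfig


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"condition_id": str})


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str})
    if "child_cf_birth_month" in df.columns:
        df["child_cf_birth_month"] = df["child_cf_birth_month"].astype("Int64")
    for col in ("screened_flag", "suspicion_flag"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_sets(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"set_id": str, "subject_id": str})
    if "short_set" in df.columns:
        df["short_set"] = df["short_set"].astype(bool)
    return df


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(data)


def save_config(config: GeneratorConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
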