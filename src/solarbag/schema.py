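"""Column schema of the 14-feature observation table.

One row is one (timestamp x treatment) observation: seven weather-station
readings, four one-hot treatment flags, the mixing/stacking flag, the rain
flag, and the binary effectiveness class label.
"""

from __future__ import annotations

import pandas as pd

#: The four mutually exclusive treatment flags (grain mass / wood box).
TREATMENT_COLUMNS = ["kg16_box", "kg21_box", "kg25_box", "kg21_no_box"]

#: Binary columns (copied, never interpolated, by SMOTE).
BINARY_COLUMNS = TREATMENT_COLUMNS + ["mixing_stacking", "rain"]

#: Continuous weather/environment predictors.
CONTINUOUS_COLUMNS = [
    "air_rh_pct",
    "ambient_temp_C",
    "solar_radiation_MJ_m2",
    "solar_flux_KJ_m2",
    "wind_speed_m_s",
    "air_pressure_kPa",
    "wind_direction_deg",
]

LABEL_COLUMN = "class_label"

#: All 13 predictors, in canonical order.
FEATURE_COLUMNS = [
    "kg16_box",
    "air_rh_pct",
    "ambient_temp_C",
    "kg21_no_box",
    "solar_radiation_MJ_m2",
    "solar_flux_KJ_m2",
    "wind_speed_m_s",
    "mixing_stacking",
    "air_pressure_kPa",
    "kg21_box",
    "wind_direction_deg",
    "kg25_box",
    "rain",
]

#: Full 14-column table schema.
ALL_COLUMNS = FEATURE_COLUMNS + [LABEL_COLUMN]


class SchemaError(ValueError):
    """A feature table violates the 14-column schema or its invariants."""


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature table against the canonical schema.

    Checks column presence, the one-hot treatment invariant, the binary
    label, RH within [0, 100] and wind direction within [0, 360).

    Returns the table with columns reordered canonically.

    Raises
    ------
    SchemaError
        with a detailed column diff or the first violated invariant.
    """
    missing = [c for c in ALL_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in ALL_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"column mismatch: missing={missing!r}, unexpected={extra!r}; "
            f"expected the 14 columns {ALL_COLUMNS!r}"
        )
    onehot = table[TREATMENT_COLUMNS].to_numpy()
    if not set(onehot.ravel().tolist()) <= {0, 1}:
        raise SchemaError("treatment flags must be 0/1")
    rowsum = onehot.sum(axis=1)
    bad = (rowsum != 1).nonzero()[0]
    if bad.size:
        raise SchemaError(
            f"one-hot treatment invariant violated on {bad.size} rows "
            f"(first offending row index {int(bad[0])})"
        )
    labels = set(pd.unique(table[LABEL_COLUMN]).tolist())
    if not labels <= {0, 1}:
        raise SchemaError(f"class_label must be binary 0/1, found {sorted(labels)}")
    rh = table["air_rh_pct"]
    if (rh < 0).any() or (rh > 100).any():
        raise SchemaError("air_rh_pct outside [0, 100]")
    wd = table["wind_direction_deg"]
    if (wd < 0).any() or (wd >= 360).any():
        raise SchemaError("wind_direction_deg outside [0, 360)")
    return table[ALL_COLUMNS]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV plus a ``.schema.json`` sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    validate_feature_table(table).to_csv(path, index=False)
    sidecar = {
        "columns": ALL_COLUMNS,
        "binary": BINARY_COLUMNS,
        "continuous": CONTINUOUS_COLUMNS,
        "label": LABEL_COLUMN,
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a feature-table CSV."""
    return validate_feature_table(pd.read_csv(path))
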