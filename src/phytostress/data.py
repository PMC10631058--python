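"""Canonical feature vocabulary and the in-memory feature table.

The tabular layout mirrors the experiment's raw-data sheet: one row per
pot x time-point, identifier columns first, then the 13 feature columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

MORPHOLOGICAL_FEATURES: tuple[str, ...] = ("entropy", "energy", "homogeneity")
PHYSIOLOGICAL_FEATURES: tuple[str, ...] = ("RWC", "CI", "CA", "AC", "PhC", "PC")
MIRNA_FEATURES: tuple[str, ...] = ("miR-156a", "miR-166i", "miR-399g", "miR-477b")

FEATURES: tuple[str, ...] = MORPHOLOGICAL_FEATURES + PHYSIOLOGICAL_FEATURES + MIRNA_FEATURES

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "morphological": MORPHOLOGICAL_FEATURES,
    "physiological": PHYSIOLOGICAL_FEATURES,
    "mirna": MIRNA_FEATURES,
    "all": FEATURES,
}

ID_COLUMNS: tuple[str, ...] = (
    "pot_id",
    "replicate",
    "time_point",
    "drought_level",
    "salinity_level",
)

#: nucleotide sequences of the assayed miRNAs (metadata only; never used numerically)
MIRNA_SEQUENCES: dict[str, str] = {
    "miR-156a": "UGACAGAAGAGAGUGAGCAC",
    "miR-166i": "UCGGACCAGGCUUCAUUCUC",
    "miR-399g": "AGGGCUUCUCUCCAUUGGCAGG",
    "miR-477b": "CUCUCCCUCAAAGGCUUCUG",
}


def parse_level_label(label: object, prefix: str) -> int:
    """Map a treatment label like ``W2``/``S3`` (or a bare integer) to 0..3."""
    if isinstance(label, (int, np.integer)):
        value = int(label)
    else:
        text = str(label).strip()
        if text.upper().startswith(prefix.upper()):
            text = text[len(prefix):]
        try:
            value = int(text)
        except ValueError:
            raise SchemaError(f"cannot parse {prefix!r} level label {label!r}") from None
    if not 0 <= value <= 3:
        raise SchemaError(f"severity level {value} out of range 0..3 for label {label!r}")
    return value


@dataclass
class FeatureTable:
    """Validated feature table with integer severity labels per row.

    ``frame`` holds the identifier columns, integer severities ``w`` and
    ``s``, and one column per feature in :data:`FEATURES` order.
    """

    frame: pd.DataFrame
    features: tuple[str, ...] = field(default=FEATURES)

    def __post_init__(self) -> None:
        missing = [c for c in self.features if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"feature table missing columns: {missing}")
        for col in ("w", "s"):
            if col not in self.frame.columns:
                raise SchemaError(f"feature table missing severity column {col!r}")
        if len(set(self.features)) != len(self.features):
            raise SchemaError("duplicate feature names")
        bad = ~self.frame["w"].isin(range(4)) | ~self.frame["s"].isin(range(4))
        if bad.any():
            raise SchemaError(f"{int(bad.sum())} rows with severity outside 0..3")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame.loc[:, list(self.features)]

    @property
    def w(self) -> np.ndarray:
        return self.frame["w"].to_numpy(dtype=float)

    @property
    def s(self) -> np.ndarray:
        return self.frame["s"].to_numpy(dtype=float)

    def subset_features(self, names: list[str] | tuple[str, ...]) -> "FeatureTable":
        unknown = [n for n in names if n not in self.features]
        if unknown:
            raise SchemaError(f"unknown features: {unknown}")
        keep = [c for c in self.frame.columns if c not in self.features or c in names]
        return FeatureTable(self.frame.loc[:, keep], features=tuple(names))


def load_feature_table(path: str | Path, fmt: str | None = None) -> FeatureTable:
    """Read a CSV/XLSX feature file into a :class:`FeatureTable`.

    Treatment labels ``W0``-``W3`` / ``S0``-``S3`` (or bare integers) are
    mapped to severity integers; rows with missing or unparseable values
    are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if fmt == "xlsx":
        df = pd.read_excel(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise SchemaError(f"unknown format {fmt!r}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    required = list(ID_COLUMNS) + list(FEATURES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    n_raw = len(df)
    feats = df.loc[:, list(FEATURES)].apply(pd.to_numeric, errors="coerce")
    keep = feats.notna().all(axis=1)

    w_vals, s_vals = [], []
    for idx, row in df.iterrows():
        try:
            w_vals.append(parse_level_label(row["drought_level"], "W"))
            s_vals.append(parse_level_label(row["salinity_level"], "S"))
        except SchemaError:
            w_vals.append(-1)
            s_vals.append(-1)
    df = df.assign(w=w_vals, s=s_vals)
    df.loc[:, list(FEATURES)] = feats
    keep &= (df["w"] >= 0) & (df["s"] >= 0)
    dropped = n_raw - int(keep.sum())
    if dropped:
        logger.warning("%s: dropped %d malformed row(s) of %d", path, dropped, n_raw)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise SchemaError(f"{path}: no valid rows after validation")

    table = FeatureTable(df)
    logger.info("%s: loaded %d rows, %d features", path, len(table), len(table.features))
    return table
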