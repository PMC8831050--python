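"""Reading, writing and masking of telemonitoring tables.

A telemonitoring table holds one row per voice recording: a subject
identifier, demographic covariates (age, sex, test_time), a block of
numeric voice features, and the two regression targets Motor-UPDRS
(0-108) and Total-UPDRS (0-176).  Feature cells may be marked missing;
targets never are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

MOTOR_RANGE = (0.0, 108.0)
TOTAL_RANGE = (0.0, 176.0)

DEFAULT_NA_TOKENS = ("", "na", "nan", "null")


class SchemaError(ValueError):
    """A required column is absent or mis-declared."""


class ParseError(ValueError):
    """A cell could not be interpreted under the declared schema."""


@dataclass(frozen=True)
class ColumnSchema:
    """Declares the role of each CSV column.

    Feature names are user-declared, not hard-coded: telemonitoring
    exports differ in which acoustic measures they carry.
    """

    subject_id: str
    features: tuple[str, ...]
    motor_updrs: str = "motor_updrs"
    total_updrs: str = "total_updrs"
    covariates: tuple[str, ...] = ("age", "sex", "test_time")

    @classmethod
    def from_file(cls, path) -> "ColumnSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            subject_id=raw["subject_id"],
            features=tuple(raw["features"]),
            motor_updrs=raw.get("motor_updrs", "motor_updrs"),
            total_updrs=raw.get("total_updrs", "total_updrs"),
            covariates=tuple(raw.get("covariates", ("age", "sex", "test_time"))),
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "features": list(self.features),
            "motor_updrs": self.motor_updrs,
            "total_updrs": self.total_updrs,
            "covariates": list(self.covariates),
        }


@dataclass
class TelemonitoringTable:
    """In-memory telemonitoring dataset.

    ``features`` is a dense float array in which masked cells still hold
    a numeric placeholder; ``missing_mask`` is the source of truth for
    missingness.  When cells were masked artificially (for the
    imputation experiment), ``held_out_values`` retains the true values
    at the masked coordinates so recovery error can be scored later.
    """

    subject_id: np.ndarray
    covariates: pd.DataFrame
    features: np.ndarray
    feature_names: tuple[str, ...]
    motor_updrs: np.ndarray
    total_updrs: np.ndarray
    missing_mask: np.ndarray
    held_out_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_id)
        self.features = np.asarray(self.features, dtype=float)
        self.motor_updrs = np.asarray(self.motor_updrs, dtype=float)
        self.total_updrs = np.asarray(self.total_updrs, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.features.shape != (n, len(self.feature_names)):
            raise SchemaError("feature block shape does not match feature names")
        if self.missing_mask.shape != self.features.shape:
            raise SchemaError("missing mask shape does not match feature block")
        for name, arr in (("motor_updrs", self.motor_updrs), ("total_updrs", self.total_updrs)):
            if arr.shape != (n,):
                raise SchemaError(f"{name} must have one value per row")
            if np.isnan(arr).any():
                raise SchemaError(f"{name} contains missing values; targets are never masked")
        lo, hi = MOTOR_RANGE
        if ((self.motor_updrs < lo) | (self.motor_updrs > hi)).any():
            raise SchemaError(f"motor_updrs outside [{lo}, {hi}]")
        lo, hi = TOTAL_RANGE
        if ((self.total_updrs < lo) | (self.total_updrs > hi)).any():
            raise SchemaError(f"total_updrs outside [{lo}, {hi}]")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def observed_features(self) -> np.ndarray:
        """Feature block with masked cells replaced by NaN."""
        out = self.features.copy()
        out[self.missing_mask] = np.nan
        return out

    def copy(self) -> "TelemonitoringTable":
        return TelemonitoringTable(
            subject_id=self.subject_id.copy(),
            covariates=self.covariates.copy(),
            features=self.features.copy(),
            feature_names=self.feature_names,
            motor_updrs=self.motor_updrs.copy(),
            total_updrs=self.total_updrs.copy(),
            missing_mask=self.missing_mask.copy(),
            held_out_values=None if self.held_out_values is None else self.held_out_values.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"subject_id": self.subject_id})
        for col in self.covariates.columns:
            frame[col] = self.covariates[col].to_numpy()
        feats = self.features.astype(object)
        feats[self.missing_mask] = None
        for j, name in enumerate(self.feature_names):
            frame[name] = feats[:, j]
        frame["motor_updrs"] = self.motor_updrs
        frame["total_updrs"] = self.total_updrs
        return frame


def load_table(path, schema: ColumnSchema, na_tokens=DEFAULT_NA_TOKENS) -> TelemonitoringTable:
    """Read a CSV into a :class:`TelemonitoringTable`.

    Empty cells and cells equal to an NA token (case-insensitive) in
    feature columns are marked missing.  Row order is preserved.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = [schema.subject_id, schema.motor_updrs, schema.total_updrs,
              *schema.covariates, *schema.features]
    for col in needed:
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} declared in schema but absent from {path}")

    tokens = {t.lower() for t in na_tokens}
    n = len(frame)
    feats = np.empty((n, len(schema.features)), dtype=float)
    mask = np.zeros_like(feats, dtype=bool)
    for j, name in enumerate(schema.features):
        for i, cell in enumerate(frame[name]):
            txt = cell.strip()
            if txt.lower() in tokens:
                mask[i, j] = True
                feats[i, j] = np.nan
            else:
                try:
                    feats[i, j] = float(txt)
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric value {cell!r} at row {i}, column {name!r}"
                    ) from exc
    # masked cells hold the column mean of observed values as a placeholder
    for j in range(feats.shape[1]):
        col = feats[:, j]
        if mask[:, j].all():
            raise ParseError(f"feature column {schema.features[j]!r} is entirely missing")
        col[mask[:, j]] = np.nanmean(col)

    def _numeric(colname: str) -> np.ndarray:
        try:
            return frame[colname].astype(float).to_numpy()
        except ValueError as exc:
            raise ParseError(f"non-numeric value in column {colname!r}") from exc

    return TelemonitoringTable(
        subject_id=frame[schema.subject_id].to_numpy(),
        covariates=pd.DataFrame({c: _numeric(c) for c in schema.covariates}),
        features=feats,
        feature_names=schema.features,
        motor_updrs=_numeric(schema.motor_updrs),
        total_updrs=_numeric(schema.total_updrs),
        missing_mask=mask,
    )


def save_table(table: TelemonitoringTable, path, float_format: str = "%.12g") -> None:
    """Write the table as CSV; masked cells become empty fields."""
    table.to_frame().to_csv(path, index=False, float_format=float_format)


def mask_random_entries(table: TelemonitoringTable, fraction: float, seed: int) -> TelemonitoringTable:
    """Mask a uniform random subset of feature cells.

    Exactly ``round(fraction * rows * n_features)`` cells are chosen
    without replacement over feature cells only (targets are never
    masked).  The true values at the masked coordinates are retained in
    ``held_out_values`` so imputation recovery can be scored.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1); got {fraction}")
    if table.missing_mask.any():
        raise ValueError("table already has masked cells")
    n_cells = table.n_rows * table.n_features
    n_mask = int(round(fraction * n_cells))
    if n_mask < 1:
        raise ValueError("fraction too small: no cell would be masked")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    mask = np.zeros(n_cells, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(table.features.shape)

    out = table.copy()
    out.held_out_values = table.features[mask].copy()
    out.missing_mask = mask
    return out


def unmask(table: TelemonitoringTable) -> TelemonitoringTable:
    """Restore held-out values, inverting :func:`mask_random_entries`."""
    if table.held_out_values is None:
        raise ValueError("table has no held-out values to restore")
    out = table.copy()
    out.features[table.missing_mask] = table.held_out_values
    out.missing_mask = np.zeros_like(table.missing_mask)
    out.held_out_values = None
    return out


def save_schema(schema: ColumnSchema, path) -> None:
    with open(path, "w") as fh:
        json.dump(schema.to_dict(), fh, indent=2)
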