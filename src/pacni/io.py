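"""Reading and writing the delimited tables the toolkit consumes.

Everything is plain CSV/TSV with automatic delimiter sniffing:
morphometric tables (one row per subject, one column per region-measure,
in the style of aparcstats2table / asegstats2table exports), longitudinal
biomarker panels, and weights tables (feature, weight) with a single
intercept record.

Column names in morphometric exports differ between FreeSurfer dialects;
``read_morphometrics`` resolves them through a user-extensible alias map
(input column name -> canonical schema name).  Unmatched extra columns are
ignored with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, IncompleteFeaturesError, ParseError
from .schema import FeatureSchema

log = logging.getLogger(__name__)

INTERCEPT_LABEL = "(Intercept)"

#: Default alias map: common dialect spellings -> canonical schema names.
#: Dot-separated aparc table headers and a few aseg variants.  Extend by
#: passing ``alias_map`` to :func:`read_morphometrics`.
DEFAULT_ALIASES: dict[str, str] = {
    "Left-Thalamus": "Left-Thalamus-Proper",
    "Right-Thalamus": "Right-Thalamus-Proper",
    "BrainSegNotVent": "BrainSegVolNotVent",
}


@dataclass
class FeatureVector:
    """One subject's morphometric values in a declared schema variant."""

    subject_id: str
    values: pd.Series  # indexed by feature name, schema order
    schema_variant: str = "full"
    complete: bool = True

    def __getitem__(self, name):
        return self.values[name]


@dataclass
class WeightsTable:
    """Linear scoring weights: feature -> coefficient, plus intercept."""

    weights: dict[str, float]
    intercept: float
    variant: str = "full"
    metadata: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(sum(1 for w in self.weights.values() if w != 0.0))


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs. tab."""
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc


def _canonicalize(columns, alias_map):
    aliases = dict(DEFAULT_ALIASES)
    # dotted aparc headers: lh.bankssts.thickness -> lh_bankssts_thickness
    if alias_map:
        aliases.update(alias_map)
    out = {}
    for col in columns:
        if col in aliases:
            out[col] = aliases[col]
        elif col.startswith(("lh.", "rh.")):
            out[col] = col.replace(".", "_")
        else:
            out[col] = col
    return out


def read_morphometrics(
    source, schema: FeatureSchema, alias_map: dict[str, str] | None = None,
    subject_column: str = "subject_id",
) -> list[FeatureVector]:
    """Read a subjects x features morphometric table against ``schema``.

    ``source`` is a path or a DataFrame.  Input column order is irrelevant;
    values are returned in schema order.  Missing schema columns raise
    :class:`IncompleteFeaturesError` naming them; non-numeric cells raise
    :class:`ParseError` with row/column context.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else read_table(source)
    rename = _canonicalize(df.columns, alias_map)
    df = df.rename(columns=rename)
    if subject_column not in df.columns:
        raise DataError(f"morphometric table lacks a {subject_column!r} column")

    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise IncompleteFeaturesError(missing)
    extra = [c for c in df.columns if c != subject_column and c not in schema]
    if extra:
        log.warning("ignoring %d unmatched columns: %s", len(extra), extra[:8])

    values = df[schema.names]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {values.iat[r, c]!r} at row {r}, column {numeric.columns[c]!r}"
        )
    if numeric.isna().any().any() or not np.isfinite(numeric.to_numpy()).all():
        raise DataError("morphometric table contains missing or non-finite values")

    vectors = []
    for i, sid in enumerate(df[subject_column].astype(str)):
        row = numeric.iloc[i]
        row.name = sid
        vectors.append(FeatureVector(sid, row, schema_variant=schema.variant))
    return vectors


def morphometrics_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a subjects x features DataFrame."""
    return pd.DataFrame(
        {v.subject_id: v.values for v in vectors}
    ).T.rename_axis("subject_id")


def write_morphometrics(frame: pd.DataFrame, path) -> None:
    frame.rename_axis("subject_id").to_csv(path, float_format="%.17g")


def read_weights(path, schema: FeatureSchema | None = None) -> WeightsTable:
    """Read a (feature, weight) table with exactly one intercept record."""
    df = read_table(path)
    if not {"feature", "weight"}.issubset(df.columns):
        raise DataError("weights file must have columns (feature, weight)")
    is_intercept = df["feature"].astype(str).str.lower().isin(
        {INTERCEPT_LABEL.lower(), "intercept"}
    )
    n_int = int(is_intercept.sum())
    if n_int != 1:
        raise DataError(f"weights file must contain exactly one intercept row, found {n_int}")
    intercept = float(df.loc[is_intercept, "weight"].iloc[0])
    coef = df.loc[~is_intercept]
    weights = dict(zip(coef["feature"].astype(str), coef["weight"].astype(float)))
    if len(weights) != len(coef):
        raise DataError("duplicate feature rows in weights file")
    variant = "full"
    if "variant" in df.columns:
        variant = str(df["variant"].iloc[0])
    if schema is not None:
        unknown = [n for n in weights if n not in schema]
        if unknown:
            raise DataError(
                f"weights name features absent from the {schema.variant} schema: {unknown[:8]}"
            )
        variant = schema.variant
    meta_cols = [c for c in df.columns if c not in ("feature", "weight", "variant")]
    metadata = {c: df[c].iloc[0] for c in meta_cols}
    return WeightsTable(weights, intercept, variant=variant, metadata=metadata)


def write_weights(table: WeightsTable, path) -> None:
    """Write a weights table; round-trips at double precision (17 sig. digits)."""
    rows = [{"feature": k, "weight": v} for k, v in table.weights.items()]
    rows.append({"feature": INTERCEPT_LABEL, "weight": table.intercept})
    df = pd.DataFrame(rows)
    df["variant"] = table.variant
    for k, v in table.metadata.items():
        df[k] = v
    df.to_csv(path, index=False, float_format="%.17g")


def audit_weights(table: WeightsTable) -> dict:
    """Coefficient-count audit of a weights table (total / nonzero / zero)."""
    n = len(table.weights)
    nz = table.n_nonzero
    return {"n_features": n, "n_nonzero": nz, "n_zero": n - nz}


def read_panel(path) -> pd.DataFrame:
    """Read a longitudinal biomarker panel as a long-format DataFrame.

    Long format has columns (subject_id, sex, age, biomarker, value).  Wide
    format has one ``<biomarker>_age<age>`` column per biomarker-wave and is
    melted to long.
    """
    df = read_table(path)
    long_cols = {"subject_id", "age", "biomarker", "value"}
    if long_cols.issubset(df.columns):
        return df
    id_cols = [c for c in ("subject_id", "sex") if c in df.columns]
    if "subject_id" not in id_cols:
        raise DataError("panel lacks a subject_id column")
    wide_cols = [c for c in df.columns if "_age" in c and c not in id_cols]
    if not wide_cols:
        raise DataError("panel is neither long (subject_id, age, biomarker, value) nor wide (<biomarker>_age<age>)")
    melted = df.melt(id_vars=id_cols, value_vars=wide_cols, var_name="key")
    parts = melted["key"].str.rsplit("_age", n=1, expand=True)
    melted["biomarker"] = parts[0]
    melted["age"] = pd.to_numeric(parts[1])
    return melted.drop(columns="key")
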