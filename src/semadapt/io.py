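"""Schema-validated TSV reading and writing for the pipeline tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "TableSchema",
    "read_table",
    "write_table",
    "CORPUS_SCHEMA",
    "REGIONS_SCHEMA",
    "PROFILES_SCHEMA",
    "PARADIGMS_SCHEMA",
    "BM_SCORES_SCHEMA",
    "CANDIDATES_SCHEMA",
    "DESIGN_SCHEMA",
    "BETAS_SCHEMA",
    "CONTRASTS_SCHEMA",
]

_CASTS = {
    "int": "int64",
    "float": "float64",
    "str": "object",
    "bool": "bool",
}


@dataclass(frozen=True)
class TableSchema:
    """Declared column set of a pipeline table.

    ``columns`` maps required column names to type kinds in
    {int, float, str, bool}. Extra columns are preserved on read but flagged
    with a warning.
    """

    name: str
    columns: Mapping[str, str]

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"{self.name} table is missing column(s): {missing}")
        extra = [c for c in df.columns if c not in self.columns]
        if extra:
            warnings.warn(
                f"{self.name} table has extra column(s) {extra}; preserved",
                stacklevel=3,
            )
        out = df.copy()
        for col, kind in self.columns.items():
            try:
                if kind == "str":
                    notna = out[col].notna()
                    vals = out[col].astype(object)
                    vals[notna] = vals[notna].astype(str)
                    out[col] = vals
                else:
                    out[col] = out[col].astype(_CASTS[kind])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{self.name} column {col!r} cannot be cast to {kind}: {exc}"
                ) from exc
        return out


def read_table(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a TSV table, validating against ``schema`` when given."""
    df = pd.read_csv(path, sep="\t", keep_default_na=True, na_values=[""])
    if schema is not None:
        df = schema.validate(df)
    # Empty strings round-trip as NaN in object columns; restore them.
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(object).where(df[col].notna(), "")
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    """Write a TSV table, validating against ``schema`` when given."""
    if schema is not None:
        df = schema.validate(df)
    df.to_csv(path, sep="\t", index=False)


CORPUS_SCHEMA = TableSchema(
    "corpus",
    {
        "study_id": "str",
        "contrast_id": "str",
        "space": "str",
        "correction": "str",
        "contrast_class": "str",
        "foci": "str",
    },
)

REGIONS_SCHEMA = TableSchema(
    "regions",
    {
        "atlas_label": "int",
        "median_x": "float",
        "median_y": "float",
        "median_z": "float",
        "correction_level_index": "float",
        "sensitivity_index": "float",
        "n_contrasts": "int",
    },
)

PROFILES_SCHEMA = TableSchema(
    "profiles", {"region_label": "str", "domain": "str", "P": "float"}
)

PARADIGMS_SCHEMA = TableSchema("paradigms", {"region_label": "str", "code": "float"})

BM_SCORES_SCHEMA = TableSchema(
    "bm_scores",
    {
        "region_label": "str",
        "n_micro": "int",
        "n_macro": "int",
        "W": "float",
        "domain_specificity": "float",
        "control_type_mean": "float",
    },
)

CANDIDATES_SCHEMA = TableSchema(
    "candidates",
    {
        "region_label": "str",
        "sensitivity_index": "float",
        "correction_level_index": "float",
        "control_type_mean": "float",
        "domain_specificity": "float",
    },
)

DESIGN_SCHEMA = TableSchema(
    "design",
    {
        "run": "int",
        "trial": "int",
        "condition": "str",
        "domain": "str",
        "prime_word": "str",
        "target_word": "str",
        "prime_category": "str",
        "target_category": "str",
        "relatedness": "float",
        "fixation_s": "float",
        "prime_s": "float",
        "blank_s": "float",
        "target_s": "float",
        "iti_s": "float",
    },
)

BETAS_SCHEMA = TableSchema(
    "betas",
    {
        "subject": "str",
        "roi": "str",
        "condition": "str",
        "domain": "str",
        "category": "str",
        "value": "float",
    },
)

CONTRASTS_SCHEMA = TableSchema(
    "contrasts",
    {
        "subject": "str",
        "roi": "str",
        "domain": "str",
        "category": "str",
        "contrast": "str",
        "granularity": "str",
        "value": "float",
    },
)
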