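"""Readers and writers for the pipeline's plain-text formats.

Abundance matrices travel as TSV/CSV with proteins in rows and sample ids in
columns; empty cells, ``NA`` and ``NaN`` mark missing values. Stage outputs
written by the CLI carry a provenance header (comment lines with stage name,
seed and config hash) which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .preprocess import AbundanceMatrix

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_header(stage: str, seed: int | None, config: dict | None = None) -> str:
    h = config_hash(config or {})
    return f"# lacrimark stage={stage} seed={seed} config_hash={h}\n"


def read_abundance(path) -> AbundanceMatrix:
    """Load a protein x sample intensity table.

    Empty/NA cells become the missingness mask; duplicate or empty protein or
    sample ids and non-numeric cells are rejected.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#",
                     na_values=_NA_VALUES, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.index.isna().any() or any(str(i).strip() == "" for i in df.index):
        raise ValueError("empty protein id")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from None
    return AbundanceMatrix.from_dataframe(df, state="raw")


def write_abundance(m: AbundanceMatrix, path, stage: str | None = None,
                    seed: int | None = None, config: dict | None = None) -> None:
    """Write the matrix; masked cells become empty fields."""
    path = Path(path)
    out = m.values.mask(m.mask)
    with path.open("w") as fh:
        if stage is not None:
            fh.write(provenance_header(stage, seed, config))
        out.to_csv(fh, sep=_sep(path), na_rep="")


def read_metadata(path, matrix: AbundanceMatrix | None = None,
                  allowed_groups: tuple = ("ALS", "control")) -> pd.DataFrame:
    """Load the sample sheet and (optionally) align it to a matrix.

    One row per sample; the ``group`` column must take values in
    ``allowed_groups``. With a matrix given, rows are reordered to the
    matrix's column order and any mismatch is reported with the offending
    ids.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    if "group" not in df.columns:
        raise ValueError("metadata needs a 'group' column")
    bad = set(df["group"].unique()) - set(allowed_groups)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if matrix is not None:
        extra = df.index.difference(matrix.samples)
        missing = matrix.samples.difference(df.index)
        if len(extra) or len(missing):
            raise ValueError(
                f"metadata/matrix sample mismatch: extra={list(extra)} missing={list(missing)}"
            )
        df = df.reindex(matrix.samples)
    return df


def write_metadata(df: pd.DataFrame, path, stage: str | None = None,
                   seed: int | None = None, config: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if stage is not None:
            fh.write(provenance_header(stage, seed, config))
        df.to_csv(fh, sep=_sep(path))


def write_json(obj, path, stage: str | None = None, seed: int | None = None,
               config: dict | None = None) -> None:
    """JSON result writer; provenance is embedded as a ``_provenance`` key."""
    payload = dict(obj)
    if stage is not None:
        payload["_provenance"] = {
            "stage": stage, "seed": seed, "config_hash": config_hash(config or {})
        }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
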