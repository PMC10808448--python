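"""Readers and writers for the pipeline's tabular and tree formats.

All tables are UTF-8 TSV with a header row; trees are Newick. Missing
values may be rendered as an empty cell, ``NA`` or ``Missing``
(case-insensitive), matching how cohort tables in the wild encode them.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .containers import RANKS, FeatureTable, FormatError, PhyloTree, SampleMetadata

log = logging.getLogger(__name__)

#: Case-insensitive missing-value markers accepted in any cell.
MISSING_MARKERS = ("", "na", "n/a", "nan", "missing")


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_MARKERS


def _read_tsv(path) -> pd.DataFrame:
    # check the header ourselves: pandas silently mangles duplicates
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise FormatError(f"{path}: duplicate column identifier(s): {dups}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _to_float(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Parse a string frame to float, reporting the coordinates of failures."""
    def parse(cell, row, col):
        if _is_missing(cell):
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise FormatError(
                f"{context}: cannot parse {cell!r} as a number "
                f"(row {row!r}, column {col!r})"
            ) from None

    out = pd.DataFrame(
        [[parse(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
         for i in range(df.shape[0])],
        index=df.index, columns=df.columns, dtype=float,
    )
    return out


def read_feature_table(path, unit_hint: str = "counts", transpose: bool = False) -> FeatureTable:
    """Read a taxa × samples abundance TSV.

    The first column holds taxon ids; columns named after taxonomic
    ranks (``kingdom`` … ``species``, case-insensitive) are collected
    into the lineage frame; all remaining columns are samples. Set
    ``transpose=True`` for tables written samples-as-rows.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus data columns")
    raw = raw.set_index(raw.columns[0])
    if transpose:
        # sample-rows orientation cannot carry lineage columns
        values = _to_float(raw, str(path)).T
        lineages = None
    else:
        rank_cols = [c for c in raw.columns if c.lower() in RANKS]
        lineages = None
        if rank_cols:
            lineages = raw[rank_cols].copy()
            lineages.columns = [c.lower() for c in rank_cols]
            lineages = lineages.map(lambda s: np.nan if _is_missing(s) else s.strip())
        values = _to_float(raw.drop(columns=rank_cols), str(path))
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing abundance value at taxon {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    return FeatureTable(values, unit=unit_hint, lineages=lineages)


# Column-name aliases recognised in metadata headers (lower-cased).
_META_ALIASES = {
    "exposure": "exposure", "pd": "exposure", "case": "exposure", "disease": "exposure",
    "bmi": "bmi", "body_mass_index": "bmi",
    "age": "age",
    "sex": "sex", "gender": "sex",
    "sample_id": "sample_id", "sample": "sample_id", "id": "sample_id",
}
_SEX_CODES = {"male": 0.0, "m": 0.0, "female": 1.0, "f": 1.0}


def read_metadata(path) -> SampleMetadata:
    """Read per-sample metadata TSV (one row per sample, first column = id).

    ``exposure`` (or alias ``PD``) is required; BMI/age/sex optional.
    Underweight is derived as BMI < 18.5 and missing when BMI is. Extra
    columns are kept verbatim (numeric where parseable, categorical
    strings otherwise).
    """
    raw = _read_tsv(path)
    raw.columns = [_META_ALIASES.get(c.lower(), c) for c in raw.columns]
    id_col = "sample_id" if "sample_id" in raw.columns else raw.columns[0]
    raw = raw.set_index(id_col)
    if "exposure" not in raw.columns:
        raise FormatError(f"{path}: metadata is missing the exposure (disease status) column")

    out = {}
    for col in raw.columns:
        ser = raw[col].map(lambda s: np.nan if _is_missing(s) else s.strip())
        if col == "sex":
            ser = ser.map(lambda s: _SEX_CODES.get(str(s).lower(), s) if pd.notna(s) else s)
        num = pd.to_numeric(ser, errors="coerce")
        # numeric column iff every non-missing cell parses
        out[col] = num if (num.notna() == ser.notna()).all() else ser
    data = pd.DataFrame(out, index=raw.index)
    if data["exposure"].isna().any():
        raise FormatError(f"{path}: exposure has missing values")
    meta = SampleMetadata(data)
    log.info("read %d samples from %s; missing per column: %s",
             len(meta.sample_ids), path, meta.missing_counts().to_dict())
    return meta


def align_samples(table: FeatureTable, meta: SampleMetadata):
    """Restrict table and metadata to their common samples, in table order.

    Discarded ids are logged. Raises on an empty intersection. Exact
    string match on ids; idempotent.
    """
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise FormatError("no samples shared between feature table and metadata")
    dropped_t = sorted(set(table.sample_ids) - set(common))
    dropped_m = sorted(set(meta.sample_ids) - set(common))
    if dropped_t or dropped_m:
        log.info("align_samples dropped %d table-only and %d metadata-only samples: %s %s",
                 len(dropped_t), len(dropped_m), dropped_t[:10], dropped_m[:10])
    return table.select_samples(common), meta.select_samples(common)


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree; branch lengths must be non-negative."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: unparseable Newick ({exc})") from exc
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"{path}: negative branch length at {node.name or '<internal>'}")
    return PhyloTree(tree)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.values.copy()
    if table.lineages is not None:
        df = pd.concat([table.lineages, df], axis=1)
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
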