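"""Core in-memory containers shared by every pipeline stage.

A :class:`FeatureTable` is a taxa-by-samples abundance matrix (counts,
relative abundances, or log abundances) with optional rank-labelled
lineages; a :class:`SampleMetadata` holds per-sample covariates for a
case-control cohort with an underweight outcome derived from BMI; a
:class:`PhyloTree` wraps a rooted tree whose tips are taxa, as required
for UniFrac distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "RANKS",
    "UNDERWEIGHT_BMI_CUTOFF",
    "FormatError",
    "FeatureTable",
    "SampleMetadata",
    "PhyloTree",
    "derive_underweight",
]

#: Taxonomic ranks recognised in lineage annotations, most to least inclusive.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: WHO underweight threshold; the outcome is BMI strictly below this value.
UNDERWEIGHT_BMI_CUTOFF = 18.5

VALID_UNITS = ("counts", "relative_abundance", "log_abundance")


class FormatError(ValueError):
    """Raised when an input artifact violates its format contract."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise FormatError(f"duplicate {what} identifier(s): {dups}")


@dataclass
class FeatureTable:
    """Taxa × samples abundance matrix.

    Parameters
    ----------
    values
        DataFrame indexed by taxon id with sample ids as columns.
    unit
        One of ``counts``, ``relative_abundance``, ``log_abundance``.
    lineages
        Optional DataFrame indexed like ``values`` with columns drawn
        from :data:`RANKS`; missing annotations are NaN.
    """

    values: pd.DataFrame
    unit: str = "counts"
    lineages: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        _check_unique(self.values.index, "taxon")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("feature table contains non-finite values")
        if self.unit != "log_abundance" and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative abundance at taxon {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.unit == "relative_abundance":
            sums = vals.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise FormatError(
                    "relative-abundance columns must sum to 1; offending sample(s): "
                    f"{[self.values.columns[i] for i in bad[:5]]}"
                )
        if self.lineages is not None:
            if not self.lineages.index.equals(self.values.index):
                self.lineages = self.lineages.reindex(self.values.index)
            unknown = [c for c in self.lineages.columns if c not in RANKS]
            if unknown:
                raise FormatError(f"unknown lineage rank column(s): {unknown}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[:, list(sample_ids)], self.unit,
                            None if self.lineages is None else self.lineages.copy())

    def select_taxa(self, taxon_ids) -> "FeatureTable":
        ids = list(taxon_ids)
        return FeatureTable(self.values.loc[ids], self.unit,
                            None if self.lineages is None else self.lineages.loc[ids])


def derive_underweight(bmi: pd.Series) -> pd.Series:
    """Binary underweight outcome: 1 iff BMI < 18.5 (strict), NaN if BMI missing."""
    uw = (bmi < UNDERWEIGHT_BMI_CUTOFF).astype(float)
    uw[bmi.isna()] = np.nan
    return uw


@dataclass
class SampleMetadata:
    """Per-sample covariates for a two-group cohort.

    ``data`` is indexed by sample id and carries at least ``exposure``
    (1 = case, 0 = control). ``bmi``, ``age``, ``sex`` and any extra
    covariates are optional columns; ``underweight`` is always derived
    from ``bmi`` (missing exactly when BMI is missing) and never trusted
    from the input file.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if "exposure" not in self.data.columns:
            raise FormatError("metadata must contain an 'exposure' column")
        if "bmi" in self.data.columns:
            self.data = self.data.copy()
            self.data["underweight"] = derive_underweight(self.data["bmi"].astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def missing_counts(self) -> pd.Series:
        return self.data.isna().sum()

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


@dataclass
class PhyloTree:
    """Rooted phylogeny over the table's taxa (tips labelled by taxon id)."""

    tree: skbio.TreeNode
    unmatched_tips: list[str] = field(default_factory=list)

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))

    def flag_unmatched(self, taxon_ids) -> list[str]:
        """Tips absent from ``taxon_ids``; recorded on the object and returned."""
        known = set(taxon_ids)
        self.unmatched_tips = [n for n in self.tip_names if n not in known]
        return self.unmatched_tips
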