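"""Turn a raw count table into an analysis-ready mediator matrix.

The pipeline order is: aggregate to the working rank, normalise to
relative abundance, apply the prevalence filter, then log-transform.
The mediator matrix is samples × taxa on the natural-log relative
abundance scale with a pseudocount; this is the scale on which the
mediation models operate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, FeatureTable, FormatError

log = logging.getLogger(__name__)

__all__ = [
    "MediatorMatrix",
    "to_relative_abundance",
    "prevalence_filter",
    "aggregate_taxa",
    "log_transform",
    "build_mediators",
]


@dataclass
class MediatorMatrix:
    """Samples × mediators matrix of log relative abundances."""

    data: pd.DataFrame  # index = sample ids, columns = mediator (taxon) ids
    pseudocount: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise FormatError("mediator matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mediator_ids(self) -> list[str]:
        return list(self.data.columns)


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total count.

    Column sums of the result are 1; an all-zero sample is an error
    (it has no defined composition).
    """
    if table.unit != "counts":
        raise FormatError(f"expected a counts table, got unit={table.unit!r}")
    sums = table.values.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise FormatError(f"sample(s) with zero total count: {zero}")
    return FeatureTable(table.values / sums, unit="relative_abundance",
                        lineages=None if table.lineages is None else table.lineages.copy())


def prevalence_filter(table: FeatureTable, threshold: float = 0.10) -> FeatureTable:
    """Keep taxa detected in strictly more than ``threshold`` of samples.

    ``threshold`` is a fraction in [0, 1); a taxon present (nonzero) in
    exactly ``threshold * n_samples`` samples is dropped. With
    ``threshold=0`` every taxon seen at least once is kept.
    """
    if not (0 <= threshold < 1):
        raise ValueError("prevalence threshold must be in [0, 1)")
    n = table.n_samples
    present = (table.values > 0).sum(axis=1)
    keep = present > threshold * n
    kept = table.values.index[keep].tolist()
    log.info("prevalence_filter(>%g): kept %d of %d taxa", threshold, len(kept), table.n_taxa)
    if not kept:
        log.warning("prevalence filter removed every taxon")
    return table.select_taxa(kept)


def aggregate_taxa(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum abundances over taxa sharing the same lineage at ``rank``.

    Taxa without an annotation at ``rank`` are dropped (their count is
    logged); the aggregated table is indexed by the rank label and
    keeps lineage columns down to ``rank``.
    """
    rank = rank.lower()
    if rank not in RANKS:
        raise FormatError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.lineages is None or rank not in table.lineages.columns:
        raise FormatError(f"table has no lineage annotation at rank {rank!r}")
    labels = table.lineages[rank]
    annotated = labels.notna()
    n_dropped = int((~annotated).sum())
    if n_dropped:
        log.info("aggregate_taxa(%s): dropped %d unannotated taxa", rank, n_dropped)
    vals = table.values.loc[annotated].groupby(labels[annotated], sort=True).sum()
    upper = [r for r in RANKS[: RANKS.index(rank) + 1] if r in table.lineages.columns]
    lin = (table.lineages.loc[annotated, upper]
           .groupby(labels[annotated], sort=True).first())
    lin = lin.reindex(vals.index)
    if table.unit == "relative_abundance" and n_dropped:
        # dropping unannotated taxa breaks the sum-to-1 invariant; renormalise
        vals = vals / vals.sum(axis=0)
        log.info("aggregate_taxa(%s): renormalised after dropping unannotated taxa", rank)
    return FeatureTable(vals, unit=table.unit, lineages=lin)


def log_transform(table: FeatureTable, pseudocount: float | str = "auto") -> MediatorMatrix:
    """Natural log of (relative abundance + pseudocount), samples × taxa.

    ``pseudocount="auto"`` uses half the smallest nonzero relative
    abundance in the table, a standard choice that keeps zeros below
    every observed value on the log scale.
    """
    if table.unit != "relative_abundance":
        raise FormatError(f"expected relative abundances, got unit={table.unit!r}")
    vals = table.values.to_numpy(dtype=float)
    if pseudocount == "auto":
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise FormatError("table has no nonzero abundance; cannot choose a pseudocount")
        pc = float(nonzero.min()) / 2.0
    else:
        pc = float(pseudocount)
        if pc <= 0:
            raise FormatError("pseudocount must be > 0")
    data = pd.DataFrame(np.log(vals + pc), index=table.values.index,
                        columns=table.values.columns).T
    return MediatorMatrix(data, pseudocount=pc,
                          provenance={"scale": "ln(relative_abundance + pseudocount)",
                                      "pseudocount": pc})


def build_mediators(table: FeatureTable, rank: str | None = None,
                    prevalence: float = 0.10,
                    pseudocount: float | str = "auto") -> MediatorMatrix:
    """Full preprocessing chain: aggregate → normalise → filter → log.

    ``table`` may hold counts or relative abundances; ``rank=None``
    skips aggregation (the table is already at the working rank).
    Records kept/dropped taxa in the provenance dict.
    """
    n0 = table.n_taxa
    if rank is not None:
        table = aggregate_taxa(table, rank)
    if table.unit == "counts":
        table = to_relative_abundance(table)
    filtered = prevalence_filter(table, prevalence)
    mm = log_transform(filtered, pseudocount)
    mm.provenance.update({
        "rank": rank, "prevalence_threshold": prevalence,
        "taxa_in": n0, "taxa_at_rank": table.n_taxa, "taxa_kept": filtered.n_taxa,
        "taxa_dropped_by_filter": table.n_taxa - filtered.n_taxa,
    })
    return mm
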