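"""Gene-level omics tables and their mapping onto reactions.

An :class:`OmicsTable` holds nonnegative gene-level measurements (expression
or chromatin accessibility, arbitrary units) as genes x samples.  Values are
pushed onto reactions through GPR rules (min over ``and``, max over ``or``),
yielding a :class:`ReactionDataVector`; reactions whose rule has no measured
gene carry the unmapped marker rather than a number.

Thresholding for context extraction uses a linear-interpolation percentile
over the *mapped* reaction values of one sample — the common default of
scientific numeric stacks, stated here so results reproduce bit-for-bit.  A
config switch (``level="gene"``) computes the same percentile over the
sample's raw gene values instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import OmicsError
from .gpr import UNMAPPED, evaluate_gpr
from .model import MetabolicModel

#: Allowed provenance channels of a ReactionDataVector.
CHANNELS = ("rna", "atac", "binary", "foldchange")


@dataclass
class OmicsTable:
    """Gene x sample table of nonnegative values; missing cells are NaN."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dup = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise OmicsError(f"duplicate gene ids: {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_values(self, sample: str) -> dict[str, float]:
        """Gene -> value mapping for one sample, missing cells omitted."""
        if sample not in self.data.columns:
            raise KeyError(f"no sample {sample!r}; available: {self.samples}")
        column = self.data[sample]
        return {g: float(v) for g, v in column.items() if pd.notna(v)}

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def read_omics(path: Union[str, Path]) -> OmicsTable:
    """Read a gene x sample TSV (header ``gene_id`` then sample names; "NA" = missing)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if frame.index.name != "gene_id":
        raise OmicsError(
            f"{path}: first header column must be 'gene_id', got {frame.index.name!r}"
        )
    if frame.index.has_duplicates:
        dup = sorted(frame.index[frame.index.duplicated()].unique())
        raise OmicsError(f"{path}: duplicate gene rows: {dup}")
    for column in frame.columns:
        coerced = pd.to_numeric(frame[column], errors="coerce")
        bad = coerced.isna() & frame[column].notna()
        if bad.any():
            raise OmicsError(
                f"{path}: non-numeric cell at gene {bad.idxmax()!r}, sample {column!r}"
            )
        frame[column] = coerced
    return OmicsTable(frame.astype(float))


def restrict_to_common_genes(a: OmicsTable, b: OmicsTable) -> tuple[OmicsTable, OmicsTable]:
    """Restrict both tables to the genes measured in both (order: as in ``a``).

    The filtered-data variant of the analysis: channel differences are then
    attributable to the values, not to which genes each assay covered.
    """
    common = [g for g in a.genes if g in set(b.genes)]
    if not common:
        raise OmicsError("no common genes between the two tables; nothing to analyze")
    return OmicsTable(a.data.loc[common].copy()), OmicsTable(b.data.loc[common].copy())


def log_transform(table: OmicsTable, pseudocount: float = 1.0) -> OmicsTable:
    """Elementwise ``log2(value + pseudocount)``; negative inputs are an error."""
    if (table.data < 0).any().any():
        bad = table.data[(table.data < 0).any(axis=1)].index[0]
        raise OmicsError(f"negative value at gene {bad!r}; log transform requires values >= 0")
    return OmicsTable(np.log2(table.data + pseudocount))


def average_replicates(table: OmicsTable, groups: Mapping[str, Iterable[str]]) -> OmicsTable:
    """Arithmetic mean of replicate columns on the raw scale.

    ``groups`` maps an output sample name (e.g. a time point) to the replicate
    column names to average.
    """
    columns = {}
    for name, replicates in groups.items():
        replicates = list(replicates)
        missing = [s for s in replicates if s not in table.data.columns]
        if missing:
            raise KeyError(f"unknown replicate columns {missing} for group {name!r}")
        columns[name] = table.data[replicates].mean(axis=1)
    return OmicsTable(pd.DataFrame(columns, index=table.data.index))


@dataclass
class ReactionDataVector:
    """Reaction-level data after GPR mapping.

    ``values`` has exactly the model's reaction ids as keys; unmapped
    reactions carry ``None``.  ``sample`` and ``channel`` record provenance.
    """

    values: dict[str, Optional[float]]
    sample: str = ""
    channel: str = "rna"

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    def mapped(self) -> dict[str, float]:
        return {r: v for r, v in self.values.items() if v is not None}

    def __getitem__(self, reaction_id: str) -> Optional[float]:
        return self.values[reaction_id]


def map_sample_to_reactions(
    model: MetabolicModel,
    table: OmicsTable,
    sample: str,
    channel: str = "rna",
) -> ReactionDataVector:
    """Map one sample's gene values onto every model reaction via its GPR."""
    gene_values = table.sample_values(sample)
    values = {
        rxn.id: evaluate_gpr(rxn.gpr, gene_values) for rxn in model.reactions
    }
    return ReactionDataVector(values=values, sample=sample, channel=channel)


def percentile_threshold(values: Iterable[Optional[float]], pct: float) -> float:
    """Linear-interpolation percentile of the mapped (non-unmapped) values."""
    if not 0 <= pct <= 100:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    mapped = [v for v in values if v is not None]
    if not mapped:
        raise OmicsError("no mapped values; cannot compute a percentile threshold")
    return float(np.percentile(mapped, pct, method="linear"))


def threshold_for_sample(
    model: MetabolicModel,
    table: OmicsTable,
    sample: str,
    pct: float = 25.0,
    level: str = "reaction",
) -> float:
    """Per-sample activity threshold at the given percentile.

    ``level="reaction"`` (default) takes the percentile over the sample's
    mapped reaction values; ``level="gene"`` over its raw gene values.
    """
    if level == "reaction":
        vector = map_sample_to_reactions(model, table, sample)
        return percentile_threshold(vector.values.values(), pct)
    if level == "gene":
        return percentile_threshold(table.sample_values(sample).values(), pct)
    raise ValueError(f"level must be 'reaction' or 'gene', got {level!r}")
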