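"""Flux-prediction evaluation and sample clustering.

Predicted fluxes are compared with measured ones (e.g. 13C-MFA values) on
the reactions common to both via Pearson's correlation coefficient r and
the mean squared error (MSE, denominator n).  Two correlations are compared
with Fisher's z transformation: each r maps to atanh(r), whose sampling
variance is approximately 1/(n-3), and the two-sample statistic

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

is referred to the standard normal; the two-sided p-value is reported with
a significance call at the conventional 0.05 cutoff.

Omics samples are grouped by agglomerative hierarchical clustering on
Euclidean distances between (log-transformed) sample profiles; average
linkage by default, with complete/ward available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .model import FluxVector
from .omics import OmicsTable, log_transform


@dataclass
class MeasuredFluxTable:
    """Reaction id -> measured flux (mmol/gDW/h)."""

    fluxes: dict[str, float]

    def __post_init__(self):
        bad = [r for r, v in self.fluxes.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite measured fluxes for {sorted(bad)}")

    @property
    def reactions(self) -> list[str]:
        return list(self.fluxes)

    def to_tsv(self, path: Union[str, Path]) -> None:
        frame = pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )
        frame.to_csv(path, sep="\t", index=False)


def read_measured_fluxes(path: Union[str, Path]) -> MeasuredFluxTable:
    frame = pd.read_csv(path, sep="\t")
    return MeasuredFluxTable(dict(zip(frame["reaction_id"], frame["flux"].astype(float))))


@dataclass
class FluxComparison:
    r: Optional[float]  # None when either vector has zero variance
    mse: float
    n: int
    matched: list[str]
    unmatched_measured: list[str] = field(default_factory=list)


def compare_fluxes(pred: FluxVector, measured: MeasuredFluxTable) -> FluxComparison:
    """Pearson r and MSE of predicted vs measured fluxes on the matched reactions.

    Requires at least 4 common reactions; a zero-variance vector makes r
    undefined (reported as None), while the MSE is always defined.
    """
    matched = [r for r in measured.reactions if r in pred]
    unmatched = [r for r in measured.reactions if r not in pred]
    if len(matched) < 4:
        raise ValueError(
            f"only {len(matched)} matched reactions; need >= 4 for a meaningful comparison"
        )
    x = pred.as_array(matched)
    y = np.array([measured.fluxes[r] for r in matched])
    mse = float(np.mean((x - y) ** 2))
    if np.std(x) == 0 or np.std(y) == 0:
        r_value = None
    else:
        r_value = float(np.corrcoef(x, y)[0, 1])
    return FluxComparison(r=r_value, mse=mse, n=len(matched), matched=matched,
                          unmatched_measured=unmatched)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of two Pearson correlations via Fisher's z.

    Returns ``(z, p)`` with a two-sided standard-normal p-value.  Requires
    n > 3 in both samples and |r| < 1 (the transform diverges at |r| = 1).
    """
    for label, n in (("n1", n1), ("n2", n2)):
        if n <= 3:
            raise ValueError(f"{label} must exceed 3 (atanh variance is 1/(n-3)), got {n}")
    for label, r in (("r1", r1), ("r2", r2)):
        if abs(r) >= 1:
            raise ValueError(f"|{label}| must be < 1 (transform diverges), got {r}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_significant(r1: float, n1: int, r2: float, n2: int, cutoff: float = 0.05) -> bool:
    """Significance call for a correlation difference at the conventional cutoff."""
    _, p = fisher_z_test(r1, n1, r2, n2)
    return p < cutoff


@dataclass
class ClusterResult:
    linkage: np.ndarray           # scipy linkage matrix over samples
    leaf_order: list[str]         # sample ids in dendrogram order
    samples: list[str]
    method: str
    cophenetic_heights: dict[tuple[str, str], float] = field(default_factory=dict)


def hierarchical_cluster(
    table: OmicsTable,
    method: str = "average",
    log2: bool = False,
) -> ClusterResult:
    """Agglomerative clustering of samples on Euclidean distance.

    ``log2=True`` applies the log2(x+1) transform first (for tables still on
    the raw scale).  Samples are pre-sorted by id so that distance ties
    break deterministically; a constant table collapses into one flat
    cluster at height 0 (not an error).
    """
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"method must be average/complete/ward, got {method!r}")
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if log2:
        table = log_transform(table)
    samples = sorted(table.samples)
    matrix = table.data[samples].to_numpy().T  # samples x genes
    distances = pdist(matrix, metric="euclidean")
    Z = hierarchy.linkage(distances, method=method)
    order = [samples[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, leaf_order=order, samples=samples, method=method)


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat cluster labels for a caller-chosen number of clusters k."""
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.samples, map(int, labels)))
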