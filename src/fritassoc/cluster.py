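"""Allele-count encoding and hierarchical clustering of samples.

Genotypes are encoded as minor-allele counts (0/1/2), missing cells are
mean-imputed per locus, and samples are agglomeratively clustered with
Euclidean distance and complete linkage — the computation behind
genotype-heatmap dendrograms. Samples are sorted by id before clustering so
tie-breaking, and hence the leaf order, is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .data import DataError, GenotypeMatrix


def encode_counts(geno: GenotypeMatrix) -> pd.DataFrame:
    """Samples x loci minor-allele counts; missing preserved as NaN."""
    return geno.minor_counts()


@dataclass
class ClusterResult:
    leaf_order: list[str]
    merges: np.ndarray  # scipy linkage matrix over the included samples
    samples: list[str]  # row order the linkage indices refer to
    excluded: list[str]  # all-missing samples left out

    def cut(self, k: int) -> pd.Series:
        labels = fcluster(self.merges, k, criterion="maxclust")
        return pd.Series(labels, index=self.samples)


def cluster_samples(
    matrix: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of the allele-count matrix."""
    matrix = matrix.sort_index()
    all_missing = matrix.index[matrix.isna().all(axis=1)]
    excluded = list(all_missing)
    matrix = matrix.drop(index=all_missing)
    if len(matrix) < 2:
        raise DataError("need >= 2 samples with genotype data to cluster")
    filled = matrix.fillna(matrix.mean(axis=0))
    # a locus missing everywhere carries no signal; treat as zero
    filled = filled.fillna(0.0)
    dist = pdist(filled.to_numpy(dtype=float), metric=metric)
    z = linkage(dist, method=method)
    order = leaves_list(z)
    samples = list(matrix.index)
    return ClusterResult(
        leaf_order=[samples[i] for i in order],
        merges=z,
        samples=samples,
        excluded=excluded,
    )


def heatmap(
    matrix: pd.DataFrame, result: ClusterResult, path, meta: pd.DataFrame | None = None
) -> None:
    """Optional clustered-heatmap rendering of the allele-count matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.loc[result.leaf_order]
    fig, ax = plt.subplots(figsize=(8, 10))
    ax.imshow(ordered.fillna(ordered.mean(axis=0)).to_numpy(), aspect="auto",
              cmap="viridis", interpolation="nearest")
    ax.set_xlabel("locus")
    ax.set_ylabel("sample (dendrogram order)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
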