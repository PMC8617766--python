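"""Phenolic-metabolite profile summaries.

Operates on LC-MS annotation tables (compound name, class, subclass,
per-genotype presence) and relative-abundance matrices: internal-standard
normalization, class composition, genotype uniqueness, top-N selection,
Ward/Euclidean hierarchical clustering (heatmap ordering) and PCA.

The identification list and the relatively-quantified matrix are treated as
separate inputs: a compound can be identified without being quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import (
    DegenerateInputError,
    NormalizationError,
    SizeError,
    VocabularyError,
)

#: Closed vocabulary of compound classes.
COMPOUND_CLASSES = ("flavonoid", "phenolic acid", "other polyphenol")


@dataclass
class AbundanceMatrix:
    """Compounds x samples matrix of nonnegative relative abundances."""

    data: pd.DataFrame  # index: compound ids, columns: sample ids
    normalization: str = "raw"  # raw | is_normalized | autoscaled

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValueError("duplicate compound ids")
        if self.normalization not in {"raw", "is_normalized", "autoscaled"}:
            raise ValueError(f"unknown normalization tag {self.normalization!r}")
        if self.normalization != "autoscaled" and (self.data.values < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def compounds(self):
        return list(self.data.index)

    @property
    def samples(self):
        return list(self.data.columns)


@dataclass
class ClusterResult:
    """Agglomeration schedule and dendrogram leaf order."""

    merges: list  # [(id_a, id_b, height), ...] with nondecreasing heights
    leaf_order: list  # item labels in dendrogram traversal order
    linkage: np.ndarray  # scipy linkage matrix
    labels: list

    def cut(self, k: int) -> dict:
        """Labels -> cluster id for a k-cluster cut of the dendrogram."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))


@dataclass
class PcaResult:
    """PCA scores, loadings and explained-variance fractions."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # compounds x components, orthonormal columns
    variance_fractions: np.ndarray
    dropped_compounds: list


def normalize_by_internal_standard(matrix: AbundanceMatrix, is_rows) -> AbundanceMatrix:
    """Divide each sample's intensities by its internal-standard level.

    The per-sample divisor is the geometric mean of the named
    internal-standard rows (robust to a single saturated standard).  The
    IS rows are dropped from the output.
    """
    is_rows = list(is_rows)
    missing = [r for r in is_rows if r not in matrix.data.index]
    if missing:
        raise NormalizationError(f"internal standards not in matrix: {missing}")
    is_block = matrix.data.loc[is_rows]
    for sample in matrix.samples:
        if (is_block[sample] <= 0).any():
            raise NormalizationError(
                f"sample {sample!r}: nonpositive internal-standard intensity"
            )
    divisor = np.exp(np.log(is_block).mean(axis=0))  # geometric mean per sample
    out = matrix.data.drop(index=is_rows) / divisor
    return AbundanceMatrix(out, normalization="is_normalized")


def class_composition(table: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Class percentages and per-class/subclass counts of an annotation table.

    Returns ``(class_percent, class_counts, subclass_counts)``; percentages
    are integer-rounded shares of the total identification count.
    """
    if table.empty:
        raise DegenerateInputError("empty metabolite table")
    unknown = set(table["compound_class"]) - set(COMPOUND_CLASSES)
    if unknown:
        raise VocabularyError(
            f"unknown compound classes {sorted(unknown)}; expected {COMPOUND_CLASSES}"
        )
    class_counts = table["compound_class"].value_counts()
    total = int(class_counts.sum())
    class_percent = (class_counts / total * 100).round().astype(int)
    subclass_counts = table.groupby(["compound_class", "subclass"]).size()
    return class_percent, class_counts, subclass_counts


@dataclass
class PresenceSummary:
    counts: dict  # genotype -> number of compounds present
    unique: dict  # genotype -> sorted list of compounds present only there
    core: list  # compounds present in every genotype


def genotype_presence_summary(table: pd.DataFrame, genotypes=None) -> PresenceSummary:
    """Per-genotype identification counts, unique sets and the shared core.

    Presence flags are read from ``present_<genotype>`` columns.
    """
    if genotypes is None:
        genotypes = [c[len("present_"):] for c in table.columns if c.startswith("present_")]
    cols = [f"present_{g}" for g in genotypes]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing presence columns {missing}")
    flags = table[cols].astype(bool).to_numpy()
    names = table["name"].tolist()
    counts = {g: int(flags[:, j].sum()) for j, g in enumerate(genotypes)}
    unique = {
        g: sorted(
            names[i]
            for i in range(len(names))
            if flags[i, j] and flags[i].sum() == 1
        )
        for j, g in enumerate(genotypes)
    }
    core = sorted(names[i] for i in range(len(names)) if flags[i].all())
    return PresenceSummary(counts=counts, unique=unique, core=core)


def select_top_n(matrix: AbundanceMatrix, n: int, criterion: str = "variance") -> AbundanceMatrix:
    """Keep the n compounds with the largest variance (or mean) across samples.

    Ties are broken by lexicographic compound id so the selection is
    deterministic.
    """
    if criterion not in {"variance", "mean"}:
        raise ValueError("criterion must be 'variance' or 'mean'")
    if n < 1 or n > len(matrix.data):
        raise SizeError(f"n={n} outside [1, {len(matrix.data)}]")
    stat = matrix.data.var(axis=1, ddof=1) if criterion == "variance" else matrix.data.mean(axis=1)
    order = (
        pd.DataFrame({"stat": stat, "id": stat.index.astype(str)})
        .sort_values(["stat", "id"], ascending=[False, True], kind="stable")
        .index[:n]
    )
    return AbundanceMatrix(matrix.data.loc[order], normalization=matrix.normalization)


def ward_cluster(matrix: AbundanceMatrix, axis: str = "compounds") -> ClusterResult:
    """Ward-linkage agglomerative clustering over Euclidean distances.

    ``axis`` selects whether compounds (rows) or samples (columns) are
    clustered.  Leaf order follows the dendrogram traversal with the
    lower-index child visited first.
    """
    if axis not in {"compounds", "samples"}:
        raise ValueError("axis must be 'compounds' or 'samples'")
    data = matrix.data if axis == "compounds" else matrix.data.T
    labels = list(data.index)
    if len(labels) < 2:
        raise SizeError(f"need >= 2 items on axis {axis!r}, got {len(labels)}")
    Z = hierarchy.linkage(pdist(data.to_numpy(), metric="euclidean"), method="ward")
    merges = [(int(row[0]), int(row[1]), float(row[2])) for row in Z]
    leaves = hierarchy.leaves_list(Z)
    return ClusterResult(
        merges=merges,
        leaf_order=[labels[i] for i in leaves],
        linkage=Z,
        labels=labels,
    )


def pca(matrix: AbundanceMatrix, scaling: str = "autoscale") -> PcaResult:
    """Principal component analysis of samples in compound space.

    Compounds are centred across samples and, with ``autoscale``, divided by
    their standard deviation (unit variance, the usual metabolomics
    convention); zero-variance compounds are dropped with a warning under
    autoscaling.  Components are ordered by explained variance and signed so
    the largest-magnitude loading of each component is positive.
    """
    if scaling not in {"autoscale", "center_only"}:
        raise ValueError("scaling must be 'autoscale' or 'center_only'")
    X = matrix.data.T  # samples x compounds
    if X.shape[0] < 2:
        raise DegenerateInputError("need >= 2 samples")
    centred = X - X.mean(axis=0)
    dropped = []
    if scaling == "autoscale":
        sd = centred.std(axis=0, ddof=1)
        dropped = list(sd.index[sd == 0])
        if dropped:
            import warnings

            warnings.warn(
                f"dropping {len(dropped)} zero-variance compounds before autoscaling",
                stacklevel=2,
            )
            centred = centred.drop(columns=dropped)
            sd = sd.drop(index=dropped)
        centred = centred / sd
    if centred.shape[1] < 2:
        raise DegenerateInputError("fewer than 2 usable compounds")

    U, s, Vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
    n_comp = int((s > s.max() * 1e-12).sum()) if s.size else 0
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_comp):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    eigvals = s**2 / (X.shape[0] - 1)
    total_var = float(centred.var(axis=0, ddof=1).sum())
    fractions = eigvals / total_var if total_var > 0 else np.zeros_like(eigvals)
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=centred.columns, columns=comp_names),
        variance_fractions=fractions,
        dropped_compounds=dropped,
    )


def plot_heatmap(matrix: AbundanceMatrix, result: ClusterResult, path) -> None:
    """Write a basic clustered-heatmap figure (dendrogram order on rows)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.data.loc[result.leaf_order]
    fig, ax = plt.subplots(figsize=(4, max(3, 0.25 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=6)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, fontsize=8)
    fig.colorbar(im, ax=ax, label="relative abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
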