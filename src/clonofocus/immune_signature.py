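"""Immune-gene expression signature: clustering, markers, scores.

Consumes an already-normalized genes x samples expression matrix
(upstream platform normalization and batch correction are out of scope),
log2-transforms it, clusters samples by Ward agglomeration on their
principal-component coordinates, selects cluster-defining marker genes,
computes median-based modified z-scores for heat-map display, and
correlates per-sample signature scores between cell-type gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .repertoire_io import FormatError

MARKER_CLASSES = ("T cell", "microglia", "macrophage", "unassigned")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag."""

    df: pd.DataFrame  # index: gene symbols, columns: sample IDs
    scale_flag: str = "linear"  # "linear" | "log2"

    def __post_init__(self) -> None:
        if self.scale_flag not in ("linear", "log2"):
            raise ValueError(f"unknown scale_flag {self.scale_flag!r}")
        if self.df.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @classmethod
    def from_file(cls, path: str | Path, scale_flag: str = "linear") -> "ExpressionMatrix":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df=df, scale_flag=scale_flag)

    def to_file(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.df.to_csv(path, sep=sep)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # sample -> cluster label in 1..k
    k: int
    linkage_method: str = "ward"
    n_pcs: int = 0

    def samples_in(self, label: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == label]


@dataclass
class MarkerSet:
    """Assignment of genes to immune cell classes."""

    classes: dict[str, str]  # gene -> class
    provenance: str = ""

    def __post_init__(self) -> None:
        for gene, cls_ in self.classes.items():
            if cls_ not in MARKER_CLASSES:
                raise ValueError(f"gene {gene} has unknown class {cls_!r}")

    def genes_of(self, cls_: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == cls_]

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("gene", "class"):
            if col not in df.columns:
                raise FormatError(f"marker file {path} is missing column {col!r}")
        return cls(
            classes=dict(zip(df["gene"], df["class"])),
            provenance=provenance or str(path),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.classes.items()), columns=["gene", "class"]
        ).to_csv(path, sep="\t", index=False)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """x -> log2(x + pseudocount), marking the matrix as log2 scale."""
    if matrix.scale_flag == "log2":
        raise ValueError("matrix is already log2 transformed")
    if (matrix.df.values < 0).any():
        raise ValueError("linear-scale expression values must be non-negative")
    return ExpressionMatrix(df=np.log2(matrix.df + pseudocount), scale_flag="log2")


def _default_n_pcs(explained_ratio: np.ndarray, threshold: float = 0.8) -> int:
    cumulative = np.cumsum(explained_ratio)
    return int(np.searchsorted(cumulative, threshold) + 1)


def pca_cluster(
    matrix: ExpressionMatrix, n_pcs: int | None = None, k: int = 3
) -> ClusterAssignment:
    """Ward clustering of samples in principal-component space.

    Samples are projected onto the top principal components of the
    gene-wise centered matrix; Ward agglomeration on Euclidean distances
    between PC coordinates is cut at k clusters. Labels are renumbered by
    ascending mean within-cluster total expression, so cluster k is the
    high-signature group (deterministic labeling). By default the number
    of components is the smallest explaining 80% of the variance.
    """
    if matrix.scale_flag != "log2":
        raise ValueError("pca_cluster expects a log2-scale matrix")
    samples = matrix.samples
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the number of samples ({len(samples)})")
    x = matrix.df.to_numpy(dtype=float).T  # samples x genes
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs is not None and not 1 <= n_pcs <= max_pcs:
        raise ValueError(f"n_pcs must lie in [1, {max_pcs}]")
    pca = PCA(n_components=max_pcs if n_pcs is None else n_pcs, svd_solver="full")
    coords = pca.fit_transform(x)  # PCA centers gene-wise internally
    if n_pcs is None:
        n_pcs = _default_n_pcs(pca.explained_variance_ratio_)
        coords = coords[:, :n_pcs]
    tree = linkage(coords, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel: ascending mean total expression -> cluster k is high-signature
    totals = matrix.df.sum(axis=0).to_numpy(dtype=float)
    order = sorted(
        np.unique(raw), key=lambda lab: (totals[raw == lab].mean(), lab)
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {s: remap[lab] for s, lab in zip(samples, raw)}
    return ClusterAssignment(labels=labels, k=k, linkage_method="ward", n_pcs=n_pcs)


def select_markers(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    target: int,
    alpha: float = 1e-4,
    method: str = "welch",
) -> list[str]:
    """Genes significantly higher in the target cluster than in the rest.

    One test per gene of the target-cluster samples against all other
    samples: Welch's unequal-variance t-test by default, Kruskal-Wallis as
    an option. Returns genes with p < alpha and a higher target mean,
    sorted by ascending p.
    """
    target_samples = clusters.samples_in(target)
    rest_samples = [s for s in matrix.samples if s not in set(target_samples)]
    if len(target_samples) < 2 or len(rest_samples) < 2:
        raise ValueError("marker selection needs >= 2 samples per side")
    a = matrix.df[target_samples].to_numpy(dtype=float)
    b = matrix.df[rest_samples].to_numpy(dtype=float)
    if method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance genes carry no signal
    elif method == "kruskal":
        pvals = np.ones(a.shape[0])
        for i in range(a.shape[0]):
            if np.ptp(np.concatenate([a[i], b[i]])) == 0:
                continue
            pvals[i] = stats.kruskal(a[i], b[i]).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    higher = a.mean(axis=1) > b.mean(axis=1)
    mask = (pvals < alpha) & higher
    hits = [(pvals[i], matrix.genes[i]) for i in np.flatnonzero(mask)]
    hits.sort()
    return [gene for _, gene in hits]


def modified_z(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Median-based modified z-scores per gene row.

    z = 0.6745 (x - median) / MAD with MAD = median(|x - median|). Rows
    with zero MAD fall back to mean-absolute-deviation scaling
    (z = (x - median) / (1.253314 MeanAD)); rows constant after that are
    all zeros.
    """
    values = matrix.df.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    dev = values - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    meanad = np.mean(np.abs(dev), axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_mad = 0.6745 * dev / mad
        z_meanad = dev / (1.253314 * meanad)
    z = np.where(mad > 0, z_mad, np.where(meanad > 0, z_meanad, 0.0))
    return pd.DataFrame(z, index=matrix.df.index, columns=matrix.df.columns)


def signature_scores(
    matrix: ExpressionMatrix, markers: MarkerSet, cls_: str
) -> pd.Series:
    """Per-sample signature score: mean log2 expression over the class genes."""
    genes = [g for g in markers.genes_of(cls_) if g in matrix.df.index]
    if not genes:
        raise ValueError(f"no genes of class {cls_!r} present in the matrix")
    return matrix.df.loc[genes].mean(axis=0)


def signature_correlation(
    matrix: ExpressionMatrix, markers: MarkerSet, class_a: str, class_b: str
) -> tuple[float, float]:
    """Pearson correlation between two cell-type signature score vectors."""
    scores_a = signature_scores(matrix, markers, class_a)
    scores_b = signature_scores(matrix, markers, class_b)
    r, p = stats.pearsonr(scores_a.to_numpy(), scores_b.to_numpy())
    return float(r), float(p)
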