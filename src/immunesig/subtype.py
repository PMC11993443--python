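"""Intrinsic subtyping, immune subtype labels, clustering and PCA.

Nearest-centroid subtyping assigns each tumor to the intrinsic subtype
(LumA, LumB, HER2-enriched, Basal-like) whose centroid profile it
correlates with best (Pearson), optionally excluding labels such as the
normal-breast-like class.  The joint immune scheme (PAMIR) splits every
intrinsic subtype by the signature call: Gp-R tumors get an "immune"
suffix (e.g. LumA-immune), and a merged 6-level scheme pools LumA with
LumB for survival analysis.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix
from .signature import SampleScores

__all__ = [
    "CentroidSet",
    "compute_centroids",
    "assign_nearest_centroid",
    "pamir_label",
    "merge_luminal",
    "hierarchical_cluster",
    "pca_loadings",
    "select_genes_by_loading",
]

PAM50_LABELS = ("Basal", "HER2", "LumA", "LumB")


@dataclasses.dataclass
class CentroidSet:
    """Per-subtype mean expression profiles over a shared gene universe."""

    profiles: pd.DataFrame  # genes x subtype labels
    source: str = "trained-from-labels"

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need >=2 subtype centroids")
        if self.profiles.columns.duplicated().any():
            raise ValueError("duplicate subtype labels")
        self.profiles = self.profiles.astype(float)

    @property
    def labels(self) -> list[str]:
        return [str(c) for c in self.profiles.columns]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.profiles.index]

    def to_json(self, path) -> None:
        payload = {
            "source": self.source,
            "centroids": {label: self.profiles[label].to_dict() for label in self.labels},
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "CentroidSet":
        with open(path) as handle:
            payload = json.load(handle)
        frame = pd.DataFrame(payload["centroids"]).sort_index()
        return cls(frame, source=payload.get("source", "loaded"))


def compute_centroids(X: ExpressionMatrix, labels: Mapping[str, str] | pd.Series) -> CentroidSet:
    """Per-label mean profiles; every label needs >=2 samples."""
    labels = pd.Series(labels)
    labels = labels.reindex(X.samples)
    if labels.isna().any():
        raise ValueError("every sample needs a subtype label")
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"subtype classes with <2 samples: {list(singletons.index)}")
    profiles = {
        str(label): X.data.loc[:, labels[labels == label].index].mean(axis=1)
        for label in sorted(counts.index)
    }
    return CentroidSet(pd.DataFrame(profiles))


def assign_nearest_centroid(
    X: ExpressionMatrix,
    centroids: CentroidSet,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Assign each sample the subtype whose centroid it best correlates with.

    Returns a frame with columns ``sample_id``, ``pam50`` and one
    ``corr_<label>`` column per retained centroid.  Samples with constant
    profiles over the shared genes (correlation undefined) are flagged
    ``unclassified``.  Exact correlation ties are broken alphabetically
    with a warning.
    """
    exclude = set(exclude)
    labels = [l for l in centroids.labels if l not in exclude]
    if len(labels) < 2:
        raise ValueError("need >=2 non-excluded centroids")
    shared = [g for g in centroids.genes if g in X.data.index]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and centroids; >=3 required"
        )
    values = X.data.loc[shared].to_numpy(dtype=float)  # genes x samples
    cent = centroids.profiles.loc[shared, labels].to_numpy(dtype=float)  # genes x labels

    def corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=0, keepdims=True)
        b = b - b.mean(axis=0, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=0))[:, None] * np.sqrt((b**2).sum(axis=0))[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            return (a.T @ b) / denom

    corr = corr_columns(values, cent)  # samples x labels
    flat_centroids = cent.std(axis=0) == 0
    if flat_centroids.any():
        flat = [labels[j] for j in np.flatnonzero(flat_centroids)]
        warnings.warn(
            f"centroids with constant profiles never win: {flat}", stacklevel=2
        )
        corr[:, flat_centroids] = -np.inf
    sample_flat = values.std(axis=0) == 0
    calls: list[str] = []
    for i, sample in enumerate(X.samples):
        row = corr[i]
        if sample_flat[i] or np.isnan(row).any():
            calls.append("unclassified")
            warnings.warn(
                f"sample {sample!r} has a constant profile; left unclassified",
                stacklevel=2,
            )
            continue
        best = row.max()
        winners = [labels[j] for j in np.flatnonzero(row == best)]
        if len(winners) > 1:
            warnings.warn(
                f"correlation tie for sample {sample!r} among {winners}; "
                "broken alphabetically",
                stacklevel=2,
            )
        calls.append(sorted(winners)[0])
    out = pd.DataFrame({"sample_id": X.samples, "pam50": calls})
    for j, label in enumerate(labels):
        out[f"corr_{label}"] = corr[:, j]
    return out


def pamir_label(calls: pd.DataFrame, scores: SampleScores) -> pd.DataFrame:
    """Attach the immune flag and joint subtype labels to nearest-centroid calls.

    immune := Gp-R (IS > 0); ``pamir`` = intrinsic label + "-immune" suffix
    when immune; ``pamir_merged`` pools LumA/LumB into LumA/B for the
    6-level survival scheme.
    """
    if set(calls["sample_id"]) != set(scores.sample_ids):
        raise ValueError("subtype calls and scores cover different samples")
    group = scores.group.reindex(calls["sample_id"]).to_numpy()
    immune = group == "Gp-R"
    out = calls.copy()
    out["immune"] = immune
    suffix = np.where(immune, "-immune", "")
    out["pamir"] = out["pam50"].astype(str) + suffix
    out["pamir_merged"] = merge_luminal(out["pamir"])
    out.loc[out["pam50"] == "unclassified", ["pamir", "pamir_merged"]] = "unclassified"
    return out


def merge_luminal(pamir: pd.Series | Sequence[str]) -> pd.Series:
    """Map LumA/LumB (± immune) onto the pooled LumA/B labels."""
    pamir = pd.Series(pamir)

    def merge(label: str) -> str:
        base, _, suffix = label.partition("-")
        if base in ("LumA", "LumB"):
            base = "LumA/B"
        return base + ("-" + suffix if suffix else "")

    return pamir.map(merge)


def hierarchical_cluster(
    X: ExpressionMatrix, genes: Iterable[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering of samples with distance 1 − Pearson r.

    Returns (leaf-order sample ids, scipy linkage matrix) for heat-map export.
    """
    frame = X.data if genes is None else X.subset(list(genes)).data
    if frame.shape[1] < 2:
        raise ValueError("clustering needs >=2 samples")
    if frame.shape[0] < 3:
        raise ValueError("clustering needs >=3 genes")
    values = frame.to_numpy(dtype=float).T  # samples x genes
    constant = values.std(axis=1) == 0
    if constant.any():
        bad = [X.samples[i] for i in np.flatnonzero(constant)]
        raise ValueError(f"constant sample profiles (correlation undefined): {bad[:5]}")
    dist = pdist(values, metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    linkage = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(linkage)
    return [X.samples[i] for i in order], linkage


def pca_loadings(
    X: ExpressionMatrix, genes: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over a gene set.

    Returns (sample scores, gene loadings, explained-variance ratio).
    Loadings are orthonormal; each component's sign is fixed so that its
    largest-|loading| gene has positive loading.
    """
    frame = X.data if genes is None else X.subset(list(genes)).data
    if frame.shape[1] <= 2:
        raise ValueError("PCA needs more than 2 samples")
    if frame.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genes")
    values = frame.to_numpy(dtype=float).T  # samples x genes
    centered = values - values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| gene positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    comps = [f"PC{k + 1}" for k in range(s.size)]
    scores = pd.DataFrame(u * s, index=frame.columns, columns=comps)
    scores.index.name = "sample_id"
    loadings = pd.DataFrame(vt.T, index=frame.index, columns=comps)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    return scores, loadings, explained


def select_genes_by_loading(
    loadings: pd.DataFrame, component: str = "PC1", threshold: float = 0.10
) -> list[str]:
    """Genes with |loading| > threshold on a component (enrichment export)."""
    if component not in loadings.columns:
        raise KeyError(f"component {component!r} not in loadings")
    mask = loadings[component].abs() > threshold
    return [str(g) for g in loadings.index[mask]]


def write_gene_list(genes: Sequence[str], path) -> None:
    """One gene symbol per line, for external enrichment tools."""
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")
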