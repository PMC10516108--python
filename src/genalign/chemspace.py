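"""Descriptor-space proxy: descriptors -> one-time PCA -> k-means clustering.

The proxy is a PCA of molecular descriptors fitted once per run (on the
pretraining set) and reused for every later projection, so that generated
ensembles from different iterations live in the same coordinate system.
Clustering uses repeated seeded k-means with a two-stage selection rule:
among the five restarts with the lowest inertia, keep the one with the
smallest variance in cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

DescriptorProvider = Callable[[Chem.Mol], dict[str, float]]


def rdkit_descriptor_provider() -> DescriptorProvider:
    """The full RDKit descriptor set (~210 names, CalcMolDescriptors)."""
    from rdkit.Chem import Descriptors

    return Descriptors.CalcMolDescriptors


#: curated fast subset used by the tiny profile (~30x faster than the full set)
FAST_DESCRIPTORS = (
    "MolWt", "MolLogP", "TPSA", "NumHAcceptors", "NumHDonors",
    "NumRotatableBonds", "RingCount", "NumAromaticRings", "FractionCSP3",
    "HeavyAtomCount", "NHOHCount", "NOCount", "NumAliphaticRings",
    "LabuteASA", "MolMR", "HallKierAlpha", "Kappa1", "Kappa2",
    "Chi0", "Chi1", "BalabanJ", "BertzCT",
)


def fast_descriptor_provider() -> DescriptorProvider:
    from rdkit.Chem import Descriptors

    fns = dict(Descriptors.descList)
    chosen = {name: fns[name] for name in FAST_DESCRIPTORS}

    def provider(mol: Chem.Mol) -> dict[str, float]:
        return {name: float(fn(mol)) for name, fn in chosen.items()}

    return provider


@dataclass
class DescriptorMatrix:
    """Finite (molecules x descriptors) matrix with row ids and column names."""

    ids: list[str]
    names: list[str]
    values: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)
    failed_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)


def compute_descriptors(
    smiles: Sequence[str], provider: DescriptorProvider | None = None
) -> DescriptorMatrix:
    """Compute descriptors for canonical SMILES, dropping non-finite columns.

    Any descriptor column that is NaN/inf for at least one molecule is
    discarded (names recorded); molecules that fail entirely are dropped
    with a warning.
    """
    provider = provider or rdkit_descriptor_provider()
    ids, rows, failed = [], [], []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            failed.append(s)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(provider(mol))
            ids.append(s)
        except Exception:
            failed.append(s)
    if failed:
        warnings.warn(f"descriptor computation failed for {len(failed)} molecules")
    if not rows:
        raise ValueError("no molecules yielded descriptors")
    frame = pd.DataFrame(rows, index=ids).astype(float)
    finite = np.isfinite(frame.to_numpy()).all(axis=0)
    dropped = [c for c, ok in zip(frame.columns, finite) if not ok]
    frame = frame.loc[:, finite]
    return DescriptorMatrix(
        ids=list(frame.index),
        names=list(frame.columns),
        values=np.ascontiguousarray(frame.to_numpy()),
        dropped_columns=dropped,
        failed_ids=failed,
    )


@dataclass
class ProjectionModel:
    """Frozen PCA of descriptor space (fit once, reused for all projections)."""

    names: list[str]
    mean: np.ndarray
    scale: np.ndarray  # ones when standardize=False
    components: np.ndarray  # (n_components, n_descriptors)
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    standardized: bool

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_projection(
    matrix: DescriptorMatrix, n_components: int = 120, standardize: bool = True
) -> ProjectionModel:
    """Fit the one-time PCA on a descriptor matrix.

    Descriptors are centered and (by default) scaled to unit variance first,
    since raw descriptors span wildly different magnitudes.
    """
    X = matrix.values
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_rows, n_cols)={min(X.shape)}"
        )
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    return ProjectionModel(
        names=list(matrix.names),
        mean=mean,
        scale=scale,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
        standardized=standardize,
    )


def project(model: ProjectionModel, matrix: DescriptorMatrix) -> np.ndarray:
    """Project molecules into the fitted space; extra columns are ignored."""
    frame = matrix.to_frame()
    missing = [c for c in model.names if c not in frame.columns]
    if missing:
        raise ValueError(f"missing descriptor columns: {missing}")
    X = frame.loc[:, model.names].to_numpy()
    return (X - model.mean) / model.scale @ model.components.T


@dataclass
class Clustering:
    """k-means result selected by the lowest-variance-of-the-five-best rule."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    size_variance: float
    n_restarts: int
    chosen_run: int
    restart_inertias: np.ndarray

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def cluster(
    coordinates: np.ndarray, k: int = 100, n_restarts: int = 100, seed: int = 0
) -> Clustering:
    """Repeated seeded k-means with the restart-selection rule.

    Restart ``r`` uses ``random_state = seed + r``. Among the five restarts
    with the lowest inertia, the one with minimal population variance of
    cluster sizes is returned; ties break toward lower inertia, then lower
    run index.
    """
    n = coordinates.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    runs = []
    for r in range(n_restarts):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed + r)
        km.fit(coordinates)
        runs.append(km)
    inertias = np.array([km.inertia_ for km in runs])
    best5 = np.argsort(inertias, kind="stable")[: min(5, n_restarts)]
    ranked = sorted(
        best5,
        key=lambda r: (
            float(np.var(np.bincount(runs[r].labels_, minlength=k))),
            float(inertias[r]),
            int(r),
        ),
    )
    chosen = int(ranked[0])
    km = runs[chosen]
    return Clustering(
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        size_variance=float(np.var(np.bincount(km.labels_, minlength=k))),
        n_restarts=n_restarts,
        chosen_run=chosen,
        restart_inertias=inertias,
    )


def select_for_scoring(
    clustering: Clustering,
    ids: Sequence[str],
    per_cluster_cap: int = 10,
    total: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Cluster-stratified subset for scoring.

    First pass: up to ``per_cluster_cap`` random molecules from each cluster
    (all of them if the cluster is smaller). If the running total is below
    ``total``, top up uniformly from not-yet-selected molecules in clusters
    larger than the cap. A shortfall (population < total) is reported via a
    warning, not an error.
    """
    if per_cluster_cap < 1 or total < 1:
        raise ValueError("per_cluster_cap and total must be >= 1")
    if len(ids) != len(clustering.labels):
        raise ValueError("ids and clustering labels disagree in length")
    rng = np.random.default_rng(seed)
    ids = list(ids)
    selected: list[int] = []
    leftovers: list[int] = []
    for label in range(clustering.k):
        members = clustering.members(label)
        if len(members) == 0:
            continue
        if len(members) <= per_cluster_cap:
            selected.extend(members.tolist())
        else:
            perm = rng.permutation(members)
            selected.extend(perm[:per_cluster_cap].tolist())
            leftovers.extend(perm[per_cluster_cap:].tolist())
    if len(selected) < total and leftovers:
        extra = rng.permutation(leftovers)[: total - len(selected)]
        selected.extend(int(i) for i in extra)
    if len(selected) < total:
        warnings.warn(
            f"selection shortfall: {len(selected)}/{total} molecules available"
        )
    return [ids[i] for i in selected]
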