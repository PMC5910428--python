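"""Structural-cluster datasets: extraction, labels, class weights, CV splits.

The unit of prediction is a *structural cluster*: a target residue plus its
N nearest neighbor residues ranked by Cα–Cα distance (neighbors may come
from any chain of the assembly, so interfaces are part of the environment).
Clusters containing any atom with occupancy < 1 or a residue with missing
backbone atoms are discarded during training-set extraction.

Archive format (HDF5, single file):

* ``features`` — float32, shape (clusters, N, 31), pair-feature rows in
  ascending-neighbor-distance order (column layout documented in
  :mod:`pdnet.geometry_features`);
* ``labels`` — int8, 0–19 in alphabetical amino-acid order ``ACDEFGHIKLMNPQRSTVWY``;
* ``folds`` — int8, cross-validation fold id per cluster (1-based);
* root attribute ``manifest`` — JSON with name, N, counts and feature version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry_features import FEATURE_VERSION, PAIR_FEATURE_SIZE, ChainContext, FeatureError
from .structure_io import AA_ALPHABET, AA_INDEX, ResidueRecord

__all__ = [
    "StructuralCluster",
    "DatasetManifest",
    "Dataset",
    "ExtractionResult",
    "extract_clusters",
    "class_weights",
    "kfold_split",
    "save_dataset",
    "load_dataset",
    "ARCHIVE_VERSION",
]

ARCHIVE_VERSION = 1


@dataclass
class StructuralCluster:
    """A target residue, its N nearest neighbors and their pair features."""

    target_index: int
    neighbor_indices: list[int]  # ascending Cα–Cα distance
    neighbor_distances: np.ndarray
    label: int | None  # 0-19, alphabetical; None when the target is non-standard
    features: np.ndarray  # (N, 31)
    position_id: str = ""


@dataclass
class ExtractionResult:
    clusters: list[StructuralCluster]
    dropped: list[tuple[str, str]]  # (position id, reason)


def extract_clusters(residues: list[ResidueRecord], n_neighbors: int,
                     require_full_occupancy: bool = True,
                     require_standard_target: bool = True,
                     context: ChainContext | None = None) -> ExtractionResult:
    """Extract one cluster per eligible target residue.

    Every residue of ``residues`` is a candidate target; neighbors are drawn
    from all residues (all chains).  A cluster is dropped — with a logged
    reason — when any member residue is missing backbone atoms, when any
    member atom has occupancy < 1 (training mode), or when the target is not
    one of the 20 canonical amino acids and a label is required.
    Distance ties are broken by (chain_id, seq_index).
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n_neighbors >= len(residues):
        raise ValueError(
            f"n_neighbors={n_neighbors} requires more than {n_neighbors} residues, "
            f"got {len(residues)}")
    if context is None:
        # Incomplete residues are handled by dropping the affected clusters,
        # so the shared feature context must tolerate them.
        context = ChainContext(residues, skip_incomplete=True)

    has_ca = np.array([r.atom("CA") is not None for r in residues])
    cas = np.array([r.coord("CA") if ok else np.zeros(3)
                    for r, ok in zip(residues, has_ca)])
    order_key = [(r.chain_id, r.seq_index, r.insertion_code) for r in residues]

    clusters: list[StructuralCluster] = []
    dropped: list[tuple[str, str]] = []
    for t, res in enumerate(residues):
        pid = res.position_id()
        if not has_ca[t] or not res.has_backbone():
            dropped.append((pid, "missing_backbone"))
            continue
        if require_standard_target and not res.is_standard:
            dropped.append((pid, "nonstandard_target"))
            continue
        d = np.linalg.norm(cas - cas[t], axis=1)
        cand = [j for j in range(len(residues)) if j != t and has_ca[j]]
        cand.sort(key=lambda j: (d[j], order_key[j]))
        if len(cand) < n_neighbors:
            dropped.append((pid, "too_few_residues"))
            continue
        nbrs = cand[:n_neighbors]
        members = [t] + nbrs
        if any(not residues[j].has_backbone() for j in nbrs):
            dropped.append((pid, "missing_backbone"))
            continue
        if require_full_occupancy and any(not residues[j].full_occupancy() for j in members):
            dropped.append((pid, "occupancy"))
            continue
        try:
            from .geometry_features import canonical_frame
            frame = canonical_frame(res)
            feats = np.stack([context.pair_features(t, j, frame) for j in nbrs])
        except FeatureError as exc:
            dropped.append((pid, f"feature: {exc}"))
            continue
        clusters.append(StructuralCluster(
            target_index=t,
            neighbor_indices=nbrs,
            neighbor_distances=d[nbrs],
            label=AA_INDEX.get(res.aa_type),
            features=feats,
            position_id=pid,
        ))
    return ExtractionResult(clusters=clusters, dropped=dropped)


def class_weights(counts) -> np.ndarray:
    """Per-class training weights W_i = N_max / N_i.

    ``counts`` is a length-20 array (or mapping class index → count).  The
    most abundant class gets weight exactly 1; classes absent from the data
    get weight 0 by convention.  Scale-invariant in the counts.
    """
    if isinstance(counts, dict):
        arr = np.zeros(20)
        for k, v in counts.items():
            arr[AA_INDEX[k] if isinstance(k, str) else k] = v
    else:
        arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("class counts must be nonnegative")
    n_max = arr.max()
    if n_max <= 0:
        raise ValueError("all class counts are zero")
    w = np.zeros_like(arr)
    present = arr > 0
    w[present] = n_max / arr[present]
    return w


def kfold_split(n_clusters: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random k-fold assignment (1-based fold ids), sizes differing by ≤ 1.

    Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_clusters < k:
        raise ValueError(f"cannot split {n_clusters} clusters into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_clusters) % k + 1
    return folds[rng.permutation(n_clusters)].astype(np.int8)


@dataclass
class DatasetManifest:
    """Provenance of one dataset archive (name pattern e.g. ``SI30N15``)."""

    name: str
    n_neighbors: int
    cluster_count: int
    class_counts: list[int] = field(default_factory=lambda: [0] * 20)
    feature_version: str = FEATURE_VERSION
    archive_version: int = ARCHIVE_VERSION

    def validate(self) -> None:
        if len(self.class_counts) != 20:
            raise ValueError("class_counts must have 20 entries")
        if sum(self.class_counts) != self.cluster_count:
            raise ValueError("class counts do not sum to the cluster count")


@dataclass
class Dataset:
    """In-memory dataset: features (M, N, 31), labels (M,), fold ids (M,)."""

    manifest: DatasetManifest
    features: np.ndarray
    labels: np.ndarray
    folds: np.ndarray

    @classmethod
    def from_clusters(cls, clusters: list[StructuralCluster], name: str,
                      k: int = 5, seed: int = 0) -> "Dataset":
        labeled = [c for c in clusters if c.label is not None]
        if not labeled:
            raise ValueError("no labeled clusters")
        feats = np.stack([c.features for c in labeled]).astype(np.float32)
        labels = np.array([c.label for c in labeled], dtype=np.int8)
        counts = np.bincount(labels, minlength=20).tolist()
        manifest = DatasetManifest(
            name=name, n_neighbors=feats.shape[1], cluster_count=len(labeled),
            class_counts=counts)
        return cls(manifest=manifest, features=feats, labels=labels,
                   folds=kfold_split(len(labeled), k=k, seed=seed))

    def subset(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.features[mask], self.labels[mask]


class ArchiveError(ValueError):
    """Corrupted, inconsistent or version-mismatched dataset archive."""


def save_dataset(ds: Dataset, path) -> None:
    """Write the dataset to a single HDF5 archive (bit-reproducible)."""
    import h5py

    ds.manifest.validate()
    if ds.features.shape != (ds.manifest.cluster_count, ds.manifest.n_neighbors,
                             PAIR_FEATURE_SIZE):
        raise ArchiveError(f"feature array shape {ds.features.shape} inconsistent with manifest")
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["manifest"] = json.dumps(ds.manifest.__dict__, sort_keys=True)
        for key, arr, dt in (("features", ds.features, np.float32),
                             ("labels", ds.labels, np.int8),
                             ("folds", ds.folds, np.int8)):
            f.create_dataset(key, data=np.asarray(arr, dtype=dt), track_times=False)


def load_dataset(path) -> Dataset:
    """Read a dataset archive; validates schema, shapes and versions."""
    import h5py

    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise ArchiveError("archive has no manifest")
        manifest = DatasetManifest(**json.loads(f.attrs["manifest"]))
        if manifest.archive_version != ARCHIVE_VERSION:
            raise ArchiveError(f"archive version {manifest.archive_version} != {ARCHIVE_VERSION}")
        if manifest.feature_version != FEATURE_VERSION:
            raise ArchiveError(
                f"feature order {manifest.feature_version!r} != {FEATURE_VERSION!r}")
        for key in ("features", "labels", "folds"):
            if key not in f:
                raise ArchiveError(f"archive missing dataset {key!r}")
        ds = Dataset(manifest=manifest, features=f["features"][...],
                     labels=f["labels"][...], folds=f["folds"][...])
    manifest.validate()
    m, n = ds.features.shape[0], ds.features.shape[1] if ds.features.ndim == 3 else -1
    if ds.features.ndim != 3 or n != manifest.n_neighbors or ds.features.shape[2] != PAIR_FEATURE_SIZE:
        raise ArchiveError(
            f"feature array shape {ds.features.shape} inconsistent with declared "
            f"N={manifest.n_neighbors}")
    if m != manifest.cluster_count or len(ds.labels) != m or len(ds.folds) != m:
        raise ArchiveError("cluster count mismatch between manifest and arrays")
    return ds
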