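"""Metrics for residue-type prediction: accuracy, top-K, per-class
recall/precision, native-vs-predicted confusion probabilities, sequence
identity, profile RMSE and contact-rank coverage of the N-nearest-neighbor
environment definition.

Top-1 and top-K ties are broken by alphabetical amino-acid order, so every
metric is deterministic.  Per-class recall/precision with an empty
denominator is reported as missing (``None``), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AA_ALPHABET, ResidueRecord

__all__ = [
    "top1_labels",
    "top_k_sets",
    "overall_accuracy",
    "top_k_accuracy",
    "recall_precision",
    "confusion_probability_matrix",
    "sequence_identity",
    "profile_rmse",
    "contact_rank_coverage",
    "metrics_report",
]


def _probs_natives(profiles) -> tuple[np.ndarray, np.ndarray]:
    """Accept a PredictionProfile or a (probs, natives) pair."""
    if hasattr(profiles, "probabilities"):
        probs = np.asarray(profiles.probabilities, dtype=float)
        if profiles.native is None:
            raise ValueError("profile has no native labels")
        natives = np.array([AA_ALPHABET.index(a) for a in profiles.native])
    else:
        probs, natives = profiles
        probs = np.asarray(probs, dtype=float)
        natives = np.asarray(natives, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != 20:
        raise ValueError("profiles must be an (L, 20) probability matrix")
    if len(natives) != len(probs):
        raise ValueError("native labels and profile rows differ in length")
    if len(probs) == 0:
        raise ValueError("empty profile")
    return probs, natives


def top1_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties resolve to the alphabetically first."""
    return np.argmax(probs, axis=1)  # np.argmax returns the first maximum


def top_k_sets(probs: np.ndarray, k: int) -> np.ndarray:
    """(L, k) class indices of the K most probable amino acids per row,
    descending probability, ties alphabetical."""
    if not 1 <= k <= 20:
        raise ValueError("K must lie in [1, 20]")
    order = np.argsort(-probs, axis=1, kind="stable")
    return order[:, :k]


def overall_accuracy(profiles) -> float:
    """Fraction of positions whose top-1 prediction equals the native type."""
    probs, natives = _probs_natives(profiles)
    return float(np.mean(top1_labels(probs) == natives))


def top_k_accuracy(profiles, k: int) -> float:
    """Fraction of positions whose native type is among the top-K predictions."""
    probs, natives = _probs_natives(profiles)
    sets = top_k_sets(probs, k)
    return float(np.mean(np.any(sets == natives[:, None], axis=1)))


def recall_precision(profiles) -> dict[str, tuple[float | None, float | None, int]]:
    """Per-amino-acid (recall, precision, native support).

    recall_a = correct_a / #native_a; precision_a = correct_a / #predicted_a.
    A quantity with zero denominator is ``None``.
    """
    probs, natives = _probs_natives(profiles)
    pred = top1_labels(probs)
    out: dict[str, tuple[float | None, float | None, int]] = {}
    for c, aa in enumerate(AA_ALPHABET):
        n_native = int(np.sum(natives == c))
        n_pred = int(np.sum(pred == c))
        n_correct = int(np.sum((natives == c) & (pred == c)))
        rec = n_correct / n_native if n_native else None
        prec = n_correct / n_pred if n_pred else None
        out[aa] = (rec, prec, n_native)
    return out


@dataclass
class ConfusionProbabilityMatrix:
    """Row-normalized native→predicted counts: entry (a, b) is the
    probability that a native residue of type a is predicted as type b."""

    matrix: np.ndarray  # (20, 20)
    support: np.ndarray  # native counts per row

    def reordered(self, order: list[str]) -> np.ndarray:
        idx = [AA_ALPHABET.index(a) for a in order]
        return self.matrix[np.ix_(idx, idx)]


def confusion_probability_matrix(profiles) -> ConfusionProbabilityMatrix:
    probs, natives = _probs_natives(profiles)
    pred = top1_labels(probs)
    counts = np.zeros((20, 20))
    np.add.at(counts, (natives, pred), 1.0)
    support = counts.sum(axis=1)
    matrix = np.divide(counts, support[:, None], out=np.zeros_like(counts),
                       where=support[:, None] > 0)
    return ConfusionProbabilityMatrix(matrix=matrix, support=support.astype(int))


def sequence_identity(predicted: str, native: str) -> float:
    """Position-wise fraction of identical residues (no alignment)."""
    if len(predicted) != len(native):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(native)}")
    if not native:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(predicted, native)) / len(native)


def profile_rmse(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Root-mean-square difference over all 20·L entries of two profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def contact_rank_coverage(residues: list[ResidueRecord], rank_n: int,
                          contact_cutoff: float = 4.5) -> float | None:
    """Fraction of contacting target–neighbor pairs covered by the N nearest.

    A neighbor *contacts* the target when any heavy-atom pair is closer than
    ``contact_cutoff`` Å (sidechain atoms are used when present).  For each
    target, neighbors are ranked by Cα–Cα distance; the coverage is the
    fraction of contacting neighbors whose rank M satisfies M ≤ ``rank_n``.
    Returns ``None`` when the structure has no contacts at all.
    """
    from scipy.spatial import cKDTree

    heavy_coords, heavy_owner = [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            if a.element.upper() not in ("H", "D"):
                heavy_coords.append(a.coord)
                heavy_owner.append(i)
    idx = [i for i, r in enumerate(residues) if r.atom("CA") is not None]
    if len(idx) < 2 or not heavy_coords:
        return None
    heavy_coords = np.asarray(heavy_coords)
    heavy_owner = np.asarray(heavy_owner)
    tree = cKDTree(heavy_coords)
    contacts: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(contact_cutoff):
        i, j = heavy_owner[a], heavy_owner[b]
        if i != j:
            contacts.add((min(i, j), max(i, j)))
    if not contacts:
        return None

    cas = np.array([residues[i].coord("CA") for i in idx])
    pos_of = {i: k for k, i in enumerate(idx)}
    dist = np.linalg.norm(cas[:, None, :] - cas[None, :, :], axis=-1)
    # rank[i, j]: position of j in i's ascending-distance neighbor list.
    ranks = np.empty_like(dist, dtype=int)
    for k in range(len(idx)):
        order = np.argsort(dist[k], kind="stable")
        ranks[k, order] = np.arange(len(idx))  # self gets rank 0

    covered = total = 0
    for (i, j) in contacts:
        if i not in pos_of or j not in pos_of:
            continue
        for t, nb in ((i, j), (j, i)):
            total += 1
            if ranks[pos_of[t], pos_of[nb]] <= rank_n:
                covered += 1
    return covered / total if total else None


def metrics_report(profiles) -> tuple[dict[str, float], "pd.DataFrame"]:
    """Flat key–value metric summary plus a per-class recall/precision table."""
    import pandas as pd

    summary = {"accuracy": overall_accuracy(profiles)}
    for k in (2, 3, 5, 10):
        summary[f"top{k}_accuracy"] = top_k_accuracy(profiles, k)
    rp = recall_precision(profiles)
    table = pd.DataFrame(
        [(aa, rec, prec, sup) for aa, (rec, prec, sup) in rp.items()],
        columns=["class", "recall", "precision", "support"])
    return summary, table
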