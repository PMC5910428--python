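"""Synthetic structures and datasets: the package is fully testable offline.

Backbones are built from internal coordinates (NeRF-style sequential atom
placement) with standard peptide geometry, written out as toy PDB files, and
assembled into small labeled cluster datasets whose labels are a
deterministic function of the generating backbone geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, DatasetManifest, kfold_split
from .geometry_features import ChainContext, canonical_frame
from .structure_io import AA_ALPHABET, AA_INDEX, ONE_TO_THREE, AtomRecord, ResidueRecord

__all__ = [
    "BackboneSpec",
    "build_ideal_backbone",
    "make_ideal_helix",
    "make_ideal_strand",
    "make_ideal_sheet",
    "make_toy_pdb",
    "place_atom",
    "learnable_dataset",
    "imbalanced_dataset",
    "LEARNABLE_CLASSES",
]

# Standard peptide geometry (Å, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

HELIX_TORSIONS = (-57.0, -47.0, 180.0)
STRAND_TORSIONS = (-120.0, 120.0, 180.0)
LOOP_TORSIONS = (60.0, 60.0, 180.0)


@dataclass
class BackboneSpec:
    """Per-residue (φ, ψ, ω) torsions plus the bond geometry to realize them.

    φ of the first residue and ω of the first residue are not realizable and
    are ignored; ψ of the last residue only orients its carbonyl oxygen.
    """

    torsions: list[tuple[float, float, float]]
    bond_n_ca: float = BOND_N_CA
    bond_ca_c: float = BOND_CA_C
    bond_c_n: float = BOND_C_N
    angle_n_ca_c: float = ANGLE_N_CA_C
    angle_ca_c_n: float = ANGLE_CA_C_N
    angle_c_n_ca: float = ANGLE_C_N_CA

    def __post_init__(self) -> None:
        if len(self.torsions) < 2:
            raise ValueError("a backbone needs at least 2 residues")
        for v in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n):
            if v <= 0:
                raise ValueError("bond lengths must be positive")
        for a in (self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if not 0 < a < 180:
                raise ValueError("bond angles must lie in (0, 180) degrees")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c−d| = length, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (same sign convention as
    :func:`pdnet.geometry_features.dihedral`)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("degenerate placement: a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)
    # Sign of the normal component chosen so that dihedral(a, b, c, d)
    # equals +torsion under the IUPAC convention used by `dihedral`.
    d_local = np.array([
        -length * np.cos(theta),
        length * np.cos(chi) * np.sin(theta),
        -length * np.sin(chi) * np.sin(theta),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_backbone(spec: BackboneSpec, chain_id: str = "A",
                         sequence: str | None = None,
                         start_index: int = 1) -> list[ResidueRecord]:
    """Build a backbone (N, Cα, C, O per residue) realizing the given torsions.

    Recomputing φ/ψ/ω from the returned coordinates recovers the specified
    angles.  The carbonyl O of residue i is placed in the Cα–C–N(i+1) plane
    (torsion N–Cα–C–O = ψ_i + 180°) at 1.231 Å, 120.5° from the Cα–C bond.
    """
    n_res = len(spec.torsions)
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match the torsion list")

    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([spec.bond_n_ca, 0.0, 0.0])
    th = np.radians(spec.angle_n_ca_c)
    c0 = ca0 + spec.bond_ca_c * np.array([-np.cos(th), np.sin(th), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi_i, _, omega_i = spec.torsions[i]
        psi_prev = spec.torsions[i - 1][1]
        prev = coords[i - 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         spec.bond_c_n, spec.angle_ca_c_n, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          spec.bond_n_ca, spec.angle_c_n_ca, omega_i)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         spec.bond_ca_c, spec.angle_n_ca_c, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, atom in enumerate(coords):
        psi_i = spec.torsions[i][1]
        atom["O"] = place_atom(atom["N"], atom["CA"], atom["C"],
                               BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)

    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    return [
        ResidueRecord(
            chain_id=chain_id,
            seq_index=start_index + i,
            insertion_code="",
            aa_type=sequence[i],
            atoms=[AtomRecord(name=k, element=elements[k], coord=v.copy())
                   for k, v in coords[i].items()],
        )
        for i in range(n_res)
    ]


def make_ideal_helix(n_res: int, chain_id: str = "A", sequence: str | None = None,
                     start_index: int = 1) -> list[ResidueRecord]:
    """Ideal α-helix (φ, ψ, ω) = (−57, −47, 180)."""
    return build_ideal_backbone(BackboneSpec([HELIX_TORSIONS] * n_res),
                                chain_id=chain_id, sequence=sequence,
                                start_index=start_index)


def make_ideal_strand(n_res: int, chain_id: str = "A", sequence: str | None = None,
                      start_index: int = 1) -> list[ResidueRecord]:
    """Ideal extended β-strand (φ, ψ, ω) = (−120, 120, 180)."""
    return build_ideal_backbone(BackboneSpec([STRAND_TORSIONS] * n_res),
                                chain_id=chain_id, sequence=sequence,
                                start_index=start_index)


def _transform(residues: list[ResidueRecord], rot: np.ndarray,
               shift: np.ndarray) -> list[ResidueRecord]:
    out = []
    for r in residues:
        out.append(ResidueRecord(
            chain_id=r.chain_id, seq_index=r.seq_index,
            insertion_code=r.insertion_code, aa_type=r.aa_type,
            atoms=[AtomRecord(a.name, a.element, rot @ a.coord + shift,
                              a.occupancy, a.altloc) for a in r.atoms],
            is_standard=r.is_standard))
    return out


def make_ideal_sheet(n_per_strand: int = 8) -> list[ResidueRecord]:
    """Two antiparallel β-strands (chains A and B) paired by backbone H-bonds.

    The second strand's rigid placement is chosen by a deterministic grid
    search maximizing the inter-chain hydrogen-bond count.
    """
    from scipy.spatial.transform import Rotation

    from .geometry_features import backbone_hbond_map

    a = make_ideal_strand(n_per_strand, chain_id="A")
    cas = np.array([r.coord("CA") for r in a])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    centroid = cas.mean(axis=0)
    # A reference direction perpendicular to the strand axis.
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    flip = Rotation.from_rotvec(np.pi * perp).as_matrix()  # antiparallel
    best, best_count = None, -1
    for roll_deg in range(0, 360, 30):
        roll = Rotation.from_rotvec(np.radians(roll_deg) * axis).as_matrix()
        rot = roll @ flip
        for sep in np.arange(4.2, 5.6, 0.2):
            for slide in np.arange(-3.5, 3.6, 0.5):
                shift = centroid - rot @ centroid + sep * perp + slide * axis
                b = _transform(a, rot, shift)
                for r in b:
                    r.chain_id = "B"
                residues = a + b
                count = sum(1 for (i, j) in backbone_hbond_map(residues)
                            if (i < n_per_strand) != (j < n_per_strand))
                if count > best_count:
                    best, best_count = residues, count
    if best_count < 1:
        raise RuntimeError("sheet construction found no inter-strand hydrogen bonds")
    return best


# ---------------------------------------------------------------------------
# Toy PDB writer


def _pdb_atom_name(name: str) -> str:
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def make_toy_pdb(chains: list[list[ResidueRecord]], hetero: tuple = (),
                 method: str | None = None, resolution: float | None = None) -> str:
    """Serialize residue chains as PDB text (parseable by ``parse_structure``).

    ``hetero`` entries ``(resname, atom_name, element, coord)`` are appended
    as HETATM records (for water/ion/ligand filter tests).  ``method`` and
    ``resolution`` emit EXPDTA / REMARK 2 header lines when given.
    """
    lines: list[str] = []
    if method is not None:
        lines.append(f"EXPDTA    {method.upper()}")
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:6.2f} ANGSTROMS.")
    serial = 1
    for chain in chains:
        last = None
        for res in chain:
            resname = ONE_TO_THREE.get(res.aa_type, "UNK")
            for atom in res.atoms:
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {_pdb_atom_name(atom.name)}{'':1s}{resname:>3s} "
                    f"{res.chain_id:1s}{res.seq_index:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
            last = res
        if last is not None:
            lines.append(f"TER   {serial:5d}      "
                         f"{ONE_TO_THREE.get(last.aa_type, 'UNK'):>3s} "
                         f"{last.chain_id:1s}{last.seq_index:4d}")
            serial += 1
    for k, (resname, atom_name, element, coord) in enumerate(hetero):
        x, y, z = coord
        lines.append(
            f"HETATM{serial:5d} {_pdb_atom_name(atom_name)}{'':1s}{resname:>3s} "
            f"X{900 + k:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Synthetic labeled datasets

# Geometry class → (torsion center, label letter). Labels live in the full
# 20-class space; only these three classes occur.
LEARNABLE_CLASSES = {
    "helix": (HELIX_TORSIONS, "A"),
    "strand": (STRAND_TORSIONS, "C"),
    "loop": (LOOP_TORSIONS, "D"),
}


def _cluster_features_for_chain(residues: list[ResidueRecord],
                                n_neighbors: int) -> np.ndarray:
    """Pair-feature matrix for the middle residue of a short chain whose
    other residues are exactly its N neighbors."""
    ctx = ChainContext(residues)
    t = len(residues) // 2
    frame = canonical_frame(residues[t])
    cas = np.array([r.coord("CA") for r in residues])
    d = np.linalg.norm(cas - cas[t], axis=1)
    order = sorted((j for j in range(len(residues)) if j != t), key=lambda j: (d[j], j))
    return np.stack([ctx.pair_features(t, j, frame) for j in order[:n_neighbors]])


def _geometry_dataset(n_clusters: int, n_neighbors: int, seed: int,
                      classes: list[tuple[tuple[float, float, float], str]],
                      fractions: np.ndarray, coord_noise: float,
                      jitter_deg: float, name: str,
                      quantize_deg: float = 0.0) -> Dataset:
    rng = np.random.default_rng(seed)
    chain_len = n_neighbors + 1
    # Deterministic class assignment honoring the requested marginals.
    draws = rng.random(n_clusters)
    cum = np.cumsum(fractions)
    feats, labels = [], []
    for draw in draws:
        cls = int(np.searchsorted(cum, draw))
        center, letter = classes[cls]
        torsions = []
        offset = rng.normal(0.0, jitter_deg, size=2) if jitter_deg > 0 else np.zeros(2)
        if quantize_deg > 0:
            offset = np.round(offset / quantize_deg) * quantize_deg
        for _ in range(chain_len):
            torsions.append((center[0] + offset[0], center[1] + offset[1], center[2]))
        residues = build_ideal_backbone(BackboneSpec(torsions),
                                        sequence=letter * chain_len)
        if coord_noise > 0:
            for r in residues:
                for a in r.atoms:
                    a.coord = a.coord + rng.normal(0.0, coord_noise, size=3)
        feats.append(_cluster_features_for_chain(residues, n_neighbors))
        labels.append(AA_INDEX[letter])
    features = np.stack(feats).astype(np.float32)
    labels = np.array(labels, dtype=np.int8)
    manifest = DatasetManifest(
        name=name, n_neighbors=n_neighbors, cluster_count=n_clusters,
        class_counts=np.bincount(labels, minlength=20).tolist())
    return Dataset(manifest=manifest, features=features, labels=labels,
                   folds=kfold_split(n_clusters, k=5, seed=seed))


def learnable_dataset(n_clusters: int = 2000, n_neighbors: int = 5, seed: int = 0,
                      class_fractions: tuple = (1 / 3, 1 / 3, 1 / 3),
                      coord_noise: float = 0.05) -> Dataset:
    """Separable-by-construction dataset: labels follow the backbone class.

    Each cluster is the middle residue of a short ideal helix / strand /
    loop-like chain (plus Gaussian coordinate noise, σ = 0.05 Å) with its
    ``n_neighbors`` chain mates as the environment.  The label is a
    deterministic function of the generating geometry (helix→A, strand→C,
    loop→D), so the Bayes-optimal accuracy is 1 by construction.
    """
    if n_clusters < 100:
        raise ValueError("n_clusters must be >= 100")
    fractions = np.asarray(class_fractions, dtype=float)
    if len(fractions) != 3 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("class_fractions must be 3 values summing to 1")
    classes = [LEARNABLE_CLASSES[k] for k in ("helix", "strand", "loop")]
    return _geometry_dataset(n_clusters, n_neighbors, seed, classes, fractions,
                             coord_noise, 0.0, f"toy-learnable-N{n_neighbors}")


def imbalanced_dataset(n_clusters: int = 2000, n_neighbors: int = 5, seed: int = 0,
                       fractions: tuple = (0.95, 0.05),
                       center_sep_deg: float = 20.0,
                       jitter_deg: float = 15.0,
                       quantize_deg: float = 10.0,
                       coord_noise: float = 0.0) -> Dataset:
    """Binary imbalanced dataset with *overlapping* classes.

    The two classes are helix-like backbones whose (φ, ψ) centers are
    ``center_sep_deg`` apart, with a per-chain Gaussian torsion offset of
    ``jitter_deg`` *quantized* to a ``quantize_deg`` grid.  Chains landing in
    the same grid cell have identical features, and in the overlap region
    both labels occur in one cell — so the training set itself is
    Bayes-limited (no model can memorize past the cell-wise label mixture)
    and the decision in each mixed cell is a weighted vote: class weighting
    flips the vote toward the minority class exactly where
    19·N_minority(cell) > N_majority(cell).  Minority recall therefore
    genuinely depends on class weighting.  Majority label A, minority C.
    """
    if n_clusters < 100:
        raise ValueError("n_clusters must be >= 100")
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != 2 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be 2 values summing to 1")
    phi0, psi0, omega = HELIX_TORSIONS
    classes = [
        ((phi0, psi0, omega), "A"),
        ((phi0 + center_sep_deg, psi0 + center_sep_deg, omega), "C"),
    ]
    return _geometry_dataset(n_clusters, n_neighbors, seed, classes, fractions,
                             coord_noise, jitter_deg,
                             f"toy-imbalanced-N{n_neighbors}",
                             quantize_deg=quantize_deg)
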