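"""Per-residue and per-pair structural features of a protein backbone.

Every directional feature is expressed in the *canonical frame* of the target
residue: the rigid transform that puts its Cα at the origin, its N on the −x
axis and its C in the z = 0 plane (with positive y, which fixes the otherwise
two-fold frame ambiguity).  This makes the features invariant under global
rigid motion of the structure.

Feature vector layout (one row per target–neighbor pair, 31 values):

====  =========================================================
cols  content
====  =========================================================
0-5   target (cos φ, sin φ, cos ψ, sin ψ, cos ω, sin ω)
6     target backbone SASA, Å²
7-9   target secondary structure one-hot (helix, sheet, loop)
10-15 neighbor dihedral cos/sin, same order
16    neighbor backbone SASA, Å²
17-19 neighbor secondary structure one-hot
20    Cα–Cα distance, Å
21-23 unit vector target Cα → neighbor Cα, canonical frame
24-26 neighbor Cα → N unit vector, canonical frame
27-29 neighbor Cα → C unit vector, canonical frame
30    backbone–backbone hydrogen-bond count between the pair
====  =========================================================

Undefined dihedrals (chain termini, chain breaks) are encoded as
(cos, sin) = (0, 0) — a point off the unit circle that a downstream model can
recognize as a sentinel.  ω of residue i describes the peptide bond
*preceding* residue i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BACKBONE_ATOMS, ResidueRecord

__all__ = [
    "BackboneDihedrals",
    "LocalFrame",
    "ChainContext",
    "GeometryError",
    "FeatureError",
    "dihedral",
    "backbone_dihedrals",
    "chain_breaks",
    "assign_secondary_structure",
    "backbone_sasa",
    "backbone_hbond_map",
    "count_backbone_hbonds",
    "canonical_frame",
    "pair_features",
    "PAIR_FEATURE_SIZE",
    "FEATURE_VERSION",
    "SS_LABELS",
]

PAIR_FEATURE_SIZE = 31
FEATURE_VERSION = "pairfeat-v1"
SS_LABELS = ("helix", "sheet", "loop")

# SASA parameters: Shrake-Rupley, Naccess-compatible radii (Å).
SASA_PROBE_RADIUS = 1.4
SASA_POINT_NUMBER = 960
SASA_RADII = {"N": 1.65, "CA": 1.76, "C": 1.76, "O": 1.40}

# Hydrogen-bond criterion: electrostatic N-H...O=C energy (kcal/mol) below
# this threshold counts as a bond.
HBOND_ENERGY_CUTOFF = -0.5
HBOND_CA_CUTOFF = 9.0  # Å; pairs with larger Cα separation are never bonded
PEPTIDE_BOND_BREAK = 2.0  # Å; C(i)-N(i+1) beyond this is a chain break


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, missing atoms)."""


class FeatureError(ValueError):
    """A pair-feature component could not be computed."""


# ---------------------------------------------------------------------------
# Dihedrals


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (−180, 180].

    Clockwise rotation of p4 relative to p1, looking from p2 toward p3, is
    positive.  Antisymmetric under reversing the point order.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise GeometryError("dihedral undefined: three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class BackboneDihedrals:
    """φ/ψ/ω of one residue in degrees; ``None`` marks an undefined angle."""

    phi: float | None
    psi: float | None
    omega: float | None

    @property
    def cos_sin(self) -> np.ndarray:
        """6-vector (cos φ, sin φ, cos ψ, sin ψ, cos ω, sin ω); undefined → (0, 0)."""
        out = np.zeros(6)
        for k, ang in enumerate((self.phi, self.psi, self.omega)):
            if ang is not None:
                r = np.radians(ang)
                out[2 * k] = np.cos(r)
                out[2 * k + 1] = np.sin(r)
        return out


def chain_breaks(chain: list[ResidueRecord]) -> np.ndarray:
    """Boolean array of length len(chain)-1: True where the peptide bond
    between residue i and i+1 is broken (C–N distance > 2 Å or atoms absent)."""
    breaks = np.zeros(max(len(chain) - 1, 0), dtype=bool)
    for i in range(len(chain) - 1):
        c = chain[i].atom("C")
        n = chain[i + 1].atom("N")
        if c is None or n is None or np.linalg.norm(c.coord - n.coord) > PEPTIDE_BOND_BREAK:
            breaks[i] = True
    return breaks


def backbone_dihedrals(chain: list[ResidueRecord], i: int,
                       breaks: np.ndarray | None = None) -> BackboneDihedrals:
    """φ, ψ, ω of residue ``chain[i]``.

    φ_i = C(i−1)–N(i)–Cα(i)–C(i); ψ_i = N(i)–Cα(i)–C(i)–N(i+1);
    ω_i = Cα(i−1)–C(i−1)–N(i)–Cα(i).  Angles spanning a terminus or a chain
    break are undefined.
    """
    if not 0 <= i < len(chain):
        raise IndexError(f"residue index {i} out of range")
    if breaks is None:
        breaks = chain_breaks(chain)
    res = chain[i]
    if not res.has_backbone():
        raise GeometryError(f"residue {res.position_id()} lacks backbone atoms")
    prev_ok = i > 0 and not breaks[i - 1] and chain[i - 1].has_backbone()
    next_ok = i < len(chain) - 1 and not breaks[i] and chain[i + 1].has_backbone()

    phi = psi = omega = None
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    if prev_ok:
        pc, pca = chain[i - 1].coord("C"), chain[i - 1].coord("CA")
        phi = dihedral(pc, n, ca, c)
        omega = dihedral(pca, pc, n, ca)
    if next_ok:
        psi = dihedral(n, ca, c, chain[i + 1].coord("N"))
    return BackboneDihedrals(phi=phi, psi=psi, omega=omega)


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _amide_hydrogens(chain: list[ResidueRecord], breaks: np.ndarray) -> list[np.ndarray | None]:
    """Reconstructed amide H per residue: 1 Å from N, opposite the bisector of
    C(i−1)–N and Cα–N.  None for chain starts, breaks, prolines and residues
    with missing atoms (these residues cannot donate)."""
    hs: list[np.ndarray | None] = []
    for i, res in enumerate(chain):
        if i == 0 or breaks[i - 1] or res.aa_type == "P":
            hs.append(None)
            continue
        n_at, ca_at = res.atom("N"), res.atom("CA")
        c_prev = chain[i - 1].atom("C")
        if n_at is None or ca_at is None or c_prev is None:
            hs.append(None)
            continue
        n = n_at.coord
        u = c_prev.coord - n
        v = ca_at.coord - n
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        d = -(u + v)
        nd = np.linalg.norm(d)
        if nd < 1e-8:
            hs.append(None)
            continue
        hs.append(n + d / nd)
    return hs


def backbone_hbond_map(residues: list[ResidueRecord],
                       chain_of: list[str] | None = None) -> set[tuple[int, int]]:
    """Donor→acceptor pairs (i, j): N–H of residue i bonds O=C of residue j.

    Criterion: electrostatic energy
    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 kcal/mol < −0.5.
    Pairs closer than 2 in sequence within one chain never bond.
    """
    from scipy.spatial import cKDTree

    if chain_of is None:
        chain_of = [r.chain_id for r in residues]
    # Per-chain amide-H reconstruction (needs the preceding residue).
    h_pos: list[np.ndarray | None] = [None] * len(residues)
    start = 0
    for end in range(1, len(residues) + 1):
        if end == len(residues) or chain_of[end] != chain_of[start]:
            sub = residues[start:end]
            hs = _amide_hydrogens(sub, chain_breaks(sub))
            h_pos[start:end] = hs
            start = end

    idx = [i for i, r in enumerate(residues) if r.atom("CA") is not None]
    if not idx:
        return set()
    cas = np.array([residues[i].coord("CA") for i in idx])
    tree = cKDTree(cas)
    bonds: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(HBOND_CA_CUTOFF):
        for i, j in ((idx[a], idx[b]), (idx[b], idx[a])):
            if chain_of[i] == chain_of[j] and abs(residues[i].seq_index - residues[j].seq_index) < 2:
                continue
            h = h_pos[i]
            n_at = residues[i].atom("N")
            o_at, c_at = residues[j].atom("O"), residues[j].atom("C")
            if h is None or n_at is None or o_at is None or c_at is None:
                continue
            n, o, c = n_at.coord, o_at.coord, c_at.coord
            r_on = np.linalg.norm(o - n)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - n)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clash; not a hydrogen bond
            e = 0.084 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn) * 332.0
            if e < HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def count_backbone_hbonds(hbonds: set[tuple[int, int]], i: int, j: int) -> int:
    """Number of backbone H-bonds between residues i and j (both directions)."""
    return int((i, j) in hbonds) + int((j, i) in hbonds)


# ---------------------------------------------------------------------------
# Secondary structure (3-state)

_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -40.0)


def _in(rng: tuple[float, float], x: float | None) -> bool:
    return x is not None and rng[0] < x < rng[1]


def _sheet_psi(x: float | None) -> bool:
    return x is not None and (60.0 < x <= 180.0 or -180.0 < x < -150.0)


def assign_secondary_structure(residues: list[ResidueRecord],
                               dihedrals: list[BackboneDihedrals] | None = None,
                               hbonds: set[tuple[int, int]] | None = None) -> list[str]:
    """Three-state secondary structure: ``helix`` / ``sheet`` / ``loop``.

    Helix: a run of ≥3 residues with helical φ/ψ, or residues spanned by an
    i→i+4 backbone H-bond (N of i+4 donating to O of i).  Sheet: extended
    φ/ψ plus at least one backbone H-bond to a residue more than 2 apart in
    sequence.  Everything else, including termini, is loop.
    """
    n = len(residues)
    chain_of = [r.chain_id for r in residues]
    if dihedrals is None:
        dihedrals = []
        start = 0
        for end in range(1, n + 1):
            if end == n or chain_of[end] != chain_of[start]:
                sub = residues[start:end]
                br = chain_breaks(sub)
                dihedrals.extend(backbone_dihedrals(sub, k, br) for k in range(len(sub)))
                start = end
    if hbonds is None:
        hbonds = backbone_hbond_map(residues, chain_of)

    helical = np.array([_in(_HELIX_PHI, d.phi) and _in(_HELIX_PSI, d.psi) for d in dihedrals])
    helix = np.zeros(n, dtype=bool)
    run = 0
    for i in range(n + 1):
        if i < n and helical[i]:
            run += 1
        else:
            if run >= 3:
                helix[i - run:i] = True
            run = 0
    for (i, j) in hbonds:  # i→i+4 turn pattern
        if chain_of[i] == chain_of[j] and i - j == 4:
            helix[j:i + 1] = True

    labels = []
    for i in range(n):
        if helix[i]:
            labels.append("helix")
            continue
        d = dihedrals[i]
        extended = _in(_SHEET_PHI, d.phi) and _sheet_psi(d.psi)
        partner = extended and any(
            count_backbone_hbonds(hbonds, i, j) > 0
            for j in range(n)
            if chain_of[i] != chain_of[j] or abs(residues[i].seq_index - residues[j].seq_index) > 2
        )
        labels.append("sheet" if partner else "loop")
    return labels


# ---------------------------------------------------------------------------
# Backbone SASA


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotate a point cloud into a deterministic principal-axes orientation.

    The sphere-point set used by Shrake–Rupley sampling is fixed in space, so
    raw SASA values drift slightly when the whole structure is rotated.
    Re-expressing the coordinates in their own principal axes (signs fixed by
    the largest-magnitude projection, right-handedness enforced) makes the
    SASA values exactly invariant under rigid motion of the input.
    """
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(3):
        proj = c @ vecs[:, k]
        if proj[np.argmax(np.abs(proj))] < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return c @ vecs


def backbone_sasa(residues: list[ResidueRecord], skip_incomplete: bool = False) -> np.ndarray:
    """Per-residue solvent-accessible surface area (Å²) of backbone atoms.

    Computed over the whole structure with every sidechain removed, so both
    the measured set and the occluding set contain only N, Cα, C, O —
    mimicking the design situation where sidechain identities are unknown.
    Shrake–Rupley with a 1.4 Å probe and Naccess-compatible radii.

    Residues missing backbone atoms raise :class:`GeometryError` unless
    ``skip_incomplete``, in which case they get NaN and do not occlude.
    """
    import biotite.structure as struc

    coords, radii, owner = [], [], []
    for ri, res in enumerate(residues):
        if not res.has_backbone():
            if skip_incomplete:
                continue
            raise GeometryError(f"residue {res.position_id()} lacks backbone atoms for SASA")
        for name in BACKBONE_ATOMS:
            coords.append(res.coord(name))
            radii.append(SASA_RADII[name])
            owner.append(ri)
    if not coords:
        raise GeometryError("no backbone atoms for SASA")

    arr = struc.AtomArray(len(coords))
    arr.coord = _canonical_orientation(np.asarray(coords)).astype(np.float32)
    arr.element = np.array(["X"] * len(coords))
    per_atom = struc.sasa(
        arr,
        probe_radius=SASA_PROBE_RADIUS,
        point_number=SASA_POINT_NUMBER,
        vdw_radii=np.asarray(radii),
        ignore_ions=False,
    )
    out = np.zeros(len(residues))
    np.add.at(out, np.asarray(owner), np.asarray(per_atom, dtype=float))
    mask = np.ones(len(residues), dtype=bool)
    mask[np.asarray(owner)] = False
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# Canonical frame


@dataclass
class LocalFrame:
    """Rigid transform into a residue's canonical frame: x ↦ R·(x − t)."""

    rotation: np.ndarray  # 3×3, proper orthonormal
    translation: np.ndarray  # origin of the frame (the Cα position)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.translation) @ self.rotation.T

    def apply_direction(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T


def canonical_frame(res: ResidueRecord) -> LocalFrame:
    """Frame with Cα at the origin, N on the −x axis, C in z = 0 with y > 0."""
    for name in ("N", "CA", "C"):
        if res.atom(name) is None:
            raise GeometryError(f"residue {res.position_id()} lacks atom {name} for frame")
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    x = ca - n
    xn = np.linalg.norm(x)
    if xn < 1e-8:
        raise GeometryError("N and CA coincide")
    x /= xn
    cv = c - ca
    y = cv - np.dot(cv, x) * x
    yn = np.linalg.norm(y)
    if yn < 1e-8:
        raise GeometryError(f"residue {res.position_id()}: N, CA, C are collinear")
    y /= yn
    z = np.cross(x, y)
    return LocalFrame(rotation=np.stack([x, y, z]), translation=ca.copy())


# ---------------------------------------------------------------------------
# Structure-level feature context and pair features


_SS_ONEHOT = {"helix": np.array([1.0, 0.0, 0.0]),
              "sheet": np.array([0.0, 1.0, 0.0]),
              "loop": np.array([0.0, 0.0, 1.0])}


class ChainContext:
    """All per-residue features of a structure, computed once.

    Holds dihedrals, secondary structure, backbone SASA and the backbone
    H-bond map for a flat residue list (all chains of an assembly), so that
    pair features for many clusters reuse the same per-residue work.
    """

    def __init__(self, residues: list[ResidueRecord], skip_incomplete: bool = False):
        self.residues = residues
        chain_of = [r.chain_id for r in residues]
        self.dihedrals: list[BackboneDihedrals | None] = [None] * len(residues)
        start = 0
        for end in range(1, len(residues) + 1):
            if end == len(residues) or chain_of[end] != chain_of[start]:
                sub = residues[start:end]
                br = chain_breaks(sub)
                for k in range(len(sub)):
                    if sub[k].has_backbone():
                        self.dihedrals[start + k] = backbone_dihedrals(sub, k, br)
                    elif not skip_incomplete:
                        raise GeometryError(
                            f"residue {sub[k].position_id()} lacks backbone atoms")
                start = end
        self.hbonds = backbone_hbond_map(residues, chain_of)
        complete = [d if d is not None else BackboneDihedrals(None, None, None)
                    for d in self.dihedrals]
        self.secondary_structure = assign_secondary_structure(residues, complete, self.hbonds)
        self.sasa = backbone_sasa(residues, skip_incomplete=skip_incomplete)

    def eligible(self, i: int) -> bool:
        return self.dihedrals[i] is not None

    def _residue_block(self, i: int) -> np.ndarray:
        d = self.dihedrals[i]
        if d is None or not np.isfinite(self.sasa[i]):
            raise FeatureError(
                f"residue {self.residues[i].position_id()}: missing dihedrals/SASA")
        return np.concatenate([d.cos_sin, [self.sasa[i]], _SS_ONEHOT[self.secondary_structure[i]]])

    def pair_features(self, target: int, neighbor: int,
                      frame: LocalFrame | None = None) -> np.ndarray:
        """31-vector of features for one target–neighbor pair."""
        if target == neighbor:
            raise FeatureError("target and neighbor are the same residue")
        t, nb = self.residues[target], self.residues[neighbor]
        if frame is None:
            frame = canonical_frame(t)
        delta = nb.coord("CA") - t.coord("CA")
        dist = float(np.linalg.norm(delta))
        if dist < 1e-8:
            raise FeatureError("coincident Cα positions")
        u_ca = frame.apply_direction(delta / dist)

        def unit_to(atom: str) -> np.ndarray:
            a = nb.atom(atom)
            if a is None:
                raise FeatureError(f"neighbor {nb.position_id()} lacks atom {atom}")
            v = a.coord - nb.coord("CA")
            nv = np.linalg.norm(v)
            if nv < 1e-8:
                raise FeatureError("degenerate neighbor geometry")
            return frame.apply_direction(v / nv)

        hb = count_backbone_hbonds(self.hbonds, target, neighbor)
        feat = np.concatenate([
            self._residue_block(target),
            self._residue_block(neighbor),
            [dist],
            u_ca,
            unit_to("N"),
            unit_to("C"),
            [float(hb)],
        ])
        assert feat.shape == (PAIR_FEATURE_SIZE,)
        return feat


def pair_features(residues: list[ResidueRecord], target: int, neighbor: int) -> np.ndarray:
    """Convenience one-shot wrapper around :class:`ChainContext`."""
    return ChainContext(residues).pair_features(target, neighbor)
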