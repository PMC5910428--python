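"""Read PDB-format structures into residue records and apply structure-level filters.

Only the protein content of a structure is retained: water, ions and other
HETATM ligands are dropped at parse time.  Metadata needed by the dataset
filters (experimental method, resolution, presence of nucleic acids, chain
lengths) is collected into :class:`StructureMeta`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureMeta",
    "Structure",
    "FilterConfig",
    "FilterDecision",
    "ParseError",
    "EmptyStructureError",
    "parse_structure",
    "filter_structure",
    "deduplicate_chains",
    "AA_ALPHABET",
    "AA_INDEX",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

# Canonical amino acids, alphabetical one-letter order.  This order defines
# label indices 0-19 everywhere in the package.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common D-amino-acid residue names in the PDB chemical component dictionary.
D_AMINO_NAMES = {
    "DAL", "DAR", "DSG", "DAS", "DCY", "DGN", "DGL", "DHI", "DIL",
    "DLE", "DLY", "MED", "DPN", "DPR", "DSN", "DTH", "DTR", "DTY", "DVA",
}

# Nucleic-acid residue names (polymeric ATOM records).
NUCLEIC_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """A PDB record could not be interpreted."""


class EmptyStructureError(ValueError):
    """The input contained no protein residues."""


@dataclass
class AtomRecord:
    """One atom: label, element, position (Å), occupancy and altloc id."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    """One residue with author numbering and its atoms.

    ``aa_type`` is a one-letter code from the 20 canonical amino acids, or
    ``"X"`` for a non-standard (but polymeric, non-HETATM) residue.
    """

    chain_id: str
    seq_index: int
    insertion_code: str
    aa_type: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_standard: bool = True

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.position_id()} has no atom {name!r}")
        return a.coord

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def full_occupancy(self) -> bool:
        return all(a.occupancy >= 1.0 for a in self.atoms)

    def position_id(self) -> str:
        return f"{self.chain_id}:{self.seq_index}{self.insertion_code}".rstrip()


@dataclass
class StructureMeta:
    """Structure-level metadata used by the dataset filters.

    ``resolution`` and ``method`` are ``None`` when the header lacks them
    (e.g. synthetic files); the filter treats missing fields according to
    :class:`FilterConfig`.
    """

    pdb_id: str = ""
    method: str | None = None
    resolution: float | None = None
    has_nucleic: bool = False
    has_d_amino: bool = False
    chains: dict[str, int] = field(default_factory=dict)
    chain_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")


@dataclass
class Structure:
    """Parsed protein content: metadata plus ordered residues per chain."""

    meta: StructureMeta
    chains: dict[str, list[ResidueRecord]]

    def residues(self, chain_ids: list[str] | None = None) -> list[ResidueRecord]:
        """Flat residue list over the given chains (default: all, file order)."""
        ids = list(self.chains) if chain_ids is None else chain_ids
        out: list[ResidueRecord] = []
        for cid in ids:
            out.extend(self.chains[cid])
        return out


# ---------------------------------------------------------------------------
# Parsing


def _scan_header(lines: list[str]) -> tuple[str, str | None, float | None]:
    pdb_id, method, resolution = "", None, None
    for line in lines:
        rec = line[:6].strip()
        if rec == "HEADER" and len(line) >= 66:
            pdb_id = line[62:66].strip()
        elif rec == "EXPDTA":
            method = line[10:].strip().lower() or None
        elif rec == "REMARK" and line[6:10].strip() == "2" and "RESOLUTION." in line:
            tail = line.split("RESOLUTION.", 1)[1]
            for tok in tail.split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
    return pdb_id, method, resolution


def _validate_atom_lines(lines: list[str]) -> None:
    for ln, line in enumerate(lines, start=1):
        if line[:6].strip() in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {ln}: truncated {line[:6].strip()} record "
                             f"({len(line.rstrip())} characters, need >= 54)")


def _pick_altloc(atoms: list) -> list:
    """Keep altloc 'A'/blank; else the highest-occupancy alternative."""
    from Bio.PDB.Atom import DisorderedAtom

    picked = []
    for atom in atoms:
        if isinstance(atom, DisorderedAtom):
            alts = atom.disordered_get_list()
            best = None
            for a in alts:
                if (a.get_altloc() or " ") in (" ", "A"):
                    best = a
                    break
            if best is None:
                best = max(alts, key=lambda a: a.get_occupancy() or 0.0)
            picked.append(best)
        else:
            picked.append(atom)
    return picked


def parse_structure(pdb_text: str | io.TextIOBase) -> Structure:
    """Parse PDB text into protein residues plus :class:`StructureMeta`.

    HETATM content (water, ions, ligands) is removed.  Nucleic-acid polymer
    records set ``meta.has_nucleic`` and are not returned as residues.
    Altloc handling: the 'A' or blank conformer is kept; residues with only
    other altlocs fall back to the highest-occupancy one.

    Raises :class:`ParseError` for malformed ATOM/HETATM records (with the
    line number) and :class:`EmptyStructureError` when no protein remains.
    """
    from Bio.PDB import PDBParser

    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()
    lines = pdb_text.splitlines()
    _validate_atom_lines(lines)
    pdb_id, method, resolution = _scan_header(lines)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(iter(parser.get_structure(pdb_id or "struct", io.StringIO(pdb_text))), None)
    if model is None:
        raise EmptyStructureError("no model in PDB input")

    has_nucleic = False
    has_d_amino = False
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        records: list[ResidueRecord] = []
        for res in chain:
            hetflag, seq_index, icode = res.get_id()
            resname = res.get_resname().strip()
            if hetflag != " ":
                continue  # water / ion / ligand
            if resname in NUCLEIC_NAMES:
                has_nucleic = True
                continue
            if resname in D_AMINO_NAMES:
                has_d_amino = True
            one = THREE_TO_ONE.get(resname)
            atoms = [
                AtomRecord(
                    name=a.get_name(),
                    element=(a.element or "").strip() or a.get_name()[:1],
                    coord=np.asarray(a.get_coord(), dtype=float),
                    occupancy=min(1.0, a.get_occupancy() if a.get_occupancy() is not None else 1.0),
                    altloc=(a.get_altloc() or "").strip(),
                )
                for a in _pick_altloc(list(res.get_atoms()))
            ]
            records.append(
                ResidueRecord(
                    chain_id=chain.id,
                    seq_index=seq_index,
                    insertion_code=icode.strip(),
                    aa_type=one or "X",
                    atoms=atoms,
                    is_standard=one is not None,
                )
            )
        if records:
            records.sort(key=lambda r: (r.seq_index, r.insertion_code))
            chains[chain.id] = records

    if not chains:
        raise EmptyStructureError("PDB input contains no protein residues")

    meta = StructureMeta(
        pdb_id=pdb_id,
        method=method,
        resolution=resolution,
        has_nucleic=has_nucleic,
        has_d_amino=has_d_amino,
        chains={cid: len(rs) for cid, rs in chains.items()},
        chain_sequences={cid: "".join(r.aa_type for r in rs) for cid, rs in chains.items()},
    )
    return Structure(meta=meta, chains=chains)


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterConfig:
    """Structure-level acceptance thresholds for dataset curation.

    Defaults keep x-ray structures at better than 2 Å resolution with at
    least one chain longer than 50 residues, no nucleic acids and no
    D-amino acids.  ``keep_missing_method`` lets header-less synthetic files
    flow through the pipeline.
    """

    allowed_methods: tuple[str, ...] = ("x-ray diffraction", "x-ray crystallography")
    max_resolution: float = 2.0
    min_chain_length: int = 50
    reject_nucleic: bool = True
    reject_d_amino: bool = True
    keep_missing_method: bool = True
    excluded_ids: tuple[str, ...] = ()  # e.g. membrane proteins


@dataclass
class FilterDecision:
    keep: bool
    reason: str | None = None  # method | resolution | resolution_missing | length | nucleic | d_amino | excluded

    def __bool__(self) -> bool:
        return self.keep


def filter_structure(meta: StructureMeta, config: FilterConfig | None = None) -> FilterDecision:
    """Decide keep/reject for a structure; the first failing rule is reported."""
    cfg = config or FilterConfig()
    if meta.pdb_id and meta.pdb_id.upper() in {x.upper() for x in cfg.excluded_ids}:
        return FilterDecision(False, "excluded")
    if meta.method is None:
        if not cfg.keep_missing_method:
            return FilterDecision(False, "method")
        # Header-less input: only the content-based rules can apply.
    else:
        if meta.method.lower() not in cfg.allowed_methods:
            return FilterDecision(False, "method")
        if meta.resolution is None:
            return FilterDecision(False, "resolution_missing")
        if meta.resolution >= cfg.max_resolution:
            return FilterDecision(False, "resolution")
    if meta.chains and max(meta.chains.values()) <= cfg.min_chain_length:
        if meta.method is not None or not cfg.keep_missing_method:
            return FilterDecision(False, "length")
    if cfg.reject_nucleic and meta.has_nucleic:
        return FilterDecision(False, "nucleic")
    if cfg.reject_d_amino and meta.has_d_amino:
        return FilterDecision(False, "d_amino")
    return FilterDecision(True, None)


# ---------------------------------------------------------------------------
# Chain deduplication


def _identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    import edlib

    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def deduplicate_chains(structure: Structure, identity_threshold: float = 1.0) -> list[str]:
    """Retain one chain per group of (near-)identical subunits.

    Chains are visited in ascending chain-id order; a chain is dropped when
    its sequence is at least ``identity_threshold`` identical (edit-distance
    identity over the longer length) to an already retained chain.
    Returns the retained chain ids.
    """
    kept: list[str] = []
    for cid in sorted(structure.chains):
        seq = structure.meta.chain_sequences.get(cid, "")
        if any(_identity(seq, structure.meta.chain_sequences.get(k, "")) >= identity_threshold
               for k in kept):
            continue
        kept.append(cid)
    return kept
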