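"""Export prediction profiles as fixed-backbone design restraints.

The top-K most probable amino acids at each position become the allowed set,
written as a Rosetta *resfile*: a ``NATAA`` default command (positions
without restraints keep their native type), ``start``, then one
``<resnum> <chain> PIKAA <letters>`` line per restrained position with the
allowed one-letter codes in alphabetical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import top_k_sets
from .structure_io import AA_ALPHABET

__all__ = [
    "RestraintSet",
    "top_k_restraints",
    "write_resfile",
    "read_resfile",
    "max_possible_identity",
]


@dataclass
class RestraintSet:
    """Allowed amino acids per position.

    ``positions`` are ``(chain_id, residue_number, insertion_code)`` tuples;
    ``allowed`` holds the matching sets of one-letter codes.
    """

    positions: list[tuple[str, int, str]]
    allowed: list[frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.allowed):
            raise ValueError("positions and allowed sets differ in length")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate positions in restraint set")
        for s in self.allowed:
            if not 1 <= len(s) <= 20 or not s <= set(AA_ALPHABET):
                raise ValueError(f"invalid allowed set {sorted(s)}")

    def __len__(self) -> int:
        return len(self.positions)


def _parse_position_id(pid: str) -> tuple[str, int, str]:
    chain, _, rest = pid.partition(":")
    num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
    icode = rest[len(num):]
    return chain, int(num), icode


def top_k_restraints(profile, k: int) -> RestraintSet:
    """Allowed set = the K highest-probability amino acids per position
    (ties broken alphabetically)."""
    if not 1 <= k <= 20:
        raise ValueError("K must lie in [1, 20]")
    probs = np.asarray(profile.probabilities, dtype=float)
    sets = top_k_sets(probs, k)
    return RestraintSet(
        positions=[_parse_position_id(p) for p in profile.position_ids],
        allowed=[frozenset(AA_ALPHABET[c] for c in row) for row in sets],
    )


def write_resfile(restraints: RestraintSet, path=None) -> str:
    """Serialize restraints in Rosetta resfile grammar; returns the text.

    ``path`` (optional) additionally writes the text to a file.
    """
    lines = ["NATAA", "start"]
    for (chain, num, icode), allowed in zip(restraints.positions, restraints.allowed):
        resnum = f"{num}{icode}" if icode else str(num)
        lines.append(f"{resnum} {chain} PIKAA {''.join(sorted(allowed))}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_resfile(text: str) -> RestraintSet:
    """Parse the PIKAA resfile layout written by :func:`write_resfile`."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lower() == "start")
    except StopIteration:
        raise ValueError("resfile has no 'start' line") from None
    positions, allowed = [], []
    for ln in lines[start + 1:]:
        tokens = ln.split()
        if len(tokens) != 4 or tokens[2].upper() != "PIKAA":
            raise ValueError(f"unsupported resfile body line: {ln!r}")
        resnum, chain, _, letters = tokens
        icode = "" if resnum.lstrip("-").isdigit() else resnum[-1]
        num = int(resnum[:-1]) if icode else int(resnum)
        positions.append((chain, num, icode))
        allowed.append(frozenset(letters))
    return RestraintSet(positions=positions, allowed=allowed)


def max_possible_identity(restraints: RestraintSet, native_sequence: str) -> float:
    """Best achievable sequence identity under the restraints: the fraction
    of positions whose allowed set contains the native amino acid."""
    if len(restraints) != len(native_sequence):
        raise ValueError(
            f"restraints cover {len(restraints)} positions but the native "
            f"sequence has {len(native_sequence)}")
    if not native_sequence:
        raise ValueError("empty native sequence")
    hits = sum(aa in allowed for aa, allowed in zip(native_sequence, restraints.allowed))
    return hits / len(native_sequence)
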