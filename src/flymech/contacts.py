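"""Charged-residue contact distances and salt-bridge classification on
atomic coordinates.

Given a PDB-format model, the distance between two residues is the
minimum Euclidean distance over the cross product of their charged
side-chain atoms (Lys: NZ; Arg: NE/NH1/NH2; Asp: OD1/OD2; Glu: OE1/OE2).
A pair is a salt bridge when the residues are oppositely charged (K/R
versus D/E) and the minimum distance is within the cutoff (default
4.0 A, consistent with 3.0-3.2 A contacts counting as bridges and
4.5-5.7 A contacts as lost).  Residues without formal side-chain charge
(e.g. Asn after an R->N mutation) fall back to their polar side-chain
N/O atoms for the distance, but can never classify as a bridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Structure import Structure

DEFAULT_CUTOFF_A = 4.0

POSITIVE_RESIDUES = {"LYS", "ARG"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}

CHARGED_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: polar side-chain fallback for residues with no formal charge
POLAR_ATOMS = {
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}


@dataclass
class ResiduePair:
    chain_a: str
    residue_number_a: int
    residue_name_a: str
    chain_b: str
    residue_number_b: int
    residue_name_b: str
    min_charged_distance: float  # Angstrom
    is_salt_bridge: bool


def load_structure(path, include_het: bool = False, name: str = "model") -> Structure:
    """Parse a PDB-format file into a Biopython structure.

    HETATM residues (waters, ligands) are removed unless ``include_het``
    is set; a structure left with zero atoms only raises a warning, so
    callers can inspect it.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name, str(path))
    if not include_het:
        for model in structure:
            for chain in model:
                het = [res.id for res in chain if res.id[0] != " "]
                for rid in het:
                    chain.detach_child(rid)
    if sum(1 for _ in structure.get_atoms()) == 0:
        warnings.warn(f"{path}: no atoms after filtering", stacklevel=2)
    return structure


def write_structure(structure: Structure, path) -> None:
    """Write the structure back out in fixed-width PDB format."""
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


def _parse_residue_spec(spec) -> tuple[str, int]:
    if isinstance(spec, str):
        chain, _, num = spec.partition(":")
        return chain, int(num)
    chain, num = spec
    return str(chain), int(num)


def _get_residue(structure: Structure, chain_id: str, resnum: int):
    model = next(iter(structure))
    if chain_id not in model:
        raise KeyError(f"chain {chain_id!r} not in structure")
    chain = model[chain_id]
    for res in chain:
        if res.id[1] == resnum:
            return res
    raise KeyError(f"residue {chain_id}:{resnum} not in structure")


def _interaction_atoms(residue) -> tuple[np.ndarray, bool]:
    """Coordinates of the charged (or polar fallback) side-chain atoms and
    whether the residue carries a formal charge."""
    name = residue.get_resname().strip()
    charged = name in CHARGED_ATOMS
    wanted = CHARGED_ATOMS.get(name) or POLAR_ATOMS.get(name)
    if wanted is None:
        raise ValueError(f"no charged or polar side-chain atoms defined for {name}")
    coords = [atom.coord for atom in residue if atom.get_name() in wanted]
    if not coords:
        raise ValueError(
            f"residue {name} {residue.id[1]}: none of {wanted} present"
        )
    return np.asarray(coords, dtype=float), charged


def min_charged_distance(structure: Structure, res_a, res_b) -> tuple[float, bool]:
    """Minimum distance (A) over charged side-chain atom pairs.

    Residue specs are ``"A:146"`` strings or ``(chain, number)`` tuples.
    Returns ``(distance, charged_pair)`` where ``charged_pair`` is True
    only if the residues are oppositely charged (one of K/R, one of D/E);
    for uncharged residues the distance is over polar side-chain N/O.
    """
    ra = _get_residue(structure, *_parse_residue_spec(res_a))
    rb = _get_residue(structure, *_parse_residue_spec(res_b))
    ca, charged_a = _interaction_atoms(ra)
    cb, charged_b = _interaction_atoms(rb)
    diff = ca[:, None, :] - cb[None, :, :]
    dist = float(np.sqrt(np.sum(diff**2, axis=-1)).min())
    names = {ra.get_resname().strip(), rb.get_resname().strip()}
    opposite = (charged_a and charged_b
                and bool(names & POSITIVE_RESIDUES)
                and bool(names & NEGATIVE_RESIDUES))
    return dist, opposite


def classify_salt_bridges(structure: Structure, pairs,
                          cutoff: float = DEFAULT_CUTOFF_A) -> list[ResiduePair]:
    """Per-pair contact records with salt-bridge classification.

    ``pairs`` is an iterable of (res_a, res_b) residue specs.  A pair is
    a bridge iff its minimum charged-atom distance is within ``cutoff``
    and the residues are oppositely charged; lowering the cutoff can only
    remove bridges, never add them.
    """
    records = []
    for spec_a, spec_b in pairs:
        chain_a, num_a = _parse_residue_spec(spec_a)
        chain_b, num_b = _parse_residue_spec(spec_b)
        ra = _get_residue(structure, chain_a, num_a)
        rb = _get_residue(structure, chain_b, num_b)
        dist, opposite = min_charged_distance(structure, spec_a, spec_b)
        records.append(ResiduePair(
            chain_a=chain_a, residue_number_a=num_a,
            residue_name_a=ra.get_resname().strip(),
            chain_b=chain_b, residue_number_b=num_b,
            residue_name_b=rb.get_resname().strip(),
            min_charged_distance=dist,
            is_salt_bridge=bool(opposite and dist <= cutoff),
        ))
    return records
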