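"""Structure parsing, native contact maps, charges, and metal distances.

A :class:`ProteinStructure` is a minimal residue-level view of a PDB chain:
heavy-atom coordinates per residue plus any Zn/Cu metal sites.  From it we
derive the two geometric inputs of the folding model -- the heavy-atom native
contact map (6 A cutoff by default) and the per-residue charge set used by the
screened-electrostatics term -- and the mutation-site-to-metal distances used
by the correlation stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: residues carrying a formal charge at neutral pH (His configurable)
NEGATIVE = {"ASP", "GLU"}
POSITIVE = {"LYS", "ARG"}

#: side-chain atoms defining the charged-group centroid
CHARGED_GROUP_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2", "CE1"),
}

METAL_ELEMENTS = {"ZN": "Zn", "CU": "Cu"}


@dataclass(frozen=True)
class Residue:
    """One residue: its PDB sequence number, 3-letter name, chain id, and
    heavy atoms as (name, x, y, z) tuples in Angstrom."""

    seq_id: int
    name: str
    chain: str
    atoms: tuple[tuple[str, float, float, float], ...]

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass(frozen=True)
class MetalSite:
    element: str  # "Zn", "Cu", or other element symbol
    x: float
    y: float
    z: float

    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ProteinStructure:
    """Residues (ordered), their heavy atoms, and metal sites."""

    residues: list[Residue]
    metal_sites: list[MetalSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chain: dict[str, int] = {}
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"residue {r.name}{r.seq_id} has no heavy atoms")
            prev = by_chain.get(r.chain)
            if prev is not None and r.seq_id <= prev:
                raise ValueError(
                    f"sequence indices not strictly increasing in chain {r.chain}"
                )
            by_chain[r.chain] = r.seq_id
            if not np.all(np.isfinite(r.coords())):
                raise ValueError(f"non-finite coordinates in residue {r.seq_id}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def sequence_ids(self) -> list[int]:
        return [r.seq_id for r in self.residues]

    def residue_by_seq_id(self, seq_id: int) -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"no residue with sequence id {seq_id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly transformed copy (rotation 3x3, translation 3-vector)."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            xyz = r.coords() @ rot.T + t
            atoms = tuple(
                (name, *map(float, p)) for (name, *_), p in zip(r.atoms, xyz)
            )
            new_res.append(Residue(r.seq_id, r.name, r.chain, atoms))
        new_metals = [
            MetalSite(m.element, *map(float, rot @ m.coord() + t))
            for m in self.metal_sites
        ]
        return ProteinStructure(new_res, new_metals)


@dataclass
class ContactMap:
    """Native heavy-atom contact counts n_ij for residue pairs i < j.

    Indices are 0-based positions along the modeled chain (not PDB numbers);
    ``seq_ids`` maps positions back to PDB numbering for serialization.
    """

    n_residues: int
    contacts: list[tuple[int, int, int]]
    cutoff: float
    min_separation: int
    seq_ids: list[int] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for i, j, n_ij in self.contacts:
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"bad contact pair ({i}, {j})")
            if n_ij < 1:
                raise ValueError("contact with n_ij < 1")
            if j - i < self.min_separation:
                raise ValueError(f"pair ({i}, {j}) violates min_separation")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))

    def to_frame(self) -> pd.DataFrame:
        ids = self.seq_ids or list(range(1, self.n_residues + 1))
        return pd.DataFrame(
            [(ids[i], ids[j], n) for i, j, n in self.contacts],
            columns=["i", "j", "n_ij"],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ChargeSet:
    """Map 0-based residue position -> (charge in e, charged-group centroid)."""

    charges: dict[int, float]
    centroids: dict[int, np.ndarray] = field(default_factory=dict)


def read_structure(path, chain: str) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Hydrogens and waters are dropped; alternate locations resolve to the
    highest-occupancy copy; Zn/Cu HETATM records anywhere in the model are
    captured as metal sites.  Only the first MODEL of a multi-model file is
    used (logged).  Insertion codes are rejected.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if len(st) > 1:
        logger.warning("multi-model file %s: using first model only", path)
    model = st[0]
    chains = [ch.name for ch in model]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")

    residues: list[Residue] = []
    metals: list[MetalSite] = []

    for ch in model:
        for res in ch:
            element_metal = res.name.strip().upper()
            # metal HETATMs may live on any chain
            if element_metal in METAL_ELEMENTS:
                for atom in res:
                    metals.append(
                        MetalSite(
                            METAL_ELEMENTS[element_metal],
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
                continue
            if ch.name != chain:
                continue
            if res.is_water():
                continue
            if res.seqid.icode not in (" ", "\x00", ""):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: "
                    "insertion codes are not supported"
                )
            best: dict[str, tuple[float, tuple[str, float, float, float]]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                occ = atom.occ if atom.occ > 0 else 1.0
                kept = best.get(atom.name)
                if kept is None or occ > kept[0]:
                    best[atom.name] = (
                        occ,
                        (atom.name, atom.pos.x, atom.pos.y, atom.pos.z),
                    )
            atoms = tuple(v[1] for v in best.values())
            if not atoms:
                continue
            if not any(a[0] == "CA" for a in atoms):
                logger.warning(
                    "residue %s%d has no CA atom; skipped", res.name, res.seqid.num
                )
                continue
            residues.append(Residue(res.seqid.num, res.name.strip(), chain, atoms))

    if not residues:
        raise ValueError(f"chain {chain!r} contains no protein residues")
    return ProteinStructure(residues, metals)


def build_contact_map(
    s: ProteinStructure, cutoff: float = 6.0, min_separation: int = 2
) -> ContactMap:
    """Count heavy-atom pairs within ``cutoff`` Angstrom for residue pairs
    separated by at least ``min_separation`` along the chain."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = [r.coords() for r in s.residues]
    contacts: list[tuple[int, int, int]] = []
    n = s.n_residues
    for i in range(n):
        ci = coords[i]
        for j in range(i + min_separation, n):
            d = np.linalg.norm(ci[:, None, :] - coords[j][None, :, :], axis=-1)
            n_ij = int(np.count_nonzero(d <= cutoff))
            if n_ij >= 1:
                contacts.append((i, j, n_ij))
    return ContactMap(
        n_residues=n,
        contacts=contacts,
        cutoff=cutoff,
        min_separation=min_separation,
        seq_ids=s.sequence_ids(),
    )


def assign_charges(
    s: ProteinStructure, his_charge: float = 0.0, include_termini: bool = False
) -> ChargeSet:
    """Assign formal charges: Asp/Glu -1, Lys/Arg +1, His ``his_charge``,
    optionally +1/-1 on the N-/C-terminus.  Charges sit on the residue's
    charged-group centroid (CA fallback) for electrostatic distances."""
    charges: dict[int, float] = {}
    centroids: dict[int, np.ndarray] = {}

    def group_centroid(r: Residue) -> np.ndarray:
        names = CHARGED_GROUP_ATOMS.get(r.name, ())
        pts = [np.array([x, y, z]) for nm, x, y, z in r.atoms if nm in names]
        if not pts:
            pts = [np.array([x, y, z]) for nm, x, y, z in r.atoms if nm == "CA"]
        if not pts:
            pts = [np.array([x, y, z]) for nm, x, y, z in r.atoms]
        return np.mean(pts, axis=0)

    for idx, r in enumerate(s.residues):
        q = 0.0
        if r.name in NEGATIVE:
            q = -1.0
        elif r.name in POSITIVE:
            q = +1.0
        elif r.name == "HIS":
            q = his_charge
        if include_termini:
            if idx == 0:
                q += 1.0
            if idx == s.n_residues - 1:
                q -= 1.0
        if q != 0.0:
            charges[idx] = q
            centroids[idx] = group_centroid(r)
    return ChargeSet(charges=charges, centroids=centroids)


def metal_distance(
    s: ProteinStructure,
    residue_seq_id: int,
    metal: str,
    convention: str = "min_heavy_atom",
) -> float:
    """Distance (A) from a residue to the nearest metal site of the given
    element.  ``convention`` is ``"min_heavy_atom"`` (default: minimum over
    the residue's heavy atoms) or ``"ca"`` (CA-to-metal)."""
    sites = [m for m in s.metal_sites if m.element == metal]
    if not sites:
        present = sorted({m.element for m in s.metal_sites})
        raise ValueError(f"no {metal} site in structure (present: {present})")
    res = s.residue_by_seq_id(residue_seq_id)
    if convention == "ca":
        pts = np.array(
            [[x, y, z] for nm, x, y, z in res.atoms if nm == "CA"], dtype=float
        )
        if pts.size == 0:
            raise ValueError(f"residue {residue_seq_id} has no CA atom")
    elif convention == "min_heavy_atom":
        pts = res.coords()
    else:
        raise ValueError(f"unknown convention {convention!r}")
    best = math.inf
    for m in sites:
        d = np.linalg.norm(pts - m.coord(), axis=1).min()
        best = min(best, float(d))
    return best
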