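"""Shared fixtures: synthetic PDB text and toy model systems."""

from __future__ import annotations

import numpy as np
import pytest

from sodscape import bwsme_engine as bw
from sodscape import structure_contacts as sc
from sodscape import synthetic_data as syn


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, *, het=False,
              altloc=" ", occ=1.00, element=None):
    record = "HETATM" if het else "ATOM  "
    element = element or name[0]
    return (
        f"{record}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """ASP-LYS-GLY chain A with one Zn ion exactly 5 A from the GLY CA and
    an A/B altloc pair on the ASP CB (occupancies 0.6/0.4)."""
    lines = [
        _pdb_line(1, "N", "ASP", "A", 1, 0.0, 0.0, 0.0),
        _pdb_line(2, "CA", "ASP", "A", 1, 1.5, 0.0, 0.0),
        _pdb_line(3, "CB", "ASP", "A", 1, 2.0, 1.0, 0.0, altloc="A", occ=0.60),
        _pdb_line(4, "CB", "ASP", "A", 1, 2.0, -1.0, 0.0, altloc="B", occ=0.40),
        _pdb_line(5, "CG", "ASP", "A", 1, 3.5, 1.2, 0.0),
        _pdb_line(6, "OD1", "ASP", "A", 1, 4.2, 1.8, 0.8, element="O"),
        _pdb_line(7, "OD2", "ASP", "A", 1, 4.0, 1.4, -1.2, element="O"),
        _pdb_line(8, "N", "LYS", "A", 2, 2.0, 0.0, 3.0),
        _pdb_line(9, "CA", "LYS", "A", 2, 3.5, 0.0, 3.2),
        _pdb_line(10, "NZ", "LYS", "A", 2, 4.5, 2.5, 3.5),
        _pdb_line(11, "N", "GLY", "A", 3, 4.0, 0.0, 6.0),
        _pdb_line(12, "CA", "GLY", "A", 3, 5.5, 0.0, 6.2),
        # hydrogen must be dropped
        _pdb_line(13, "H", "GLY", "A", 3, 5.6, 0.8, 6.2, element="H"),
        # water must be dropped
        _pdb_line(14, "O", "HOH", "A", 90, 20.0, 20.0, 20.0, het=True,
                  element="O"),
        # Zn exactly 5 A from GLY CA (and far from everything else)
        _pdb_line(15, "ZN", "ZN", "B", 101, 10.5, 0.0, 6.2, het=True,
                  element="ZN"),
        "END",
    ]
    path = tmp_path / "three_res.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_loop() -> dict:
    """Toy two-loop structure with its contact map and block scheme."""
    s = syn.toy_structure("two_loop_protein")
    cm = sc.build_contact_map(s)
    q = sc.assign_charges(s)
    bs = bw.BlockScheme.from_block_length(s.n_residues, 3)
    return {"structure": s, "cm": cm, "q": q, "bs": bs}


def toy_variant(name: str) -> bw.VariantScheme:
    return bw.VariantScheme(
        name, loop_zn=syn.TOY_LOOP_ZN, loop_cu=syn.TOY_LOOP_CU
    )


def random_contact_system(seed: int):
    """Random small contact map + block scheme for oracle-equivalence tests
    (n_blocks <= 6)."""
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(6, 19))
    bs = bw.BlockScheme.from_block_length(n_res, 3)
    contacts = [
        (i, j, int(rng.integers(1, 6)))
        for i in range(n_res)
        for j in range(i + 2, n_res)
        if rng.random() < 0.35
    ]
    cm = sc.ContactMap(
        n_residues=n_res, contacts=contacts, cutoff=6.0, min_separation=2
    )
    q = sc.ChargeSet(charges={}, centroids={})
    vs = bw.VariantScheme("apo", loop_zn=(2, 5), loop_cu=(8, 10))
    p = bw.EnergyParams(xi=float(rng.uniform(-700, -150)))
    return cm, q, bs, vs, p
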