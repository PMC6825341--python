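"""Multi-model PDB reading and writing for coarse-grained chains.

Decoys are stored as Cα (plus virtual Cβ) records, one MODEL per decoy.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1, seq3

from .folding_engine import ChainConformation, DecoyEnsemble
from .geometry import virtual_cb


class PDBIOError(ValueError):
    pass


def _atom_line(serial: int, name: str, resname: str, resseq: int,
               xyz: np.ndarray) -> str:
    return (f"ATOM  {serial:5d} {name:^4s}{resname:>4s} A{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           {name[0]:>2s}\n")


def write_pdb(conformations, path, energies=None) -> None:
    """Write one or more conformations as a multi-model PDB file."""
    if isinstance(conformations, ChainConformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        for m, conf in enumerate(conformations, 1):
            fh.write(f"MODEL     {m:4d}\n")
            if energies is not None:
                fh.write(f"REMARK   1 ENERGY {energies[m - 1]:.6f}\n")
            serial = 1
            for r, aa in enumerate(conf.sequence):
                resname = seq3(aa).upper()
                fh.write(_atom_line(serial, "CA", resname, r + 1,
                                    conf.ca[r]))
                serial += 1
                fh.write(_atom_line(serial, "CB", resname, r + 1,
                                    conf.cb[r]))
                serial += 1
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


def read_pdb(path) -> list[ChainConformation]:
    """Read every model of a PDB file as a chain conformation.

    Missing Cβ atoms are rebuilt from the Cα trace.
    """
    path = Path(path)
    if not path.exists():
        raise PDBIOError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("decoys", str(path))
    conformations = []
    for model in structure:
        ca_coords, cb_coords, letters = [], [], []
        for chain in model:
            for residue in chain:
                if "CA" not in residue:
                    continue
                ca_coords.append(residue["CA"].coord.astype(float))
                cb_coords.append(
                    residue["CB"].coord.astype(float)
                    if "CB" in residue else None)
                try:
                    letters.append(seq1(residue.get_resname().capitalize()))
                except Exception:
                    letters.append("X")
        if not ca_coords:
            continue
        ca = np.array(ca_coords)
        if any(c is None for c in cb_coords):
            cb = virtual_cb(ca)
        else:
            cb = np.array(cb_coords)
        conformations.append(
            ChainConformation("".join(letters), ca, cb))
    if not conformations:
        raise PDBIOError(f"{path} contains no Cα records")
    return conformations


def read_ensemble(path) -> DecoyEnsemble:
    confs = read_pdb(path)
    energies = _read_energies(path, len(confs))
    return DecoyEnsemble(decoys=confs, energies=energies)


def _read_energies(path, n: int) -> list[float]:
    energies = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK   1 ENERGY"):
                energies.append(float(line.split()[-1]))
    if len(energies) != n:
        return [0.0] * n
    return energies
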