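"""Structure file I/O.

Two on-disk dialects are supported:

* **PDB** (``.pdb``, ``.ent``) -- parsed and written through ``biotite``;
  coordinates are converted between angstrom (file) and nm (in memory).
  Chain ids must be single characters on write (PDB column limit); use
  the plain dialect for assemblies with many chains.
* **plain coordinate table** (``.tsv``, ``.txt``) -- a tab-separated
  table with header ``element atom_name res_id res_name chain_id x y z``
  and coordinates in nm.  No column-width limits, arbitrary chain ids.

Assembly transforms (BIOMT-style) are read from a simple text file:
each block of four lines ``r11 r12 r13 t1`` ... defines one
rotation+translation; translations in nm.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .structures import ChainAnnotation, EmptyStructureError, MolecularStructure

__all__ = ["read_structure", "write_structure", "read_transforms", "FormatError"]

_NM_PER_ANGSTROM = 0.1
_PLAIN_HEADER = ["element", "atom_name", "res_id", "res_name", "chain_id", "x", "y", "z"]


class FormatError(ValueError):
    """Raised for unparseable structure files; names the offending line."""


def _validate_pdb_lines(path: Path) -> None:
    # pre-scan so parse failures can be reported with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable coordinates") from exc


def _read_pdb(path: Path) -> MolecularStructure:
    import biotite.structure.io.pdb as pdbfile

    _validate_pdb_lines(path)
    try:
        arr = pdbfile.PDBFile.read(str(path)).get_structure(model=1,
                                                            altloc="first")
    except ValueError as exc:
        raise EmptyStructureError(f"{path}: empty model ({exc})") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: empty model")
    ins = arr.ins_code
    if np.any(ins != ""):
        n_bad = int(np.count_nonzero(ins != ""))
        warnings.warn(f"{path}: dropping {n_bad} atoms with insertion codes")
        arr = arr[ins == ""]
    return MolecularStructure(
        elements=arr.element.astype(str),
        atom_names=arr.atom_name.astype(str),
        residue_indices=arr.res_id.astype(int),
        residue_names=arr.res_name.astype(str),
        chain_ids=arr.chain_id.astype(str),
        positions=arr.coord.astype(float) * _NM_PER_ANGSTROM,
        source=str(path),
    )


def _read_plain(path: Path) -> MolecularStructure:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "res_name": str,
                                                "element": str, "atom_name": str})
    except Exception as exc:
        raise FormatError(f"{path}: not a valid coordinate table: {exc}") from exc
    missing = [c for c in _PLAIN_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    if len(df) == 0:
        raise EmptyStructureError(f"{path}: empty model")
    bad = ~np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        raise FormatError(f"{path}:{int(np.flatnonzero(bad)[0]) + 2}: "
                          "non-finite coordinates")
    return MolecularStructure(
        elements=df["element"].to_numpy(dtype=str),
        atom_names=df["atom_name"].to_numpy(dtype=str),
        residue_indices=df["res_id"].to_numpy(dtype=int),
        residue_names=df["res_name"].to_numpy(dtype=str),
        chain_ids=df["chain_id"].to_numpy(dtype=str),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        source=str(path),
    )


def read_structure(path, heavy_only: bool = False,
                   annotations: list[ChainAnnotation] | None = None,
                   ) -> MolecularStructure:
    """Read a structure from PDB or the plain coordinate dialect.

    Parameters
    ----------
    path : path-like
        ``.pdb``/``.ent`` files are parsed as PDB; anything else as the
        plain tab-separated dialect.
    heavy_only : bool
        Drop hydrogen atoms after parsing.
    annotations : list of ChainAnnotation, optional
        Attach per-chain position labels / tail ranges.
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        struct = _read_pdb(path)
    else:
        struct = _read_plain(path)
    if heavy_only:
        struct = struct.select(struct.heavy_mask())
        if struct.n_atoms == 0:
            raise EmptyStructureError(f"{path}: no heavy atoms")
    if annotations is not None:
        struct.chains = list(annotations)
    return struct


def write_structure(structure: MolecularStructure, path) -> None:
    """Write a structure as PDB or the plain dialect (chosen by extension).

    PDB output keeps three decimals in angstrom, i.e. coordinates
    round-trip to 1e-4 nm (well inside the declared 1e-3 nm precision).
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("cannot write an empty structure")
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        _write_pdb(structure, path)
    else:
        _write_plain(structure, path)


def _write_pdb(structure: MolecularStructure, path: Path) -> None:
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdbfile

    if any(len(str(c)) > 1 for c in set(structure.chain_ids.tolist())):
        raise ValueError(
            "PDB chain-id column holds a single character; "
            "write multi-chain assemblies in the plain dialect (.tsv) instead")
    arr = bst.AtomArray(structure.n_atoms)
    arr.coord = structure.positions / _NM_PER_ANGSTROM
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.residue_indices.astype(int)
    arr.res_name = structure.residue_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = np.zeros(structure.n_atoms, dtype=bool)
    f = pdbfile.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def _write_plain(structure: MolecularStructure, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PLAIN_HEADER) + "\n")
        for i in range(structure.n_atoms):
            x, y, z = structure.positions[i]
            fh.write(f"{structure.elements[i]}\t{structure.atom_names[i]}\t"
                     f"{int(structure.residue_indices[i])}\t{structure.residue_names[i]}\t"
                     f"{structure.chain_ids[i]}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_transforms(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read rigid transforms: blocks of 3 lines, 4 numbers each (R | t)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            vals = line.split()
            if len(vals) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 numbers per row")
            rows.append([float(v) for v in vals])
    if len(rows) % 3 != 0:
        raise FormatError(f"{path}: transform rows not a multiple of 3")
    out = []
    for b in range(0, len(rows), 3):
        block = np.array(rows[b:b + 3])
        out.append((block[:, :3], block[:, 3]))
    return out
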