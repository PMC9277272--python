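"""Readers and writers: multi-MODEL PDB, multi-frame XYZ, profile TSV.

PDB access goes through Biopython (Bio.PDB); the XYZ dialect is the plain
``count / comment / element x y z`` multi-frame concatenation, with an
optional ``t= <ps>`` token on the comment line carrying frame times.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .geometry import Conformation, StructureEnsemble

__all__ = [
    "FormatError",
    "read_pdb_models",
    "write_pdb_models",
    "read_xyz",
    "write_xyz",
    "read_structure",
    "write_profile_tsv",
    "read_profile_tsv",
    "PROFILE_COLUMNS",
]


class FormatError(ValueError):
    """A structure or table file violates its format contract."""


_ALTLOCS_KEPT = (" ", "", "A")


def read_pdb_models(path: str | Path, selection: str = "ca") -> StructureEnsemble:
    """Read a (multi-MODEL) PDB file into an ensemble.

    One Conformation per MODEL (a file without MODEL records yields one
    member).  ``selection`` "ca" keeps atoms named CA with blank or 'A'
    altloc; "all" keeps every atom.  Frame time is the 0-based model
    index, since PDB carries no times.
    """
    if selection not in ("ca", "all"):
        raise ValueError("selection must be 'ca' or 'all'")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("chain", str(path))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    members = []
    counts = set()
    for idx, model in enumerate(structure):
        coords, labels = [], []
        for chain in model:
            for residue in chain:
                for atom in residue.get_unpacked_list():
                    if atom.get_altloc() not in _ALTLOCS_KEPT:
                        continue
                    if selection == "ca" and atom.get_name() != "CA":
                        continue
                    coords.append(atom.get_coord())
                    labels.append(f"{residue.get_resname()}{residue.get_id()[1]}")
        if not coords:
            raise FormatError(
                f"no atoms left after selection '{selection}' in model {idx} of {path}"
            )
        counts.add(len(coords))
        members.append(
            Conformation(np.asarray(coords, dtype=float), tuple(labels),
                         frame_time=float(idx))
        )
    if not members:
        raise FormatError(f"no models found in {path}")
    if len(counts) != 1:
        raise FormatError(
            f"inconsistent bead counts across MODELs in {path}: {sorted(counts)}"
        )
    return StructureEnsemble(tuple(members), kind="trajectory")


def write_pdb_models(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB of CA pseudo-atoms."""
    builder = StructureBuilder()
    builder.init_structure("chain")
    for mi, member in enumerate(ensemble):
        builder.init_model(mi)
        builder.init_chain("A")
        builder.init_seg(" ")
        for bi, xyz in enumerate(member.coordinates):
            resname = "GLY"
            if member.labels is not None:
                match = re.match(r"([A-Za-z]{1,3})", member.labels[bi])
                if match:
                    resname = match.group(1).upper()[:3]
            builder.init_residue(resname, " ", bi + 1, " ")
            builder.init_atom("CA", np.asarray(xyz, dtype=float), 0.0, 1.0,
                              " ", " CA ", bi, element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


_TIME_TOKEN = re.compile(r"\bt=\s*([-+0-9.eE]+)")


def read_xyz(path: str | Path) -> StructureEnsemble:
    """Read a multi-frame XYZ file.

    A ``t= <ps>`` token on a comment line is parsed into the frame time.
    """
    lines = Path(path).read_text().splitlines()
    members = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}:{i + 1}: malformed atom-count line: {lines[i]!r}"
            ) from None
        if count < 1:
            raise FormatError(f"{path}:{i + 1}: invalid atom count {count}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        frame_time = None
        match = _TIME_TOKEN.search(comment)
        if match:
            frame_time = float(match.group(1))
        coords, labels = [], []
        for j in range(count):
            k = i + 2 + j
            if k >= len(lines):
                raise FormatError(f"{path}:{len(lines)}: truncated frame")
            parts = lines[k].split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{k + 1}: expected 'element x y z'")
            labels.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise FormatError(f"{path}:{k + 1}: non-numeric coordinate") from None
        members.append(
            Conformation(np.asarray(coords), tuple(labels), frame_time=frame_time)
        )
        i += 2 + count
    if not members:
        raise FormatError(f"{path}: empty XYZ file")
    return StructureEnsemble(tuple(members), kind="trajectory")


def write_xyz(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as multi-frame XYZ, coordinates at 6 decimals."""
    out = []
    for fi, member in enumerate(ensemble):
        out.append(str(member.n_beads))
        comment = f"frame {fi}"
        if member.frame_time is not None:
            comment += f" t= {member.frame_time:g}"
        out.append(comment)
        for bi, (x, y, z) in enumerate(member.coordinates):
            label = member.labels[bi] if member.labels is not None else "C"
            out.append(f"{label} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_structure(path: str | Path, selection: str = "ca") -> StructureEnsemble:
    """Dispatch on file extension: .pdb -> PDB reader, anything else XYZ."""
    if str(path).lower().endswith(".pdb"):
        return read_pdb_models(path, selection)
    return read_xyz(path)


PROFILE_COLUMNS = ["frame", "time_ps", "rg_A", "ree_A", "rmsd_A",
                   "alpha", "dimension", "flag"]


def write_profile_tsv(profile, path: str | Path) -> None:
    """Write a folding profile as TSV: floats at 4 decimals, missing RMSD as NA."""
    df = profile if isinstance(profile, pd.DataFrame) else profile.frame
    lines = ["\t".join(PROFILE_COLUMNS)]
    for _, row in df.iterrows():
        cells = [str(int(row["frame"]))]
        for col in ("time_ps", "rg_A", "ree_A", "rmsd_A", "alpha", "dimension"):
            val = row.get(col, np.nan)
            cells.append("NA" if pd.isna(val) else f"{val:.4f}")
        cells.append(str(row["flag"]))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a profile TSV written by :func:`write_profile_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing profile columns {missing}")
    return df
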