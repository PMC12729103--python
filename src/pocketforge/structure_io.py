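"""Read/write the standard formats the pipeline touches.

Legacy PDB structures (the input format the constituent pocket finders
require), BioLiP-style binding annotation tables, and the pocket result
tables written at the end of a run.

PDB conventions: first model only; altloc ``' '`` or ``'A'`` only; ATOM
records become residues, non-water HETATM groups become ligands.  For
predicted structures the per-residue pLDDT is the mean B-factor of the
residue's atoms.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyStructureError, FormatError, JoinError, ParseError
from .structures import (
    ONE_TO_THREE,
    THREE_TO_ONE,
    WATER_NAMES,
    Atom,
    BindingAnnotation,
    LigandInstance,
    ProteinStructure,
    Residue,
)

if TYPE_CHECKING:
    from .harmonize import CandidatePocket

_RES_TOKEN = re.compile(r"^([A-Za-z])(-?\d+[A-Za-z]?)$")


def _res_id(number: int, ins_code: str) -> str:
    return f"{number}{ins_code.strip()}"


def read_pdb(path: str | Path, source: str = "experimental") -> ProteinStructure:
    """Parse a legacy-format PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM record.
    source:
        ``"experimental"`` or ``"predicted"``.  For predicted structures each
        residue's pLDDT is taken as the mean B-factor of its atoms.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, altloc="first", extra_fields=["b_factor"]
        )
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc

    is_protein = ~atoms.hetero
    if not np.any(is_protein):
        raise EmptyStructureError(f"{path}: no ATOM records")

    structure_id = path.stem
    chains: dict[str, list[Residue]] = {}
    prot = atoms[is_protein]
    starts = struc.get_residue_starts(prot, add_exclusive_stop=True)
    for i in range(len(starts) - 1):
        seg = prot[starts[i] : starts[i + 1]]
        cid = str(seg.chain_id[0])
        rid = _res_id(int(seg.res_id[0]), str(seg.ins_code[0]))
        aa = THREE_TO_ONE.get(str(seg.res_name[0]), "X")
        res_atoms = [
            Atom(
                name=str(seg.atom_name[j]),
                element=str(seg.element[j]),
                position=seg.coord[j],
                bfactor=float(seg.b_factor[j]),
            )
            for j in range(seg.array_length())
        ]
        plddt = None
        if source == "predicted":
            plddt = float(np.mean([a.bfactor for a in res_atoms]))
        chains.setdefault(cid, []).append(
            Residue(chain_id=cid, res_id=rid, aa=aa, atoms=res_atoms, plddt=plddt)
        )

    ligands: list[LigandInstance] = []
    het = atoms[atoms.hetero]
    if het.array_length() > 0:
        hstarts = struc.get_residue_starts(het, add_exclusive_stop=True)
        for i in range(len(hstarts) - 1):
            seg = het[hstarts[i] : hstarts[i + 1]]
            ccd = str(seg.res_name[0])
            if ccd in WATER_NAMES:
                continue
            ligands.append(
                LigandInstance(
                    ccd_code=ccd,
                    chain_id=str(seg.chain_id[0]),
                    atoms=[
                        Atom(
                            name=str(seg.atom_name[j]),
                            element=str(seg.element[j]),
                            position=seg.coord[j],
                            bfactor=float(seg.b_factor[j]),
                        )
                        for j in range(seg.array_length())
                    ],
                )
            )

    return ProteinStructure(
        structure_id=structure_id, source=source, chains=chains, ligands=ligands
    )


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure back to legacy PDB format (one model)."""
    records: list[tuple] = []  # (hetero, chain, resnum, icode, resname, atom)
    for res in structure.iter_residues():
        num, icode = _split_res_id(res.res_id)
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        for atom in res.atoms:
            records.append((False, res.chain_id, num, icode, resname, atom))
    for lig in structure.ligands:
        for atom in lig.atoms:
            records.append((True, lig.chain_id, 1, "", lig.ccd_code, atom))

    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r[5].position for r in records])
    arr.chain_id = np.array([r[1] for r in records])
    arr.res_id = np.array([r[2] for r in records], dtype=int)
    arr.ins_code = np.array([r[3] for r in records])
    arr.res_name = np.array([r[4] for r in records])
    arr.atom_name = np.array([r[5].name for r in records])
    arr.element = np.array([r[5].element for r in records])
    arr.hetero = np.array([r[0] for r in records])
    arr.set_annotation("b_factor", np.array([r[5].bfactor for r in records]))

    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _split_res_id(res_id: str) -> tuple[int, str]:
    m = re.match(r"^(-?\d+)([A-Za-z]?)$", res_id)
    if m is None:
        raise ValueError(f"bad residue id {res_id!r}")
    return int(m.group(1)), m.group(2)


def parse_residue_token(token: str) -> tuple[str, str]:
    """Split an annotation token like ``A101`` into (one-letter aa, res_id)."""
    m = _RES_TOKEN.match(token)
    if m is None:
        raise ParseError(f"malformed residue token {token!r}")
    return m.group(1).upper(), m.group(2)


def read_binding_annotations(path: str | Path) -> list[BindingAnnotation]:
    """Read a minimal BioLiP-style annotation table.

    Dialect: 4 tab-separated columns — structure_id, chain_id, ligand CCD
    code, and a space-separated list of residue tokens (``A101`` = Ala 101).
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns")
            structure_id, chain_id, ligand_ccd, residue_field = fields[:4]
            residues = set()
            for token in residue_field.split():
                try:
                    _aa, rid = parse_residue_token(token)
                except ParseError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                residues.add(rid)
            if not residues:
                raise ParseError(f"{path}:{lineno}: empty binding residue list")
            annotations.append(
                BindingAnnotation(
                    structure_id=structure_id,
                    chain_id=chain_id,
                    ligand_ccd=ligand_ccd,
                    binding_residues=residues,
                )
            )
    return annotations


def join_annotation(
    annotation: BindingAnnotation, structure: ProteinStructure
) -> set[tuple[str, str]]:
    """Resolve an annotation against a structure.

    Returns the set of (chain_id, res_id) keys; raises :class:`JoinError`
    naming every unresolvable identifier.
    """
    missing = sorted(
        rid
        for rid in annotation.binding_residues
        if not structure.has_residue(annotation.chain_id, rid)
    )
    if missing:
        raise JoinError(
            f"annotation {annotation.structure_id}/{annotation.chain_id}/"
            f"{annotation.ligand_ccd}: unresolvable residues {missing}"
        )
    return {(annotation.chain_id, rid) for rid in annotation.binding_residues}


# -- pocket tables ----------------------------------------------------------

POCKET_COLUMNS = ["structure_id", "pocket_id", "method", "score", "residues"]


def _residue_set_to_token(residues) -> str:
    keys = sorted(residues)
    return ",".join(f"{c}:{r}" for c, r in keys)


def _token_to_residue_set(token: str) -> set[tuple[str, str]]:
    if not token:
        return set()
    out = set()
    for part in token.split(","):
        c, r = part.split(":")
        out.add((c, r))
    return out


def write_pockets(pockets: Sequence, path: str | Path) -> None:
    """Write scored/candidate pockets as TSV plus a JSON mirror.

    Accepts any object with ``structure_id``, ``method``, ``residues`` and an
    optional score attribute (``model_score`` preferred, else ``native_score``).
    """
    rows = []
    for i, p in enumerate(pockets):
        score = getattr(p, "model_score", None)
        if score is None:
            score = getattr(p, "native_score", None)
        rows.append(
            {
                "structure_id": p.structure_id,
                "pocket_id": i,
                "method": p.method,
                "score": "" if score is None else f"{score:.9g}",
                "residues": _residue_set_to_token(p.residues),
            }
        )
    df = pd.DataFrame(rows, columns=POCKET_COLUMNS)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(rows, fh, indent=1)


def read_pockets(path: str | Path) -> list["CandidatePocket"]:
    from .harmonize import CandidatePocket

    df = pd.read_csv(path, sep="\t", dtype={"score": str}, keep_default_na=False)
    pockets = []
    for _, row in df.iterrows():
        score: Optional[float] = None
        if row["score"] != "":
            score = float(row["score"])
        pockets.append(
            CandidatePocket(
                structure_id=str(row["structure_id"]),
                method=str(row["method"]),
                residues=_token_to_residue_set(row["residues"]),
                native_score=score,
            )
        )
    return pockets
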