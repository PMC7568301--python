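"""PDB structure reading and writing on top of gemmi.

The in-memory representation is a flat atom table (one pandas row per
atom) carrying author residue numbering, which matches how residues
are named in the literature ("Ser225", "Cys529").  On reading, at most
one atom is kept per (chain, residue, atom name): the highest-occupancy
alternate location wins, with ties resolved toward altloc 'A' (then
lexicographically).  Hydrogens are retained but flagged; waters are
kept and tagged so geometry operations can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = ["Structure", "read_structure", "write_structure", "ParseError"]

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


class ParseError(ValueError):
    """Unreadable PDB content."""


@dataclass
class Structure:
    """Atom table of one model of a PDB entry."""

    atoms: pd.DataFrame
    model_id: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        required = {"serial", "name", "element", "altloc", "occupancy",
                    "resname", "resseq", "chain", "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table lacks columns {sorted(missing)}")
        coords = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        if "is_hydrogen" not in self.atoms.columns:
            self.atoms["is_hydrogen"] = self.atoms["element"].str.upper().isin(["H", "D"])
        if "is_water" not in self.atoms.columns:
            self.atoms["is_water"] = self.atoms["resname"].isin(WATER_NAMES)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue(self, chain: str, resseq: int) -> pd.DataFrame:
        """Atoms of one residue (author numbering)."""
        sel = self.atoms[(self.atoms["chain"] == chain) & (self.atoms["resseq"] == resseq)]
        if sel.empty:
            raise KeyError(f"no residue {chain}:{resseq} in structure")
        return sel

    def coords(self, rows: pd.DataFrame) -> np.ndarray:
        return rows[["x", "y", "z"]].to_numpy(dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with coordinates rigidly transformed (testing helper)."""
        atoms = self.atoms.copy()
        xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float) @ np.asarray(rotation).T
        xyz = xyz + np.asarray(translation, dtype=float)
        atoms[["x", "y", "z"]] = xyz
        return Structure(atoms=atoms, model_id=self.model_id, name=self.name)


def _resolve_altlocs(df: pd.DataFrame) -> pd.DataFrame:
    """Keep one atom per (chain, resseq, name): max occupancy, tie → 'A'."""
    if (df["altloc"] == "").all():
        return df
    ranked = df.sort_values(
        by=["occupancy", "altloc"], ascending=[False, True], kind="stable"
    )
    keep = ranked.drop_duplicates(subset=["chain", "resseq", "name"], keep="first")
    return keep.sort_index()


def _model_to_frame(model: gemmi.Model) -> pd.DataFrame:
    records = []
    for chain in model:
        for res in chain:
            for atom in res:
                records.append(
                    (
                        atom.serial,
                        atom.name,
                        atom.element.name.upper(),
                        atom.altloc.strip() if atom.altloc else "",
                        atom.occ,
                        res.name,
                        res.seqid.num,
                        chain.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    return pd.DataFrame(
        records,
        columns=["serial", "name", "element", "altloc", "occupancy",
                 "resname", "resseq", "chain", "x", "y", "z"],
    )


def read_structure(source: str | Path, model: int | None = None) -> Structure:
    """Read a PDB file (path or raw text) into a :class:`Structure`.

    ``model`` selects a model by number from multi-model files; the
    default is the first model.
    """
    models = read_models(source)
    if model is None:
        return models[0]
    for st in models:
        if st.model_id == model:
            return st
    raise KeyError(f"model {model} not present (models: {[s.model_id for s in models]})")


def read_models(source: str | Path) -> list[Structure]:
    """Read every model of a (possibly multi-model) PDB file."""
    text, name = _load(source)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB content: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no models found in PDB content")
    out = []
    for model in st:
        df = _model_to_frame(model)
        if df.empty:
            continue
        df = _resolve_altlocs(df).reset_index(drop=True)
        out.append(Structure(atoms=df, model_id=int(model.num), name=name or st.name))
    if not out:
        raise ParseError("PDB content contains no atoms")
    return out


def _load(source: str | Path) -> tuple[str, str]:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        return Path(source).read_text(), Path(source).stem
    return str(source), ""


def write_structure(structure: Structure | list[Structure], path: str | Path | None = None) -> str:
    """Write one structure (or a multi-model list) as PDB text.

    Returns the text; writes it to ``path`` when given.
    """
    structures = structure if isinstance(structure, list) else [structure]
    st = gemmi.Structure()
    st.name = structures[0].name or "synthetic"
    for s in structures:
        serials = s.atoms["serial"]
        if serials.duplicated().any():
            dupes = sorted(serials[serials.duplicated()].unique().tolist())
            raise ValueError(f"clashing atom serial numbers: {dupes}")
        model = gemmi.Model(s.model_id)
        for chain_name in s.atoms["chain"].unique():
            chain = gemmi.Chain(str(chain_name))
            sub = s.atoms[s.atoms["chain"] == chain_name]
            for resseq in sub["resseq"].unique():
                rsub = sub[sub["resseq"] == resseq]
                res = gemmi.Residue()
                res.name = str(rsub.iloc[0]["resname"])
                res.seqid = gemmi.SeqId(int(resseq), " ")
                for row in rsub.itertuples():
                    atom = gemmi.Atom()
                    atom.name = row.name
                    atom.serial = int(row.serial)
                    atom.element = gemmi.Element(row.element)
                    atom.occ = float(row.occupancy)
                    atom.altloc = row.altloc if row.altloc else "\0"
                    atom.pos = gemmi.Position(row.x, row.y, row.z)
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text
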