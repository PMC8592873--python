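"""Atomic-structure I/O and selection primitives.

Structures are read from PDB files (plain or gzipped) through gemmi and
normalized into a lightweight chain/residue/atom hierarchy that the rest of
the package consumes.  Author residue numbering is kept verbatim: the
literature on this system labels residues by author numbers (Gly16, His49,
Asn62, ...) and every downstream report uses the same labels.

Alternate locations are resolved eagerly: for each (chain, residue, atom
name) key only the conformer with the highest occupancy is kept, ties going
to the lexicographically first alt-loc identifier.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "heavy_atoms",
    "protein_only",
    "ca_atoms",
    "infer_element",
]

#: residue names treated as solvent
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CU", "NI", "CO", "NA", "CA", "CL", "BR", "SE", "CD",
}


class PDBParseError(ValueError):
    """Raised for malformed fixed-width coordinate records."""


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Used when the element columns are blank (common in older entries).
    Digits and primes are stripped; a leading two-letter metal/halogen
    symbol is honored, otherwise the first alphabetic character wins.
    """
    name = atom_name.strip().upper()
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) == len(stripped):
        # distinguish calcium "CA" (hetero ion) from C-alpha " CA " by residue
        if not (stripped[:2] == "CA" and residue_name not in {"CA", ""} and residue_name not in WATER_NAMES):
            return stripped[:2].capitalize()
    return stripped[0]


@dataclass(slots=True)
class AtomRecord:
    """One atom as read from an ATOM/HETATM record (alt-loc resolved)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    xyz: np.ndarray  # (3,) Å
    occupancy: float
    b_factor: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite triple")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element after inference")


@dataclass(slots=True)
class Residue:
    name: str
    number: int
    insertion_code: str
    hetero: bool
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.name} {self.number}")

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES


@dataclass(slots=True)
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"no residue {number}{insertion_code} in chain {self.chain_id}")


@dataclass
class StructureModel:
    """Parsed multi-chain structure; iteration order equals file order."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def iter_residues(self):
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self.iter_atoms())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates in file order, shape (A, 3)."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.stack([a.xyz for a in self.iter_atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3), got {xyz.shape}")
        for a, row in zip(self.iter_atoms(), xyz):
            a.xyz = row.copy()

    def filtered(self, predicate, suffix: str = "") -> "StructureModel":
        """New structure keeping atoms for which ``predicate(residue, atom)`` holds."""
        out = StructureModel(id=self.id + suffix)
        for c in self.chains:
            new_c = Chain(chain_id=c.chain_id)
            for r in c.residues:
                kept = [a for a in r.atoms if predicate(r, a)]
                if kept:
                    new_c.residues.append(replace(r, atoms=[replace(a, xyz=a.xyz.copy()) for a in kept]))
            if new_c.residues:
                out.chains.append(new_c)
        return out

    def atom_index(self) -> dict[tuple[str, int, str, str], int]:
        """Map (chain, resnum, icode, atom name) -> flat atom position."""
        idx = {}
        for i, (cid, r, a) in enumerate(
            (c.chain_id, r, a) for c in self.chains for r in c.residues for a in r.atoms
        ):
            idx[(cid, r.number, r.insertion_code, a.name)] = i
        return idx


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"truncated coordinate record at line {lineno}")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"malformed coordinate fields at line {lineno}") from exc


def _read_text(source) -> tuple[str, str]:
    """Return (text, default id) from a path, text stream, or raw string."""
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        return data, getattr(source, "name", "structure")
    path = os.fspath(source)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        text = fh.read()
    base = os.path.basename(path)
    for ext in (".gz", ".pdb", ".ent"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return text, base


def _resolve_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per name: highest occupancy, ties to first alt-loc id."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        else:
            b = best[a.name]
            if (a.occupancy, b.alt_loc) > (b.occupancy, a.alt_loc):
                best[a.name] = a
    return [best[n] for n in order]


def read_pdb(source, model_index: int = 0, id: str | None = None) -> StructureModel:
    """Read one model from a PDB file, path, stream or string.

    Parameters
    ----------
    source
        Path (gzip-transparent), open text/binary stream, or a string that
        contains PDB records.
    model_index
        Zero-based MODEL to extract; multi-model files hold one
        conformation per MODEL block.
    """
    if isinstance(source, str) and ("\n" in source or source.startswith(("ATOM", "HETATM", "MODEL", "HEADER"))):
        text, default_id = source, "structure"
    else:
        text, default_id = _read_text(source)
    _validate_coordinate_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is permissive
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models found")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model {model_index} absent: file has {len(st)} model(s)")
    model = st[model_index]

    out = StructureModel(id=id or (st.name.strip() or default_id))
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            residue = Residue(
                name=res.name,
                number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                hetero=(res.het_flag == "H"),
            )
            records = []
            for at in res:
                elem = at.element.name if at.element and at.element.name not in ("X", "") else ""
                if not elem:
                    elem = infer_element(at.name, res.name)
                records.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=elem,
                        alt_loc=(at.altloc or "").strip("\x00").strip(),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=ch.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                    )
                )
            residue.atoms = _resolve_alt_locs(records)
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    return out


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "ATOM  "  # caller rewrites the prefix for hetero residues
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    return (
        f"{record}{serial:>5d} {name:<4s}{(a.alt_loc or ' '):1s}{a.residue_name:>3s} "
        f"{a.chain_id[:1]:1s}{a.residue_number:>4d}{(a.insertion_code or ' '):1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element.upper():>2s}"
    )


def write_pdb(structure: StructureModel, target, frames: np.ndarray | None = None) -> None:
    """Write a structure (optionally as a multi-model file) in PDB format.

    ``frames`` with shape (F, A, 3) produces one MODEL block per frame using
    the structure as topology; coordinates print at the format's 3-decimal
    precision.
    """
    def emit(fh):
        def one_model(xyz=None):
            serial = 0
            i = 0
            for c in structure.chains:
                for r in c.residues:
                    for a in r.atoms:
                        serial += 1
                        rec = a if xyz is None else replace(a, xyz=np.asarray(xyz[i]))
                        line = _format_atom_line(rec, serial)
                        if r.hetero:
                            line = "HETATM" + line[6:]
                        fh.write(line + "\n")
                        i += 1
                serial += 1
                fh.write(f"TER   {serial:>5d}      {c.residues[-1].name:>3s} {c.chain_id[:1]:1s}"
                         f"{c.residues[-1].number:>4d}\n")

        if frames is None:
            one_model()
        else:
            arr = np.asarray(frames, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != structure.n_atoms:
                raise ValueError("frames must have shape (F, n_atoms, 3)")
            for m, xyz in enumerate(arr, start=1):
                fh.write(f"MODEL     {m:>4d}\n")
                one_model(xyz)
                fh.write("ENDMDL\n")
        fh.write("END\n")

    if hasattr(target, "write"):
        emit(target)
    else:
        with open(os.fspath(target), "w") as fh:
            emit(fh)


def heavy_atoms(structure: StructureModel) -> StructureModel:
    """Atoms whose element is not hydrogen or deuterium, order preserved."""
    return structure.filtered(lambda r, a: a.element.upper() not in ("H", "D"))


def protein_only(structure: StructureModel, include_het: bool = False) -> StructureModel:
    """Drop waters, and hetero residues unless ``include_het``."""
    def keep(r, a):
        if r.is_water:
            return False
        return include_het or not r.hetero
    return structure.filtered(keep)


def ca_atoms(structure: StructureModel) -> StructureModel:
    """C-alpha trace of the protein part."""
    return structure.filtered(lambda r, a: a.name == "CA" and not r.hetero and not r.is_water)


def ca_indices(structure: StructureModel) -> np.ndarray:
    """Flat atom indices of protein C-alpha atoms."""
    idx = []
    i = 0
    for c in structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if a.name == "CA" and not r.hetero and not r.is_water:
                    idx.append(i)
                i += 1
    return np.asarray(idx, dtype=int)
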