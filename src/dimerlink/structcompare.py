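"""Structure comparison: C-alpha superposition/RMSD, solvent-accessible
surface area, dimer-interface analysis, and a polar-contact census.

SASA uses Shrake-Rupley sphere sampling with a deterministic golden-spiral
point set.  To make the result exactly equivariant under rigid motion of
the whole structure, the sphere points are expressed in a local orthonormal
frame built from the principal axes of the heavy-atom cloud (deterministic
sign convention), so the sampling pattern rotates with the molecule.

Relative accessibility divides a residue's SASA by the theoretical maximum
for its type (Tien et al. Gly-X-Gly values), and the dimer interface is the
set of residues whose relative accessibility drops by more than a threshold
(default 10 percentage points) between the isolated chain and the dimer.

Polar contacts use heavy-atom distance-only criteria (crystal structures at
~2 Å resolution carry no hydrogens): N/O-N/O within 3.5 Å for hydrogen
bonds, side-chain N (Arg/Lys/His) to side-chain carboxylate O (Asp/Glu)
within 4.0 Å for salt bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import kabsch
from .structio import StructureModel, heavy_atoms, protein_only

__all__ = [
    "SuperpositionResult",
    "SasaResult",
    "InterfaceReport",
    "PolarContact",
    "superpose",
    "pair_ca_coords",
    "sasa",
    "interface_residues",
    "buried_surface_area",
    "polar_contacts",
    "atom_distance",
]

#: van der Waals radii (Å), Chothia-style values for protein heavy atoms
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "Se": 1.90, "H": 1.20, "D": 1.20, "F": 1.47, "Cl": 1.75,
    "Br": 1.85, "I": 1.98,
}

#: theoretical maximum residue SASA (Å²), Tien et al. Gly-X-Gly values
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3) proper orthonormal
    translation: np.ndarray   # (3,)
    rmsd: float               # Å, over pairs actually used
    rmsd_all_pairs: float     # Å, over every supplied pair under the final fit
    n_pairs_used: int
    rejected: list[int] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class SasaResult:
    atom_sasa: np.ndarray                       # (A,) Å²
    residue_sasa: dict[tuple[str, int], float]  # Å²
    relative: dict[tuple[str, int], float]      # fraction of reference maximum
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


@dataclass
class PolarContact:
    atom1: tuple[str, int, str]  # (chain, resnum, atom name)
    atom2: tuple[str, int, str]
    distance: float
    kind: str                    # "hbond" or "salt_bridge"


@dataclass
class InterfaceReport:
    residues: dict[str, dict[int, dict]]   # chain -> resnum -> accessibility record
    threshold: float                       # percentage points
    bsa: float | None = None               # Å², total buried surface
    interface_area: float | None = None    # Å², BSA / 2
    contacts: list[PolarContact] = field(default_factory=list)

    def flagged(self, chain: str) -> list[int]:
        return sorted(n for n, rec in self.residues.get(chain, {}).items() if rec["flagged"])


def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    mode: str = "all_pairs",
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> SuperpositionResult:
    """Kabsch least-squares fit of paired coordinate sets.

    ``iterative_reject`` repeats the fit up to ``max_cycles`` times,
    discarding pairs whose deviation exceeds ``reject_factor`` times the
    current RMSD — the behavior of molecular-graphics aligners, whose
    published RMSDs are computed after outlier rejection.  Both the final
    (post-rejection) RMSD and the all-pairs RMSD under the final transform
    are reported.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape:
        raise ValueError("reference and mobile must be paired (same shape)")
    n = ref.shape[0]
    keep = np.ones(n, dtype=bool)
    R, t, rmsd = kabsch(mob, ref)
    if mode == "iterative_reject":
        for _ in range(max_cycles):
            dev = np.linalg.norm(mob[keep] @ R.T + t - ref[keep], axis=1)
            cur = np.sqrt(np.mean(dev**2))
            new_keep = keep.copy()
            new_keep[np.flatnonzero(keep)[dev > reject_factor * cur]] = False
            if new_keep.sum() < 3:
                raise ValueError("fewer than 3 pairs left after rejection")
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
            R, t, rmsd = kabsch(mob[keep], ref[keep])
    elif mode != "all_pairs":
        raise ValueError(f"unknown mode {mode!r}")
    dev_all = np.linalg.norm(mob @ R.T + t - ref, axis=1)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=float(rmsd),
        rmsd_all_pairs=float(np.sqrt(np.mean(dev_all**2))),
        n_pairs_used=int(keep.sum()),
        rejected=np.flatnonzero(~keep).tolist(),
    )


def pair_ca_coords(
    a: StructureModel, b: StructureModel, chains: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """C-alpha coordinates paired by (chain, residue number) across two structures."""
    def ca_map(s):
        out = {}
        for c in s.chains:
            if chains is not None and c.chain_id not in chains:
                continue
            for r in c.residues:
                if r.hetero or r.is_water:
                    continue
                for at in r.atoms:
                    if at.name == "CA":
                        out[(c.chain_id, r.number)] = at.xyz
        return out

    ma, mb = ca_map(a), ca_map(b)
    keys = sorted(set(ma) & set(mb))
    if len(keys) < 3:
        raise ValueError("fewer than 3 shared C-alpha pairs")
    return np.stack([ma[k] for k in keys]), np.stack([mb[k] for k in keys]), keys


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (no RNG)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _local_frame(coords: np.ndarray) -> np.ndarray:
    """Orthonormal frame from principal axes with deterministic signs.

    The frame rotates with the structure, which makes the sampled SASA
    exactly equivariant under rigid motion.  For (near-)degenerate clouds
    the frame is arbitrary within the degenerate subspace, but such shapes
    are rotationally symmetric to within sampling error anyway.
    """
    if coords.shape[0] < 3:
        return np.eye(3)
    X = coords - coords.mean(axis=0)
    C = X.T @ X / coords.shape[0]
    evals, evecs = np.linalg.eigh(C)
    frame = evecs[:, ::-1]  # principal axis first
    for j in range(3):
        col = frame[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            frame[:, j] = -col
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    return frame


def _radii_for(atoms, fallback_radius: float | None) -> np.ndarray:
    r = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        key = a.element.capitalize()
        if key in VDW_RADII:
            r[i] = VDW_RADII[key]
        elif fallback_radius is not None:
            r[i] = fallback_radius
        else:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
    return r


def sasa(
    structure: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
    fallback_radius: float | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area of the heavy atoms."""
    body = heavy_atoms(protein_only(structure, include_het=include_het))
    atoms = body.atoms
    if not atoms:
        raise ValueError("no heavy atoms to compute SASA for")
    xyz = body.coords()
    radii = _radii_for(atoms, fallback_radius)
    ext = radii + probe
    sphere = _golden_spiral(n_points) @ _local_frame(xyz).T

    tree = cKDTree(xyz)
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], ext[i] + ext.max())
                     if j != i and np.linalg.norm(xyz[j] - xyz[i]) < ext[i] + ext[j]]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()

    res_sasa: dict[tuple[str, int], float] = {}
    res_name: dict[tuple[str, int], str] = {}
    i = 0
    for c in body.chains:
        for r in c.residues:
            key = (c.chain_id, r.number)
            res_sasa[key] = res_sasa.get(key, 0.0) + float(areas[i : i + len(r.atoms)].sum())
            res_name[key] = r.name
            i += len(r.atoms)
    relative = {
        k: (v / MAX_SASA[res_name[k]] if res_name[k] in MAX_SASA else float("nan"))
        for k, v in res_sasa.items()
    }
    return SasaResult(atom_sasa=areas, residue_sasa=res_sasa, relative=relative,
                      probe=probe, n_points=n_points)


def _single_chain(structure: StructureModel, chain_id: str) -> StructureModel:
    structure.chain(chain_id)  # raises KeyError if absent
    return structure.filtered(lambda r, a: a.chain_id == chain_id, suffix=f":{chain_id}")


def interface_residues(
    dimer: StructureModel,
    chain_a: str,
    chain_b: str,
    threshold: float = 10.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Residues whose relative accessibility drops by more than ``threshold``
    percentage points between the isolated chain and the dimer."""
    sasa_dimer = sasa(dimer, probe=probe, n_points=n_points)
    report: dict[str, dict[int, dict]] = {}
    for cid in (chain_a, chain_b):
        mono = sasa(_single_chain(dimer, cid), probe=probe, n_points=n_points)
        per_res = {}
        for (c, n), rel_mono in mono.relative.items():
            rel_dimer = sasa_dimer.relative.get((c, n), 0.0)
            delta_pp = 100.0 * (rel_mono - rel_dimer)
            per_res[n] = {
                "rel_monomer": rel_mono,
                "rel_dimer": rel_dimer,
                "delta_pp": delta_pp,
                "dsasa": mono.residue_sasa[(c, n)] - sasa_dimer.residue_sasa.get((c, n), 0.0),
                "flagged": bool(np.isfinite(delta_pp) and delta_pp > threshold),
            }
        report[cid] = per_res
    return InterfaceReport(residues=report, threshold=threshold)


def buried_surface_area(
    dimer: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """(BSA, interface area): SASA(A) + SASA(B) - SASA(AB), and half of it."""
    s_ab = sasa(dimer, probe=probe, n_points=n_points).total
    s_a = sasa(_single_chain(dimer, chain_a), probe=probe, n_points=n_points).total
    s_b = sasa(_single_chain(dimer, chain_b), probe=probe, n_points=n_points).total
    bsa = s_a + s_b - s_ab
    return bsa, bsa / 2.0


def polar_contacts(
    structure: StructureModel,
    cross_chain_only: bool = False,
    hbond_cutoff: float = 3.5,
    salt_bridge_cutoff: float = 4.0,
) -> list[PolarContact]:
    """Distance-criterion hydrogen bonds and salt bridges between residues."""
    body = heavy_atoms(protein_only(structure))
    entries = []  # (key, element, resname, xyz)
    for c in body.chains:
        for r in c.residues:
            for a in r.atoms:
                if a.element.upper() in ("N", "O"):
                    entries.append(((c.chain_id, r.number, a.name), a.element.upper(), r.name, a.xyz))
    if not entries:
        return []
    xyz = np.stack([e[3] for e in entries])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(max(hbond_cutoff, salt_bridge_cutoff), output_type="ndarray")
    out = []
    for i, j in pairs:
        k1, e1, rn1, x1 = entries[i]
        k2, e2, rn2, x2 = entries[j]
        if k1[:2] == k2[:2]:
            continue  # same residue
        if cross_chain_only and k1[0] == k2[0]:
            continue
        d = float(np.linalg.norm(x1 - x2))
        is_sb = False
        for (kb, rb), (ka, ra) in (((k1, rn1), (k2, rn2)), ((k2, rn2), (k1, rn1))):
            if (rb in BASIC_SIDECHAIN_N and kb[2] in BASIC_SIDECHAIN_N[rb]
                    and ra in ACIDIC_SIDECHAIN_O and ka[2] in ACIDIC_SIDECHAIN_O[ra]
                    and d <= salt_bridge_cutoff):
                is_sb = True
                break
        if is_sb:
            out.append(PolarContact(atom1=k1, atom2=k2, distance=d, kind="salt_bridge"))
        elif d <= hbond_cutoff:
            out.append(PolarContact(atom1=k1, atom2=k2, distance=d, kind="hbond"))
    out.sort(key=lambda c: (c.atom1, c.atom2))
    return out


def _resolve_atom(structure: StructureModel, spec: str) -> np.ndarray:
    try:
        chain, resnum, name = spec.split(":")
        return structure.chain(chain).residue(int(resnum)).atom(name).xyz
    except (ValueError, KeyError) as exc:
        raise KeyError(f"cannot resolve atom spec {spec!r}: {exc}") from exc


def atom_distance(structure: StructureModel, spec1: str, spec2: str) -> float:
    """Euclidean distance between two atoms given as 'chain:resnum:name'."""
    return float(np.linalg.norm(_resolve_atom(structure, spec1) - _resolve_atom(structure, spec2)))
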