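"""Seeded synthetic-data generators with planted ground truth.

Every input class the pipeline consumes can be generated here:

* :func:`make_planted_ensemble` — a toy dimer ensemble (two mirrored
  zig-zag pseudo-chains, four heavy atoms per residue) whose residue
  contact graph and minimum-weight interprotomer path are known by
  construction.  Residues on the planted path share a collective rigid
  displacement plus small individual jitter, so the distance series along
  planted edges have low relative fluctuation, while all other residues
  move independently with larger amplitude;
* :func:`make_enm_ensemble` — Gaussian frames drawn from the covariance of
  a Hookean (anisotropic elastic-network) Hessian, with analytic marginal
  variances emitted for oracle checks;
* :func:`make_ddg_table` — stability-prediction tables in which every row
  either passes the mutation screen with >= 0.5 kcal/mol margin on every
  criterion or violates exactly one named criterion;
* :func:`make_curves` — noisy realizations of the diffusion-decay, 4PL
  dose-response, two-state melting and dimer-exchange models on their
  standard measurement grids.

Each generator is a pure function of (spec, seed): the same seed yields
bit-identical output, and the emitted ground-truth record is sufficient
for every downstream assertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biophys
from .biophys import CurveSeries, DecayExperiment
from .ensemble import Ensemble
from .mutscreen import AA_CHARGE, DdgRecord, ScreenCriteria
from .structio import AtomRecord, Chain, Residue, StructureModel

__all__ = [
    "PlantedEnsembleSpec",
    "PlantedTruth",
    "EnmSpec",
    "make_planted_ensemble",
    "make_enm_ensemble",
    "make_ddg_table",
    "make_curves",
    "to_decay_experiment",
]

# ---------------------------------------------------------------------------
# planted dimer ensembles


@dataclass(frozen=True)
class PlantedEnsembleSpec:
    """Toy dimer geometry with a planted minimum-weight interprotomer path.

    Geometry: two parallel mirrored zig-zag chains (A below, B above).
    Within a chain, residues i and i+2 are in contact (the "rails"); the
    chains touch only at ``interface_columns``, where each residue carries
    an extra atom reaching toward the opposite chain.  The planted path
    runs along chain A's rail from ``source_column``, crosses at
    ``cross_column`` (must be an interface column of matching parity), and
    returns along chain B's rail to ``target_column``.

    ``cv_low``/``cv_high`` are nominal distance coefficient-of-variation
    targets (sd/mean at the 4 Å rail distance) for on-path and off-path
    edges; the planted contrast is ``cv_high / cv_low``.
    """

    n_per_chain: int = 30
    n_frames: int = 2000
    seed: int = 0
    cv_low: float = 0.02
    cv_high: float = 0.065
    interface_columns: tuple[int, ...] = (13, 14, 15, 16, 17, 18)
    source_column: int = 6
    cross_column: int = 14
    target_column: int = 6
    # geometry constants (Å); see class docstring
    dx: float = 2.0
    zig: float = 3.4
    gap: float = 5.6
    tet_radius: float = 0.35
    reach: float = 1.5
    contact_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if not self.cv_low < self.cv_high:
            if self.cv_low != self.cv_high:
                raise ValueError("cv_low must not exceed cv_high")
        cols = range(1, self.n_per_chain + 1)
        for c in (self.source_column, self.cross_column, self.target_column):
            if c not in cols:
                raise ValueError(f"column {c} outside chain 1..{self.n_per_chain}")
        if self.cross_column not in self.interface_columns:
            raise ValueError("cross_column must be an interface column")
        for c in (self.source_column, self.target_column):
            if (c - self.cross_column) % 2 != 0:
                raise ValueError("source/target parity must match the crossing column")


@dataclass
class PlantedTruth:
    path: list[tuple[str, int]]
    expected_weight: float
    cross_contacts: set[frozenset]
    contacts: set[frozenset]
    degenerate: bool
    spec: PlantedEnsembleSpec | None = None

    def expected_edges(self, neighbor_exclusion: int = 1) -> set[frozenset]:
        """Contacts that survive the network's sequence-neighbor exclusion."""
        out = set()
        for e in self.contacts:
            (c1, n1), (c2, n2) = sorted(e)
            if c1 == c2 and abs(n1 - n2) <= neighbor_exclusion:
                continue
            out.add(e)
        return out


_TET_OFFSETS = np.array([  # unit tetrahedron directions, fixed orientation
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)
_ATOM_NAMES = ("N", "CA", "C", "O")
_ATOM_ELEMS = ("N", "C", "C", "O")


def _toy_topology(spec: PlantedEnsembleSpec) -> tuple[StructureModel, np.ndarray, list[int]]:
    """Build the rest-state structure; returns (topology, rest coords, residue sizes)."""
    model = StructureModel(id="planted-dimer")
    coords = []
    sizes = []
    serial = 0
    for cid, z0, direction in (("A", 0.0, +1.0), ("B", spec.gap, -1.0)):
        chain = Chain(chain_id=cid)
        for i in range(1, spec.n_per_chain + 1):
            center = np.array([spec.dx * i, spec.zig * (i % 2), z0])
            res = Residue(name="ALA", number=i, insertion_code="", hetero=False)
            atom_xyz = [center + spec.tet_radius * o for o in _TET_OFFSETS]
            names = list(_ATOM_NAMES)
            elems = list(_ATOM_ELEMS)
            if i in spec.interface_columns:
                atom_xyz.append(center + np.array([0.0, 0.0, direction * spec.reach]))
                names.append("CB")
                elems.append("C")
            for name, elem, xyz in zip(names, elems, atom_xyz):
                serial += 1
                res.atoms.append(AtomRecord(
                    serial=serial, name=name, element=elem, alt_loc="",
                    residue_name="ALA", residue_number=i, insertion_code="",
                    chain_id=cid, xyz=xyz, occupancy=1.0, b_factor=0.0,
                ))
            chain.residues.append(res)
            coords.extend(atom_xyz)
            sizes.append(len(atom_xyz))
        model.chains.append(chain)
    return model, np.asarray(coords), sizes


def _rest_contacts(spec: PlantedEnsembleSpec, rest: np.ndarray, sizes: list[int]):
    """Residue pairs in heavy-atom contact at rest, with feasibility margins.

    Because the per-frame fluctuations are small and zero-mean, contact
    occupancy concentrates tightly around its per-frame probability, so a
    rest-state distance comfortably below (above) the cutoff guarantees an
    occupancy far above (below) the 75% retention threshold.  Distances in
    the ambiguous band around the cutoff make the spec infeasible.
    """
    n_res = len(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    keys = []
    for cid in ("A", "B"):
        keys += [(cid, i) for i in range(1, spec.n_per_chain + 1)]
    lo_band = spec.contact_cutoff - 0.30
    hi_band = spec.contact_cutoff - 0.05
    contacts = set()
    for a in range(n_res):
        for b in range(a + 1, n_res):
            xa = rest[starts[a]:starts[a + 1]]
            xb = rest[starts[b]:starts[b + 1]]
            dmin = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min()
            if dmin <= lo_band:
                contacts.add(frozenset((keys[a], keys[b])))
            elif dmin < hi_band:
                raise ValueError(
                    f"infeasible geometry: pair {keys[a]}-{keys[b]} rest distance "
                    f"{dmin:.2f} Å lies in the ambiguous band around the cutoff"
                )
    return contacts, keys


def _planted_path(spec: PlantedEnsembleSpec) -> list[tuple[str, int]]:
    step_a = 2 if spec.cross_column >= spec.source_column else -2
    cols_a = list(range(spec.source_column, spec.cross_column + np.sign(step_a), step_a))
    step_b = 2 if spec.target_column >= spec.cross_column else -2
    cols_b = list(range(spec.cross_column, spec.target_column + np.sign(step_b), step_b))
    return [("A", c) for c in cols_a] + [("B", c) for c in cols_b]


def make_planted_ensemble(spec: PlantedEnsembleSpec) -> tuple[Ensemble, PlantedTruth]:
    """Generate the planted-path dimer ensemble and its ground truth."""
    topology, rest, sizes = _toy_topology(spec)
    contacts, keys = _rest_contacts(spec, rest, sizes)
    path = _planted_path(spec)
    path_set = set(path)
    path_edges = {frozenset(e) for e in zip(path, path[1:])}
    missing = path_edges - contacts
    if missing:
        raise ValueError(f"infeasible spec: planted path edges not in contact: {missing}")

    d_ref = 2.0 * spec.dx  # nominal rail distance the cv targets refer to
    sigma_jit = spec.cv_low * d_ref / np.sqrt(2.0)
    sigma_off = spec.cv_high * d_ref / np.sqrt(2.0)
    sigma_coll = sigma_off  # collective motion of the path group

    rng = np.random.default_rng(spec.seed)
    n_res = len(sizes)
    F = spec.n_frames
    disp = np.empty((F, n_res, 3))
    on_path = np.array([k in path_set for k in keys])
    coll = rng.normal(0.0, sigma_coll, size=(F, 3))
    disp[:, on_path, :] = coll[:, None, :] + rng.normal(0.0, sigma_jit, size=(F, int(on_path.sum()), 3))
    disp[:, ~on_path, :] = rng.normal(0.0, sigma_off, size=(F, int((~on_path).sum()), 3))

    starts = np.concatenate([[0], np.cumsum(sizes)])
    frames = np.broadcast_to(rest, (F, *rest.shape)).copy()
    for r in range(n_res):
        frames[:, starts[r]:starts[r + 1], :] += disp[:, r, None, :]

    # first-order expected path weight under the default (variance/mean) convention
    centers = np.array([rest[starts[r]:starts[r + 1]].mean(axis=0) for r in range(n_res)])
    key_idx = {k: i for i, k in enumerate(keys)}
    exp_weight = 0.0
    for u, v in zip(path, path[1:]):
        d = float(np.linalg.norm(centers[key_idx[u]] - centers[key_idx[v]]))
        exp_weight += 2.0 * sigma_jit**2 / d
    cross = {e for e in contacts if len({k[0] for k in e}) == 2}
    truth = PlantedTruth(
        path=path,
        expected_weight=exp_weight,
        cross_contacts=cross,
        contacts=contacts,
        degenerate=(spec.cv_low == spec.cv_high),
        spec=spec,
    )
    return Ensemble(topology=topology, frames=frames), truth


# ---------------------------------------------------------------------------
# elastic-network ensembles


@dataclass(frozen=True)
class EnmSpec:
    """Hookean network: springs between particles within ``cutoff``."""

    coords: tuple  # (N, 3) reference coordinates, Å (tuple-of-tuples for hashability)
    cutoff: float = 7.0
    spring_k: float = 1.0     # kcal/mol/Å²
    kT: float = 0.6           # kcal/mol (about 300 K)
    n_frames: int = 5000
    seed: int = 0


def _enm_hessian(xyz: np.ndarray, cutoff: float, k: float) -> np.ndarray:
    n = len(xyz)
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            dv = xyz[j] - xyz[i]
            d = np.linalg.norm(dv)
            if d <= cutoff:
                block = -k * np.outer(dv, dv) / (d * d)
                H[3*i:3*i+3, 3*j:3*j+3] += block
                H[3*j:3*j+3, 3*i:3*i+3] += block
                H[3*i:3*i+3, 3*i:3*i+3] -= block
                H[3*j:3*j+3, 3*j:3*j+3] -= block
    return H


def make_enm_ensemble(spec: EnmSpec) -> tuple[Ensemble, dict]:
    """Sample frames from the Gaussian ensemble of an elastic network.

    The covariance is kT times the pseudo-inverse of the Hessian over its
    internal (non-rigid-body) modes; a disconnected network has more than
    six null modes and is rejected (its variance would be infinite).
    Returns the ensemble plus analytic per-particle positional variances.
    """
    xyz = np.asarray(spec.coords, float).reshape(-1, 3)
    n = len(xyz)
    if n < 2:
        raise ValueError("need at least 2 particles")
    H = _enm_hessian(xyz, spec.cutoff, spec.spring_k)
    evals, evecs = np.linalg.eigh(H)
    tol = max(1e-9, 1e-9 * evals.max())
    n_null = int(np.sum(evals < tol))
    if n_null > 6:
        raise ValueError("disconnected elastic network: infinite variance modes")
    inv = np.where(evals < tol, 0.0, 1.0 / np.clip(evals, tol, None))
    cov = spec.kT * (evecs * inv) @ evecs.T
    # sample via the eigenbasis (deterministic given the seed)
    rng = np.random.default_rng(spec.seed)
    amp = np.sqrt(spec.kT * inv)
    z = rng.normal(size=(spec.n_frames, 3 * n)) * amp
    frames = (z @ evecs.T).reshape(spec.n_frames, n, 3) + xyz

    model = StructureModel(id="enm")
    chain = Chain(chain_id="A")
    for i, x in enumerate(xyz, start=1):
        res = Residue(name="GLY", number=i, insertion_code="", hetero=False)
        res.atoms.append(AtomRecord(
            serial=i, name="CA", element="C", alt_loc="", residue_name="GLY",
            residue_number=i, insertion_code="", chain_id="A", xyz=x,
            occupancy=1.0, b_factor=0.0,
        ))
        chain.residues.append(res)
    model.chains.append(chain)

    var3 = np.diag(cov).reshape(n, 3)
    truth = {
        "covariance": cov,
        "particle_variance": var3.sum(axis=1),      # <|dx|^2> per particle, Å²
        "marginal_std": np.sqrt(var3),               # per coordinate, Å
        "n_null_modes": n_null,
    }
    return Ensemble(topology=model, frames=frames), truth


# ---------------------------------------------------------------------------
# stability-prediction tables

_NEUTRAL_AAS = sorted(aa for aa, q in AA_CHARGE.items() if q == 0 and aa not in "GPC")
_CHARGED_AAS = sorted(aa for aa, q in AA_CHARGE.items() if q != 0)


def make_ddg_table(
    n_positions: int = 50,
    pass_positions: tuple[int, ...] = (16, 18, 91, 135),
    seed: int = 0,
    margin: float = 0.5,
) -> tuple[list[DdgRecord], dict]:
    """Generate a ΔΔG table with a known pass/fail ledger.

    Rows at ``pass_positions`` satisfy every screen criterion with at least
    ``margin`` kcal/mol to spare; every other row violates exactly one
    named criterion (by at least the same margin where numeric).  The
    emitted truth carries the matching :class:`ScreenCriteria`, the
    expected survivor labels and the expected first-failure annotation per
    row.
    """
    rng = np.random.default_rng(seed)
    pass_positions = tuple(sorted(set(pass_positions)))
    pool = [p for p in range(1, max(4 * n_positions, 200)) if p not in pass_positions]
    fail_positions = sorted(rng.choice(pool, size=max(n_positions - len(pass_positions), 0),
                                       replace=False).tolist())
    # half the failing positions sit on the interface and fail a later filter
    interface = set(pass_positions) | set(fail_positions[::2])

    def neutral_pair():
        wt, mut = rng.choice(_NEUTRAL_AAS, size=2, replace=False)
        return str(wt), str(mut)

    records: list[DdgRecord] = []
    expected_fail: list[str | None] = []
    gap_ok = lambda: 2.0 + margin + rng.uniform(0.0, 2.0)
    gap_bad = lambda: 2.0 - margin - rng.uniform(0.0, 2.0)
    ddgb_ok = lambda: 4.0 + margin + rng.uniform(0.0, 2.0)
    ddgb_bad = lambda: 4.0 - margin - rng.uniform(0.0, 2.0)

    for p in pass_positions:
        wt, mut = neutral_pair()
        mono = rng.uniform(-1.0, 1.0)
        records.append(DdgRecord(p, wt, mut, mono, mono + gap_ok(), ddgb_ok()))
        expected_fail.append(None)
    for p in fail_positions:
        if p in interface:
            mode = str(rng.choice(["ddgf_gap", "aa_exclusion", "charge", "ddgb"]))
        else:
            mode = "interface"
        mono = rng.uniform(-1.0, 1.0)
        gap = gap_bad() if mode == "ddgf_gap" else gap_ok()
        ddgb = ddgb_bad() if mode == "ddgb" else ddgb_ok()
        if mode == "aa_exclusion":
            wt = str(rng.choice(_NEUTRAL_AAS))
            mut = str(rng.choice(["G", "P", "C"]))
            while mut == wt:
                mut = str(rng.choice(["G", "P", "C"]))
        elif mode == "charge":
            wt = str(rng.choice(_NEUTRAL_AAS))
            mut = str(rng.choice(_CHARGED_AAS))
        else:
            wt, mut = neutral_pair()
        records.append(DdgRecord(p, wt, mut, mono, mono + gap, ddgb))
        expected_fail.append(mode)

    criteria = ScreenCriteria(interface_positions=frozenset(interface))
    truth = {
        "criteria": criteria,
        "expected_fail": expected_fail,
        "survivor_labels": [r.label for r, f in zip(records, expected_fail) if f is None],
        "pass_positions": set(pass_positions),
    }
    return records, truth


# ---------------------------------------------------------------------------
# biophysical curves

#: default gradient grid of the diffusion experiment: 40 linear steps,
#: 3.6 to 32.5 G/cm, with delta/2 = 4.3 ms, Delta = 70 ms, tau = 0.226 ms
DECAY_CONSTANTS = {"delta": 8.6e-3, "Delta": 70e-3, "tau": 0.226e-3}
DECAY_GRID_G_PER_CM = np.linspace(3.6, 32.5, 40)

_CURVE_DEFAULTS = {
    "decay": {"D": 1.0e-10, "I0": 1.0},
    "dose_response": {"ec50": 8.4, "hill": 1.5, "top": 100.0, "bottom": 0.0},
    "melt": {"tm": 67.8, "width": 1.5, "folded": -18.0, "unfolded": -5.0},
    "exchange": {"kd": 0.06, "free": 1.0, "bound": 0.0},
}
_NOISE_DEFAULTS = {  # (model, scale): multiplicative Gaussian for decay, additive otherwise
    "decay": ("multiplicative", 0.01),
    "dose_response": ("additive", 5.0),
    "melt": ("additive", 0.15),
    "exchange": ("additive", 0.01),
}


def make_curves(
    kind: str,
    truth: dict | None = None,
    noise: float | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[CurveSeries, dict]:
    """Evaluate a biophysical model on its standard grid and add seeded noise.

    kinds: ``decay`` (gradient strength in G/cm vs intensity),
    ``dose_response`` (μM vs % activity), ``melt`` (°C vs ellipticity),
    ``exchange`` (total protomer μM vs normalized signal).
    """
    if kind not in _CURVE_DEFAULTS:
        raise ValueError(f"unknown curve kind {kind!r}")
    params = dict(_CURVE_DEFAULTS[kind])
    if truth:
        params.update(truth)
    noise_model, noise_scale = _NOISE_DEFAULTS[kind]
    if noise is not None:
        noise_scale = noise
    rng = np.random.default_rng(seed)

    if kind == "decay":
        g = DECAY_GRID_G_PER_CM if grid is None else np.asarray(grid, float)
        exp = DecayExperiment.from_gauss_per_cm(g, np.ones_like(g), **DECAY_CONSTANTS)
        y = biophys.decay_model(exp.b_values, params["I0"], params["D"])
        x, xlabel, ylabel = g, "gradient_G_per_cm", "intensity"
        meta = {**DECAY_CONSTANTS}
    elif kind == "dose_response":
        x = np.geomspace(1.0, 50.0, 10) if grid is None else np.asarray(grid, float)
        y = biophys.logistic4(x, params["bottom"], params["top"],
                              np.log10(params["ec50"]), params["hill"])
        xlabel, ylabel, meta = "conc_uM", "activity_pct", {}
    elif kind == "melt":
        x = np.arange(20.0, 80.0 + 1e-9, 0.5) if grid is None else np.asarray(grid, float)
        y = biophys.melt_model(x, params["tm"], params["width"],
                               params["folded"], params["unfolded"])
        xlabel, ylabel, meta = "temperature_C", "ellipticity_mdeg", {}
    else:  # exchange
        x = 50.0 / 2.0 ** np.arange(16) if grid is None else np.asarray(grid, float)
        x = np.sort(x)
        y = biophys.exchange_model(x, params["kd"], params["free"], params["bound"])
        xlabel, ylabel, meta = "total_conc_uM", "signal_norm", {}

    if noise_model == "multiplicative":
        y = y * (1.0 + rng.normal(0.0, noise_scale, size=y.shape))
    else:
        y = y + rng.normal(0.0, noise_scale, size=y.shape)

    series = CurveSeries(x=x, y=y, xlabel=xlabel, ylabel=ylabel,
                         meta={**meta, "kind": kind, "seed": seed})
    truth_out = {"params": params, "noise_model": noise_model,
                 "noise_scale": noise_scale, "seed": seed}
    return series, truth_out


def to_decay_experiment(series: CurveSeries) -> DecayExperiment:
    """Interpret a decay CurveSeries (G/cm grid) as a DecayExperiment."""
    return DecayExperiment.from_gauss_per_cm(
        series.x, series.y,
        delta=series.meta.get("delta", DECAY_CONSTANTS["delta"]),
        Delta=series.meta.get("Delta", DECAY_CONSTANTS["Delta"]),
        tau=series.meta.get("tau", DECAY_CONSTANTS["tau"]),
    )
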