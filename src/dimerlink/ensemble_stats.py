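"""Per-residue flexibility measures: RMSF, ensemble PCA, and normalized
B-factor (B') comparison between crystal structures.

B' z-scores make B-factors comparable across structures refined at
different resolutions: ``classic_z`` is the ordinary (B - mean)/sd over a
chain's C-alpha set (sample standard deviation), ``robust_mad`` (default)
uses the median and 1.4826*MAD so single highly mobile loops do not inflate
the scale.  Normalization is per chain, because flexibility asymmetry
between the two protomers of a homodimer is itself a quantity of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble
from .structio import StructureModel, ca_indices

__all__ = [
    "FlexibilityProfile",
    "PCAModes",
    "rmsf",
    "pca_modes",
    "bprime_zscores",
    "compare_bprime",
]


@dataclass
class FlexibilityProfile:
    """Per-residue scalar profile keyed by (chain_id, residue_number)."""

    values: dict[tuple[str, int], float]
    kind: str  # "rmsf" (Å) or "bprime" (dimensionless)
    source: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite profile values at {bad[:3]}")
        if self.kind == "rmsf" and any(v < 0 for v in self.values.values()):
            raise ValueError("RMSF values must be non-negative")

    def to_frame(self):
        import pandas as pd

        rows = [{"chain": c, "resnum": n, "value": v} for (c, n), v in sorted(self.values.items())]
        return pd.DataFrame(rows)


@dataclass
class PCAModes:
    mean: np.ndarray                 # (3a,) mean conformation of the selection
    eigenvalues: np.ndarray          # (n_modes,) Å², non-increasing
    eigenvectors: np.ndarray         # (n_modes, 3a) orthonormal rows
    explained: np.ndarray            # fractions of total coordinate variance
    keys: list[tuple[str, int]] = field(default_factory=list)


def _selection_keys(topology: StructureModel, selection: np.ndarray) -> list[tuple[str, int]]:
    flat = []
    for c in topology.chains:
        for r in c.residues:
            for _a in r.atoms:
                flat.append((c.chain_id, r.number))
    return [flat[i] for i in selection]


def rmsf(ensemble: Ensemble, selection: np.ndarray | None = None, source: str = "") -> FlexibilityProfile:
    """Root mean square fluctuation about the mean position, per selected atom.

    The ensemble must already be aligned to a common reference; RMSF_i =
    sqrt(<|x_i - <x_i>|^2>) with population averages over frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection is None:
        selection = ca_indices(ensemble.topology)
    selection = np.asarray(selection, int)
    X = ensemble.frames[:, selection, :]
    mean = X.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    keys = _selection_keys(ensemble.topology, selection)
    return FlexibilityProfile(values=dict(zip(keys, vals.tolist())), kind="rmsf", source=source)


def pca_modes(ensemble: Ensemble, selection: np.ndarray | None = None, n_modes: int = 5) -> PCAModes:
    """Principal components of the selected coordinates across frames.

    Eigendecomposition of the 3a x 3a population covariance of the
    flattened coordinates.  Sign convention: each mode's largest-magnitude
    component is positive.  Warns when F <= 3a (covariance rank-deficient).
    """
    if selection is None:
        selection = ca_indices(ensemble.topology)
    selection = np.asarray(selection, int)
    X = ensemble.frames[:, selection, :].reshape(ensemble.n_frames, -1)
    if X.shape[0] <= X.shape[1]:
        warnings.warn("fewer frames than coordinate dimensions: PCA covariance is rank-deficient")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("zero-variance ensemble")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    for v in evecs:
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    n_modes = min(n_modes, len(evals))
    return PCAModes(
        mean=mean,
        eigenvalues=evals[:n_modes],
        eigenvectors=evecs[:n_modes],
        explained=evals[:n_modes] / total_var,
        keys=_selection_keys(ensemble.topology, selection),
    )


def bprime_zscores(
    structure: StructureModel, chain: str, method: str = "robust_mad"
) -> FlexibilityProfile:
    """Normalized C-alpha B-factors (B') for one chain.

    classic_z: (B - mean)/sd with the sample standard deviation.
    robust_mad: (B - median)/(1.4826 * MAD).
    """
    ch = structure.chain(chain)
    keys, b = [], []
    for r in ch.residues:
        if r.hetero or r.is_water:
            continue
        try:
            a = r.atom("CA")
        except KeyError:
            continue
        keys.append((chain, r.number))
        b.append(a.b_factor)
    if len(b) < 2:
        raise ValueError(f"chain {chain}: fewer than 2 C-alpha B-factors")
    b = np.asarray(b, float)
    if method == "classic_z":
        scale = b.std(ddof=1)
        if scale == 0:
            raise ValueError("zero B-factor spread")
        z = (b - b.mean()) / scale
    elif method == "robust_mad":
        med = np.median(b)
        mad = np.median(np.abs(b - med))
        if mad == 0:
            raise ValueError("zero B-factor spread (MAD)")
        z = (b - med) / (1.4826 * mad)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FlexibilityProfile(values=dict(zip(keys, z.tolist())), kind="bprime",
                              source=f"{structure.id}:{chain}")


def compare_bprime(
    profile_a: FlexibilityProfile,
    profile_b: FlexibilityProfile,
    region: tuple[int, int] | None = None,
) -> dict:
    """Per-residue delta B' (b minus a) and an optional region summary.

    ``region`` is an inclusive residue-number range; the summary is the
    signed mean of delta B' over shared residues inside it.
    """
    shared = sorted(set(profile_a.values) & set(profile_b.values))
    if not shared:
        raise ValueError("profiles share no residues")
    delta = {k: profile_b.values[k] - profile_a.values[k] for k in shared}
    out = {"delta": delta}
    if region is not None:
        lo, hi = region
        sel = [v for (c, n), v in delta.items() if lo <= n <= hi]
        if not sel:
            raise ValueError(f"no shared residues in region {region}")
        out["region"] = region
        out["region_mean"] = float(np.mean(sel))
    return out
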