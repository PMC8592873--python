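"""Interface-mutation prioritization from stability-prediction tables.

Consumes externally produced per-mutation free-energy predictions (e.g.
PoPMuSiC folding ΔΔG_F for the monomer and the dimer, BeAtMuSiC binding
ΔΔG_B; positive = destabilizing) and applies the dimer-destabilization
screen:

1. the position must belong to the dimer interface set (from the SASA
   interface analysis),
2. ΔΔG_F(dimer) - ΔΔG_F(monomer) >= 2 kcal/mol (mutation hurts the dimer
   more than the monomer),
3. the replacement is not Gly/Pro/Cys (secondary-structure or disulfide
   liabilities),
4. the overall formal charge at pH 7 is preserved (His counted neutral),
5. ΔΔG_B >= 4 kcal/mol.

Every record is annotated with the first filter it fails; survivors are
ranked by ΔΔG_B descending.  The predicates are mutually independent, so
the surviving set does not depend on filter order — only the annotation
does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DdgRecord",
    "ScreenCriteria",
    "ScreenResult",
    "charge_delta",
    "screen_destabilizing",
    "read_ddg_table",
]

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")

#: formal side-chain charge at pH 7 (histidine neutral)
AA_CHARGE = {aa: 0 for aa in AA_CODES}
AA_CHARGE.update({"D": -1, "E": -1, "K": +1, "R": +1, "H": 0})

FILTER_ORDER = ("interface", "ddgf_gap", "aa_exclusion", "charge", "ddgb")


@dataclass(frozen=True)
class DdgRecord:
    """One candidate point mutation with predicted energies (kcal/mol)."""

    position: int
    wt_aa: str
    mut_aa: str
    ddg_f_monomer: float
    ddg_f_dimer: float
    ddg_b: float | None = None

    def __post_init__(self) -> None:
        for aa, what in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AA_CODES:
                raise ValueError(f"unknown amino acid code {aa!r} in {what}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"position {self.position}: wt and mutant are identical")
        for v, what in ((self.ddg_f_monomer, "ddg_f_monomer"), (self.ddg_f_dimer, "ddg_f_dimer")):
            if not np.isfinite(v):
                raise ValueError(f"non-finite {what} at position {self.position}")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def ddgf_gap(self) -> float:
        return self.ddg_f_dimer - self.ddg_f_monomer


@dataclass(frozen=True)
class ScreenCriteria:
    interface_positions: frozenset[int]
    ddgf_gap_min: float = 2.0           # kcal/mol
    ddgb_min: float = 4.0               # kcal/mol
    excluded_mutant_aas: frozenset[str] = frozenset({"G", "P", "C"})
    require_charge_preserving: bool = True

    def __post_init__(self) -> None:
        if self.ddgf_gap_min < 0 or self.ddgb_min < 0:
            raise ValueError("thresholds must be >= 0")
        object.__setattr__(self, "interface_positions", frozenset(self.interface_positions))
        object.__setattr__(self, "excluded_mutant_aas", frozenset(self.excluded_mutant_aas))


@dataclass
class ScreenResult:
    survivors: list[DdgRecord]                       # ranked by ddg_b descending
    ledger: list[tuple[DdgRecord, str | None]] = field(default_factory=list)

    @property
    def surviving_positions(self) -> set[int]:
        return {r.position for r in self.survivors}


def charge_delta(wt_aa: str, mut_aa: str) -> int:
    """Formal-charge change q(mut) - q(wt) at pH 7."""
    for aa in (wt_aa, mut_aa):
        if aa not in AA_CHARGE:
            raise ValueError(f"unknown amino acid code {aa!r}")
    return AA_CHARGE[mut_aa] - AA_CHARGE[wt_aa]


def _first_failure(rec: DdgRecord, criteria: ScreenCriteria) -> str | None:
    checks = {
        "interface": rec.position in criteria.interface_positions,
        "ddgf_gap": rec.ddgf_gap >= criteria.ddgf_gap_min,
        "aa_exclusion": rec.mut_aa not in criteria.excluded_mutant_aas,
        "charge": (not criteria.require_charge_preserving)
                  or charge_delta(rec.wt_aa, rec.mut_aa) == 0,
        "ddgb": rec.ddg_b is not None and np.isfinite(rec.ddg_b)
                and rec.ddg_b >= criteria.ddgb_min,
    }
    for name in FILTER_ORDER:
        if not checks[name]:
            return name
    return None


def screen_destabilizing(records: list[DdgRecord], criteria: ScreenCriteria) -> ScreenResult:
    """Apply the dimer-destabilization screen to a ΔΔG table.

    Returns survivors ranked by ΔΔG_B descending (ties by position then
    mutant residue) and a per-record ledger naming the first failed filter
    (None for survivors).
    """
    if not records:
        return ScreenResult(survivors=[], ledger=[])
    known = {r.position for r in records}
    orphans = criteria.interface_positions - known
    if orphans:
        warnings.warn(f"interface positions absent from the table: {sorted(orphans)}")
    ledger = [(rec, _first_failure(rec, criteria)) for rec in records]
    survivors = [rec for rec, fail in ledger if fail is None]
    survivors.sort(key=lambda r: (-(r.ddg_b if r.ddg_b is not None else -np.inf),
                                  r.position, r.mut_aa))
    return ScreenResult(survivors=survivors, ledger=ledger)


DEFAULT_COLUMNS = {
    "position": "position", "wt_aa": "wt_aa", "mut_aa": "mut_aa",
    "ddg_f_monomer": "ddg_f_monomer", "ddg_f_dimer": "ddg_f_dimer", "ddg_b": "ddg_b",
}


def read_ddg_table(source, column_map: dict[str, str] | None = None, sep=None) -> list[DdgRecord]:
    """Read a delimited ΔΔG table (CSV/TSV autodetected) into records.

    ``column_map`` maps canonical field names to the file's column names so
    prediction-server exports can be ingested without editing.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(source, sep=sep, engine="python")
    missing = [c for c in cols.values() if c != cols["ddg_b"] and c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        ddgb = row[cols["ddg_b"]] if cols["ddg_b"] in df.columns else None
        if ddgb is not None and not np.isfinite(ddgb):
            ddgb = None
        records.append(DdgRecord(
            position=int(row[cols["position"]]),
            wt_aa=str(row[cols["wt_aa"]]).strip().upper(),
            mut_aa=str(row[cols["mut_aa"]]).strip().upper(),
            ddg_f_monomer=float(row[cols["ddg_f_monomer"]]),
            ddg_f_dimer=float(row[cols["ddg_f_dimer"]]),
            ddg_b=None if ddgb is None else float(ddgb),
        ))
    return records


def write_ddg_table(records: list[DdgRecord], target) -> None:
    pd.DataFrame([{
        "position": r.position, "wt_aa": r.wt_aa, "mut_aa": r.mut_aa,
        "ddg_f_monomer": r.ddg_f_monomer, "ddg_f_dimer": r.ddg_f_dimer,
        "ddg_b": r.ddg_b,
    } for r in records]).to_csv(target, sep="\t", index=False)
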