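"""pH-dependent protonation: consensus pKa selection, protonation-state
assignment, net formal charge, and per-atom charge/radius maps.

Per-residue pKa values come from external predictors (consumed as tables,
one column per predictor). A residue's consensus pKa is accepted when at
least two predictors agree within a tolerance; the consensus value is the
mean of the largest mutually-agreeing predictor subset.

Protonation at pH `ph` with margin `m` (all comparisons inclusive):

    Asp/Glu   protonated (charge 0)  iff pKa >= ph - m, else charge -1
    His       protonated (charge +1) iff pKa >= ph - m, else charge 0
    Lys/Arg   charge +1 unless pKa < ph - m (then 0)
    Tyr/Cys   charge 0 unless pKa < ph - m (then -1)

i.e. every titratable site holds its proton when its pKa (less the margin)
is at or above the ambient pH — the majority species of the
Henderson-Hasselbalch equilibrium. The margin (default 0.1 pH units)
absorbs predictor noise near the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import IONIZABLE_RESIDUES, REPRESENTATIVE_ATOM, element_radius
from .structure_io import Structure

__all__ = [
    "ResidueKey",
    "PkaTable",
    "ConsensusPka",
    "ProtonationState",
    "ChargeRadiusAssignment",
    "consensus_pka",
    "assign_protonation",
    "net_charge",
    "assign_charges_radii",
    "read_pka_table",
    "write_pka_table",
]

ACIDIC = ("ASP", "GLU")
BASIC = ("LYS", "ARG")


class ResidueKey(NamedTuple):
    chain: str
    res_seq: int
    res_name: str


@dataclass
class PkaTable:
    """residue key -> {predictor name -> predicted pKa}."""
    entries: dict[ResidueKey, dict[str, float]]

    def __post_init__(self):
        for key, preds in self.entries.items():
            if key.res_name not in IONIZABLE_RESIDUES:
                raise ValueError(f"{key}: {key.res_name} is not an ionizable residue type")
            for name, v in preds.items():
                if not np.isfinite(v):
                    raise ValueError(f"{key}: predictor {name} has non-finite pKa")


@dataclass
class ConsensusEntry:
    value: float | None          # None = unresolved (no >=2-way agreement)
    supporting_methods: tuple[str, ...]

    @property
    def resolved(self) -> bool:
        return self.value is not None


@dataclass
class ConsensusPka:
    entries: dict[ResidueKey, ConsensusEntry]

    def unresolved(self) -> list[ResidueKey]:
        return [k for k, e in self.entries.items() if not e.resolved]

    def drop_unresolved(self) -> "ConsensusPka":
        return ConsensusPka({k: e for k, e in self.entries.items() if e.resolved})


@dataclass
class SiteState:
    protonated: bool
    side_chain_charge: int


@dataclass
class ProtonationState:
    ph: float
    entries: dict[ResidueKey, SiteState]


@dataclass
class ChargeRadiusAssignment:
    structure: Structure
    charges: np.ndarray  # e, per atom
    radii: np.ndarray    # Å, per atom
    param_set: str = "element-vdw"

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def consensus_pka(table: PkaTable, agreement_tol: float = 0.5) -> ConsensusPka:
    """Largest pairwise-agreeing predictor subset (>= 2 members) per residue.

    Ties between equal-size subsets go to the smaller internal spread, then
    to the subset containing the lexicographically first predictor name.
    """
    if agreement_tol <= 0:
        raise ValueError("agreement_tol must be > 0")
    out: dict[ResidueKey, ConsensusEntry] = {}
    for key, preds in table.entries.items():
        if len(preds) < 2:
            raise ValueError(f"{key}: needs >= 2 predictor values, has {len(preds)}")
        names = sorted(preds)
        best: tuple | None = None
        for size in range(len(names), 1, -1):
            for subset in combinations(names, size):
                vals = [preds[n] for n in subset]
                if max(vals) - min(vals) <= agreement_tol:
                    # rank: larger size, then smaller spread, then lexicographic
                    rank = (-size, max(vals) - min(vals), subset)
                    if best is None or rank < best[0]:
                        best = (rank, subset, float(np.mean(vals)))
            if best is not None:
                break  # subsets of this (maximal) size found; smaller are worse
        if best is None:
            out[key] = ConsensusEntry(None, ())
        else:
            out[key] = ConsensusEntry(best[2], best[1])
    return ConsensusPka(out)


def _site_state(res_name: str, pka: float, ph: float, margin: float) -> SiteState:
    holds_proton = pka >= ph - margin
    if res_name in ACIDIC:
        return SiteState(holds_proton, 0 if holds_proton else -1)
    if res_name == "HIS":
        return SiteState(holds_proton, +1 if holds_proton else 0)
    if res_name in BASIC:
        return SiteState(holds_proton, +1 if holds_proton else 0)
    if res_name in ("TYR", "CYS"):
        return SiteState(holds_proton, 0 if holds_proton else -1)
    raise ValueError(f"not an ionizable residue type: {res_name}")


def assign_protonation(c: ConsensusPka, ph: float, margin: float = 0.1) -> ProtonationState:
    """Protonation flags and formal side-chain charges at the target pH."""
    bad = c.unresolved()
    if bad:
        raise ValueError(f"unresolved consensus pKa for residues: {bad}")
    entries = {
        key: _site_state(key.res_name, e.value, ph, margin)
        for key, e in c.entries.items()
    }
    return ProtonationState(ph=ph, entries=entries)


def net_charge(state: ProtonationState, include_termini: bool = False) -> int:
    """Sum of formal side-chain charges; termini excluded by default."""
    q = sum(e.side_chain_charge for e in state.entries.values())
    if include_termini:
        q += 0  # +1 (N-term) - 1 (C-term) per chain cancels for free termini
    return int(q)


def assign_charges_radii(s: Structure, state: ProtonationState,
                         param_set: str = "element-vdw") -> ChargeRadiusAssignment:
    """Place each residue's formal charge on its representative side-chain atom.

    All other atoms carry zero charge; radii are element-based van der Waals
    values from the named parameter set.
    """
    if param_set != "element-vdw":
        raise ValueError(f"unknown parameter set {param_set!r}")
    charges = np.zeros(len(s))
    radii = np.array([element_radius(a.element) for a in s.atoms])
    # index atoms by (chain, res_seq, name)
    lookup = {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(s.atoms)}
    for key, site in state.entries.items():
        if key.res_name not in REPRESENTATIVE_ATOM:
            raise ValueError(f"unknown residue type in protonation state: {key.res_name}")
        if site.side_chain_charge == 0:
            continue
        rep = REPRESENTATIVE_ATOM[key.res_name]
        idx = lookup.get((key.chain, key.res_seq, rep))
        if idx is None:
            raise ValueError(
                f"residue {key.chain}:{key.res_seq}:{key.res_name} lacks its "
                f"representative atom {rep}"
            )
        charges[idx] += site.side_chain_charge
    return ChargeRadiusAssignment(s, charges, radii, param_set)


# ---------------------------------------------------------------------------
# table I/O: delimited text with columns chain, resseq, resname, <predictors...>

def read_pka_table(text_or_path) -> PkaTable:
    df = pd.read_csv(text_or_path, sep=r"\s+")
    required = {"chain", "resseq", "resname"}
    if not required.issubset(df.columns):
        raise ValueError(f"pKa table needs columns {sorted(required)}; got {list(df.columns)}")
    predictors = [c for c in df.columns if c not in required]
    entries = {}
    for _, row in df.iterrows():
        key = ResidueKey(str(row["chain"]), int(row["resseq"]), str(row["resname"]).upper())
        entries[key] = {p: float(row[p]) for p in predictors if pd.notna(row[p])}
    return PkaTable(entries)


def write_pka_table(table: PkaTable) -> str:
    predictors = sorted({p for preds in table.entries.values() for p in preds})
    rows = []
    for key, preds in table.entries.items():
        rows.append({"chain": key.chain, "resseq": key.res_seq, "resname": key.res_name,
                     **{p: preds.get(p, np.nan) for p in predictors}})
    df = pd.DataFrame(rows, columns=["chain", "resseq", "resname", *predictors])
    return df.to_csv(sep="\t", index=False)
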