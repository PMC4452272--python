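"""Roll per-subsystem residue energies up to per-ring quantities.

Per-ring contributions follow the ring-sum convention: for the lateral
interface class the ring total of any entity x (a residue, domain, subunit
role, or the whole subsystem) is the sum of its contributions over the 12
ordinary lateral subsystems plus the seam subsystem; for the longitudinal
class it is the sum over the 13 longitudinal subsystems,

    E_x(lateral)      = ϵ_x(R₁₃L′₁) + Σ_{k=1..12} ϵ_x(R_k L_{k+1})
    E_x(longitudinal) = Σ_{k=1..13} ϵ_x(R_k L′_k)

where primes denote periodic images.  Entities are keyed on
(role, subunit, res_num) — robust to templates whose subunits lack a few
residues — with the continuous subsystem index derivable from the ordering
Rα, Rβ, Lα, Lβ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energy import COMPONENTS, EnergyComponents, PerResidueEnergyTable

__all__ = [
    "DomainMap",
    "RingEnergyTable",
    "SubunitMatrix",
    "RingDiagram",
    "ring_aggregate",
    "subunit_matrix",
    "model_difference",
    "ring_diagram",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------


@dataclass
class DomainMap:
    """Mapping (subunit, residue-number ranges) → domain label.

    ``ranges`` maps subunit → list of (label, lo, hi) inclusive residue-number
    ranges; ``special_res_names`` maps residue names (e.g. cofactors 'GTP',
    'GDP', 'MG') directly to domain labels, taking precedence over ranges.
    Ranges must not overlap within a subunit; unmapped residues fall into the
    reserved 'unassigned' domain so that domain sums always conserve the
    total.
    """

    ranges: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    special_res_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subunit, rng in self.ranges.items():
            spans = sorted((lo, hi, lab) for lab, lo, hi in rng)
            for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"overlapping domain ranges in {subunit}: "
                        f"{l1}({lo1}-{hi1}) and {l2}({lo2}-{hi2})"
                    )

    def domain_of(self, subunit: str, res_num: int, res_name: str = "") -> str:
        if res_name and res_name in self.special_res_names:
            return self.special_res_names[res_name]
        for label, lo, hi in self.ranges.get(subunit, []):
            if lo <= res_num <= hi:
                return label
        return UNASSIGNED

    @classmethod
    def from_dict(cls, data: Mapping) -> "DomainMap":
        ranges: dict[str, list[tuple[str, int, int]]] = {}
        for subunit, doms in data.get("ranges", {}).items():
            out: list[tuple[str, int, int]] = []
            for label, spans in doms.items():
                for span in spans:
                    lo, hi = int(span[0]), int(span[1])
                    out.append((label, lo, hi))
            ranges[subunit] = out
        return cls(
            ranges=ranges,
            special_res_names=dict(data.get("special_res_names", {})),
        )

    @classmethod
    def default(cls) -> "DomainMap":
        """The bundled tubulin secondary-structure domain map."""
        from .io import load_default_domain_map

        return load_default_domain_map()


# ---------------------------------------------------------------------------
# Ring aggregation
# ---------------------------------------------------------------------------

RING_COLS = list(COMPONENTS) + ["E_total"]


@dataclass
class RingEnergyTable:
    """Per-ring energies of one interface class (lateral incl. seam, or
    longitudinal).

    ``per_residue`` is indexed by (role, subunit, res_num) with component
    columns summed over all subsystems of the class; ``per_subsystem`` holds
    each subsystem's totals (one row per subsystem, seam labeled 'seam');
    ``sd`` optionally carries per-residue SDs propagated from per-subsystem
    ensemble SDs in quadrature.
    """

    per_residue: pd.DataFrame
    per_subsystem: pd.DataFrame
    kind: str
    domain_map: DomainMap | None = None
    sd: pd.DataFrame | None = None

    def totals(self) -> EnergyComponents:
        return EnergyComponents(
            *(float(self.per_residue[c].sum()) for c in COMPONENTS)
        )

    @property
    def total(self) -> float:
        return self.totals().E_total

    # -- entity roll-ups ---------------------------------------------------

    def by_role_subunit(self) -> pd.DataFrame:
        """Sum over residues into the four (role, subunit) cells."""
        return (
            self.per_residue[RING_COLS]
            .groupby(level=["role", "subunit"], sort=False)
            .sum()
        )

    def by_domain(self) -> pd.DataFrame:
        """Sum per (role, subunit, domain); requires a domain map."""
        if self.domain_map is None:
            raise ValueError("no DomainMap attached to this ring table")
        idx = self.per_residue.index
        domains = [
            self.domain_map.domain_of(
                subunit, res_num, str(self.per_residue["res_name"].iloc[i])
            )
            for i, (role, subunit, res_num) in enumerate(idx)
        ]
        df = self.per_residue[RING_COLS].reset_index()
        df["domain"] = domains
        return df.groupby(["role", "subunit", "domain"], sort=False)[
            RING_COLS
        ].sum()

    def select(self, role=None, subunit=None, res_num=None) -> pd.DataFrame:
        """Residue rows matching the given entity selector."""
        df = self.per_residue
        mask = np.ones(len(df), dtype=bool)
        if role is not None:
            mask &= df.index.get_level_values("role") == role
        if subunit is not None:
            mask &= df.index.get_level_values("subunit") == subunit
        if res_num is not None:
            mask &= df.index.get_level_values("res_num") == res_num
        out = df[mask]
        if out.empty:
            raise KeyError(
                f"selector matched no residues: role={role} subunit={subunit} "
                f"res_num={res_num}"
            )
        return out


def ring_aggregate(
    tables: Sequence[PerResidueEnergyTable],
    kind: str,
    domain_map: DomainMap | None = None,
    n_pf: int = 13,
) -> RingEnergyTable:
    """Sum per-subsystem residue tables into one per-ring table.

    ``tables`` must contain exactly n_pf subsystems of the stated class; for
    'lateral' the seam subsystem counts as the n_pf-th lateral element, so a
    lateral ring table built with or without explicit seam labeling is
    identical as long as the seam table is supplied.
    """
    if len(tables) != n_pf:
        raise ValueError(
            f"{kind} ring aggregation needs {n_pf} subsystem tables, "
            f"got {len(tables)}"
        )
    frames = []
    sub_rows = []
    for t in tables:
        frames.append(t.df[RING_COLS])
        sub_rows.append(
            {"subsystem": t.subsystem or f"{kind}_{len(sub_rows) + 1:02d}"}
            | t.totals().as_dict()
        )
    summed = (
        pd.concat(frames)
        .groupby(level=["role", "subunit", "res_num"], sort=False)[RING_COLS]
        .sum()
    )
    # carry residue names from the first table that has each key
    names = pd.concat([t.df["res_name"] for t in tables])
    names = names[~names.index.duplicated(keep="first")]
    summed.insert(0, "res_name", names.reindex(summed.index))
    per_subsystem = pd.DataFrame(sub_rows).set_index("subsystem")
    return RingEnergyTable(
        per_residue=summed,
        per_subsystem=per_subsystem,
        kind=kind,
        domain_map=domain_map,
    )


# ---------------------------------------------------------------------------
# Subunit matrix
# ---------------------------------------------------------------------------


@dataclass
class SubunitMatrix:
    """2×2 subunit/role contribution matrix with margins (kcal/mol per ring).

    Rows are subunits (beta, alpha), columns roles (L, R); 'Lβ' is the
    contribution of the β subunit of the dimer acting as ligand.  Margins are
    exact sums of their cells and the grand margin equals the per-ring total.
    """

    cells: pd.DataFrame  # index: beta, alpha; columns: L, R
    sd: pd.DataFrame | None = None

    @classmethod
    def from_cells(
        cls,
        L_beta: float,
        R_beta: float,
        L_alpha: float,
        R_alpha: float,
        sd: Mapping[str, float] | None = None,
    ) -> "SubunitMatrix":
        cells = pd.DataFrame(
            [[L_beta, R_beta], [L_alpha, R_alpha]],
            index=["beta", "alpha"],
            columns=["L", "R"],
            dtype=float,
        )
        sd_df = None
        if sd is not None:
            sd_df = pd.DataFrame(
                [[sd["L_beta"], sd["R_beta"]], [sd["L_alpha"], sd["R_alpha"]]],
                index=["beta", "alpha"],
                columns=["L", "R"],
                dtype=float,
            )
        return cls(cells=cells, sd=sd_df)

    @property
    def row_margins(self) -> pd.Series:
        """Per-subunit totals (L+R)."""
        return self.cells.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        """Per-role totals (β+α)."""
        return self.cells.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.cells.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["Tot"] = self.row_margins
        out.loc["Tot"] = out.sum(axis=0)
        return out


def subunit_matrix(ring_table: RingEnergyTable, component: str = "E_total") -> SubunitMatrix:
    """Collapse a ring table into the 2×2 subunit/role matrix."""
    grouped = ring_table.by_role_subunit()[component]
    cells = pd.DataFrame(
        0.0, index=["beta", "alpha"], columns=["L", "R"], dtype=float
    )
    for (role, subunit), value in grouped.items():
        if role not in ("L", "R") or subunit not in ("alpha", "beta"):
            raise KeyError(f"unexpected role/subunit labels: {(role, subunit)}")
        cells.loc[subunit, role] = float(value)
    return SubunitMatrix(cells=cells)


# ---------------------------------------------------------------------------
# Model differences
# ---------------------------------------------------------------------------


def model_difference(
    table_a: pd.DataFrame | RingEnergyTable,
    table_b: pd.DataFrame | RingEnergyTable,
    fill: float = 0.0,
) -> pd.DataFrame:
    """Per-entity ΔE = E_A − E_B (A = GTP model by convention).

    Entity sets are outer-joined; entities present in only one table are
    zero-filled and flagged in the boolean columns ``only_in_a``/``only_in_b``.
    Raises if the entity sets are entirely disjoint.
    """
    a = table_a.per_residue if isinstance(table_a, RingEnergyTable) else table_a
    b = table_b.per_residue if isinstance(table_b, RingEnergyTable) else table_b
    cols = [c for c in RING_COLS if c in a.columns and c in b.columns]
    if not cols:
        cols = [c for c in a.columns if c in b.columns and a[c].dtype.kind == "f"]
    if a.index.intersection(b.index).empty:
        raise ValueError("entity sets are entirely disjoint")
    union = a.index.union(b.index, sort=False)
    av = a[cols].reindex(union, fill_value=fill)
    bv = b[cols].reindex(union, fill_value=fill)
    out = av - bv
    out["only_in_a"] = ~union.isin(b.index)
    out["only_in_b"] = ~union.isin(a.index)
    return out


# ---------------------------------------------------------------------------
# Ring energy diagram
# ---------------------------------------------------------------------------


@dataclass
class RingDiagram:
    """Ordered interface energies around the ring with the seam flagged.

    ``weakest`` is the set of labels sharing the minimum |E| (a singleton
    unless tied); the weakest interface is the natural candidate trigger
    point for ring opening and disassembly.
    """

    energies: pd.Series  # index: interface labels, ordered around the ring
    seam_label: str | None
    weakest: frozenset[str]

    @property
    def weakest_energy(self) -> float:
        return float(self.energies[sorted(self.weakest)[0]])

    @property
    def seam_is_weakest(self) -> bool:
        return self.seam_label is not None and self.seam_label in self.weakest


def ring_diagram(
    totals: Mapping[str, float] | pd.Series,
    seam_label: str | None = "seam",
    n_pf: int = 13,
) -> RingDiagram:
    """Build the ring energy diagram from 13 per-interface totals."""
    s = pd.Series(totals, dtype=float)
    if len(s) != n_pf:
        raise ValueError(f"expected {n_pf} interface totals, got {len(s)}")
    mags = s.abs()
    weakest = frozenset(s.index[mags == mags.min()])
    seam = seam_label if seam_label in s.index else None
    return RingDiagram(energies=s, seam_label=seam, weakest=weakest)
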