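"""Worked examples on the bundled published ring energetics.

Desk-scale reproduction of the published per-ring arithmetic: the bundled
reference values (subunit/role matrices, component groupings, profile splits
for the GDP- and GTP-state 13-protofilament ring models) are fed through this
package's aggregation, difference, ring-diagram and profile-split machinery,
and the derived totals, margins, fractions and differences are returned as
computed numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import SubunitMatrix, model_difference, ring_diagram
from .energy import COMPONENTS
from .io import load_reference_energetics
from .lattice import LatticeSpec
from .profiles import Profile, inner_outer_split

__all__ = ["worked_examples", "lattice_constants"]


def _cells_frame(cells: dict[str, float]) -> pd.DataFrame:
    """Subunit/role cells as a per-entity frame usable by model_difference."""
    idx = pd.MultiIndex.from_tuples(
        [tuple(k.split("_")) + (0,) for k in cells],
        names=("role", "subunit", "res_num"),
    )
    return pd.DataFrame({"E_total": list(cells.values())}, index=idx)


def _two_bin_profile(inner: float, outer: float, x_com: float = 30.0) -> Profile:
    df = pd.DataFrame(
        {"bin_lower": [x_com - 3.0, x_com], "bin_upper": [x_com, x_com + 3.0]}
    )
    for c in COMPONENTS:
        df[c] = 0.0
    df["E_total"] = [inner, outer]
    return Profile(df=df, coordinate="radial", x_com=x_com)


def worked_examples() -> dict[str, float]:
    """Recompute the published per-ring arithmetic; returns computed values."""
    ref = load_reference_energetics()
    out: dict[str, float] = {}

    matrices: dict[tuple[str, str], SubunitMatrix] = {}
    for kind in ("lateral", "longitudinal"):
        for model in ("GDP", "GTP"):
            cells = ref["subunit_matrix"][kind][model]["cells"]
            m = SubunitMatrix.from_cells(**cells)
            matrices[(kind, model)] = m
            out[f"{kind}_ring_total_{model.lower()}"] = m.grand_total

    # model differences (GTP − GDP) through the difference machinery
    for kind in ("lateral", "longitudinal"):
        a = _cells_frame(ref["subunit_matrix"][kind]["GTP"]["cells"])
        b = _cells_frame(ref["subunit_matrix"][kind]["GDP"]["cells"])
        d = model_difference(a, b)
        out[f"{kind}_gtp_minus_gdp"] = float(d["E_total"].sum())

    # curl-opposing lateral pull: both neighbors act, 2 × E_tot_lat
    out["doubled_lateral_gdp"] = 2 * out["lateral_ring_total_gdp"]
    out["doubled_lateral_gtp"] = 2 * out["lateral_ring_total_gtp"]

    # subunit shares of the lateral total
    for model in ("GDP", "GTP"):
        m = matrices[("lateral", model)]
        g = m.grand_total
        out[f"lateral_alpha_share_pct_{model.lower()}"] = (
            100.0 * m.row_margins["alpha"] / g
        )
        out[f"lateral_receptor_share_pct_{model.lower()}"] = (
            100.0 * m.col_margins["R"] / g
        )
        la_rb = float(m.cells.loc["alpha", "L"] + m.cells.loc["beta", "R"])
        out[f"lateral_la_rb_sum_{model.lower()}"] = la_rb
        out[f"lateral_la_rb_share_pct_{model.lower()}"] = 100.0 * la_rb / g
    m_long = matrices[("longitudinal", "GDP")]
    out["longitudinal_lbeta_share_pct_gdp"] = (
        100.0 * float(m_long.cells.loc["beta", "L"]) / m_long.grand_total
    )

    # component-grouping consistency: E(vdW+SA) + E(ele+GB) = ring total
    for kind in ("lateral", "longitudinal"):
        for model, comps in ref["components"][kind].items():
            out[f"{kind}_component_sum_{model.lower()}"] = (
                comps["vdw_sa"] + comps["ele_gb"]
            )

    # ring energy diagram: seam −9 and the printed neighbor −57; the other
    # 11 interfaces share the remainder of the printed ring total uniformly
    seam = ref["lateral_interfaces"]["GDP"]["seam"]["energy"]
    strong = ref["lateral_interfaces"]["GDP"]["lateral_12"]["energy"]
    rest = (out["lateral_ring_total_gdp"] - seam - strong) / 11.0
    totals = {f"lateral_{k:02d}": rest for k in range(1, 12)}
    totals["lateral_12"] = strong
    totals["seam"] = seam
    diagram = ring_diagram(totals)
    out["seam_weakest_interface_energy_gdp"] = diagram.weakest_energy
    out["seam_is_weakest_gdp"] = float(diagram.seam_is_weakest)

    # radial outward and tangential right-side splits
    for model in ("GDP", "GTP"):
        total = out[f"longitudinal_ring_total_{model.lower()}"]
        outer = ref["radial_outward"][model]
        p = _two_bin_profile(total - outer, outer)
        _, outer_sum, frac = inner_outer_split(p)
        out[f"radial_outward_sum_{model.lower()}"] = outer_sum
        out[f"radial_outward_fraction_pct_{model.lower()}"] = 100.0 * frac
        right = ref["tangential_right"][model]
        p = _two_bin_profile(total - right, right)
        _, right_sum, frac = inner_outer_split(p)
        out[f"tangential_right_sum_{model.lower()}"] = right_sum
        out[f"tangential_right_fraction_pct_{model.lower()}"] = 100.0 * frac

    # exchangeable-site swap: cofactor change plus the Mg²⁺ destabilization
    out["esite_swap_net_gtp_minus_gdp"] = (
        ref["esite"]["cofactor_gtp_minus_gdp"]["energy"]
        + ref["esite"]["mg_destabilization"]["energy"]
    )
    out["mg_destabilization"] = ref["esite"]["mg_destabilization"]["energy"]
    return out


def lattice_constants() -> dict[str, float]:
    """Geometry of the canonical 13_3 lattice, computed from the spec."""
    gdp = LatticeSpec(nucleotide_state="GDP")
    gtp = LatticeSpec(nucleotide_state="GTP")
    return {
        "axial_repeat_gdp": gdp.dimer_repeat_c,
        "axial_repeat_gtp": gtp.dimer_repeat_c,
        "lateral_twist_deg": float(np.degrees(gdp.lateral_twist)),
        "lateral_rise_per_step_gdp": gdp.lateral_rise,
        "seam_axial_offset_gdp": gdp.seam_offset,
        "helix_rise_per_turn_gdp": gdp.lateral_rise * gdp.n_pf,
    }
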