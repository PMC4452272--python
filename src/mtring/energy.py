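"""MM/GBSA-style interaction energies with per-residue decomposition.

The interaction energy between two dimers (receptor R and ligand L) is
evaluated under the single-trajectory convention: the complex and the two
isolated partners are scored on identical coordinates, so internal bonded and
intramolecular terms cancel and the interaction energy is

    ΔE = E(complex) − E(R) − E(L)
       = ΔE_vdW + ΔE_ele + ΔE_GB + ΔE_SA        (kcal/mol)

* ΔE_vdW, ΔE_ele — exactly the cross-molecular 12-6 Lennard-Jones and Coulomb
  pair sums (solute dielectric ε_in), half-assigned to each pair partner, so
  the receptor and ligand shares of these components are symmetric.
* ΔE_GB — generalized-Born polar solvation difference.  Burial in the complex
  grows the effective Born radii, so the per-atom GB self and cross terms
  change between complex and isolated states; this is the only route (with
  ΔE_SA) by which receptor and ligand totals can differ.
* ΔE_SA — non-polar solvation, γ·SASA + β, from the buried solvent-accessible
  surface area.

GB flavor is OBC-II (tanh-rescaled pairwise descreening, α=1.0, β=0.8,
γ=4.85, intrinsic-radius offset 0.09 Å) with the Still pairwise function
f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))).  SASA is Shrake–Rupley on a
deterministic golden-spiral point set.  No pair cutoff is applied: subsystems
are small after dimer extraction, and a cutoff would only add a tolerance
knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lattice import Atoms, Subsystem

__all__ = [
    "K_COULOMB",
    "EnergyComponents",
    "PerResidueEnergyTable",
    "EnsembleTable",
    "coulomb_pair",
    "lj_pair",
    "born_radii",
    "gb_energy",
    "sasa",
    "nonpolar_energy",
    "interaction_energy",
    "ensemble_average",
]

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻².
K_COULOMB = 332.0636

#: OBC-II parameters.
GB_OFFSET = 0.09  # Å subtracted from intrinsic radii
OBC_ALPHA = 1.0
OBC_BETA = 0.8
OBC_GAMMA = 4.85

#: Non-polar surface-tension defaults.
SA_GAMMA = 0.0072  # kcal·mol⁻¹·Å⁻²
SA_BETA = 0.0
PROBE_RADIUS = 1.4  # Å, water probe

COMPONENTS = ("E_vdW", "E_ele", "E_GB", "E_SA")


class SingularityError(ZeroDivisionError):
    """Raised when a pair distance is zero in a pairwise energy term."""


class ParameterizationError(KeyError):
    """Raised when atoms lack force-field parameters."""


# ---------------------------------------------------------------------------
# Energy components record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyComponents:
    """The four MM/GBSA components plus the conventional groupings."""

    E_vdW: float
    E_ele: float
    E_GB: float
    E_SA: float

    @property
    def E_vdW_SA(self) -> float:
        return self.E_vdW + self.E_SA

    @property
    def E_ele_GB(self) -> float:
        return self.E_ele + self.E_GB

    @property
    def E_total(self) -> float:
        return self.E_vdW + self.E_ele + self.E_GB + self.E_SA

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["E_total"] = self.E_total
        return d


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------


def coulomb_pair(q_i: float, q_j: float, r_ij: float, eps_in: float = 1.0) -> float:
    """Coulomb energy of one charge pair in a medium of dielectric eps_in."""
    if r_ij <= 0:
        raise SingularityError("coulomb_pair: r_ij must be > 0")
    return K_COULOMB * q_i * q_j / (eps_in * r_ij)


def lj_pair(
    rmin2_i: float, eps_i: float, rmin2_j: float, eps_j: float, r_ij: float
) -> float:
    """12-6 Lennard-Jones pair energy.

    Combination rules: r_min,ij = r_min,i/2 + r_min,j/2 (half-radii summed),
    ε_ij = sqrt(ε_i ε_j).  The minimum value −ε_ij occurs at r = r_min,ij.
    """
    if r_ij <= 0:
        raise SingularityError("lj_pair: r_ij must be > 0")
    rmin = rmin2_i + rmin2_j
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (rmin / r_ij) ** 6
    return eps * (sr6 * sr6 - 2.0 * sr6)


def _cross_pair_matrices(
    rec: Atoms, lig: Atoms, eps_in: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_rec, n_lig) matrices of LJ and Coulomb cross-pair energies."""
    diff = rec.coords[:, None, :] - lig.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    if np.any(r <= 0):
        raise SingularityError("overlapping atoms between receptor and ligand")
    rmin = rec.rmin2[:, None] + lig.rmin2[None, :]
    eps = np.sqrt(rec.epsilon[:, None] * lig.epsilon[None, :])
    sr6 = (rmin / r) ** 6
    e_vdw = eps * (sr6 * sr6 - 2.0 * sr6)
    e_ele = K_COULOMB * rec.charge[:, None] * lig.charge[None, :] / (eps_in * r)
    return e_vdw, e_ele


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------


def _hct_integral(r: np.ndarray, s: np.ndarray, rho_i: np.ndarray) -> np.ndarray:
    """Pairwise descreening integral H(r_ij, s_j; ρ_i).

    Closed form of the Coulomb-field integral (1/4π)∫ dV/x⁴ of atom i over the
    scaled sphere s_j of atom j, excluding the interior of ρ_i.  All inputs
    broadcast; entries with ρ_i ≥ r + s (neighbor fully engulfed) contribute 0.
    """
    U = r + s
    L = np.maximum(np.abs(r - s), rho_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = 0.5 * (
            1.0 / L
            - 1.0 / U
            + 0.25 * (r - s**2 / r) * (1.0 / U**2 - 1.0 / L**2)
            + 0.5 / r * np.log(L / U)
        )
        # atom i's reduced sphere entirely inside neighbor's scaled sphere
        inside = rho_i < (s - r)
        H = np.where(inside, H + (1.0 / rho_i - 1.0 / L), H)
    return np.where(rho_i >= U, 0.0, H)


def born_radii(
    atoms: Atoms,
    offset: float = GB_OFFSET,
    alpha: float = OBC_ALPHA,
    beta: float = OBC_BETA,
    gamma: float = OBC_GAMMA,
) -> np.ndarray:
    """Effective Born radii by the OBC-II recipe.

    For an isolated atom the effective radius equals the reduced intrinsic
    radius ρ = R − offset; descreening by neighbors grows it toward the
    molecular scale, saturating via the tanh rescaling at the intrinsic
    radius' inverse.
    """
    R = atoms.gb_radius
    if np.any(R <= 0):
        raise ParameterizationError("all intrinsic GB radii must be > 0")
    rho = R - offset
    if np.any(rho <= 0):
        raise ParameterizationError("intrinsic GB radius <= offset")
    n = len(atoms)
    if n == 1:
        return rho.copy()
    diff = atoms.coords[:, None, :] - atoms.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(r[off_diag] <= 1e-10):
        raise SingularityError("coincident atoms in Born-radius descreening")
    s = (atoms.gb_screen * rho)[None, :]  # scaled neighbor radii, per column j
    H = _hct_integral(r, s, rho[:, None])
    np.fill_diagonal(H, 0.0)
    I = H.sum(axis=1)
    psi = I * rho
    inv_B = 1.0 / rho - np.tanh(alpha * psi - beta * psi**2 + gamma * psi**3) / R
    return 1.0 / inv_B


def gb_energy(
    atoms: Atoms,
    radii: np.ndarray | None = None,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
) -> tuple[float, np.ndarray]:
    """GB polar solvation energy and its per-atom shares.

    E = −(1/2)(1/ε_in − 1/ε_out) k_e Σ_ij q_i q_j / f_GB(r_ij, B_i, B_j)
    with f_GB = sqrt(r² + B_i B_j exp(−r²/(4 B_i B_j))); the i=j self terms
    use f_GB(0) = B_i.  Each atom's share is its full self term plus half of
    every pair term it participates in, so shares sum to the total.
    """
    if eps_in <= 0 or eps_out <= 0:
        raise ValueError("dielectric constants must be positive")
    if radii is None:
        radii = born_radii(atoms)
    B = np.asarray(radii, dtype=float)
    q = atoms.charge
    diff = atoms.coords[:, None, :] - atoms.coords[None, :, :]
    r2 = (diff**2).sum(axis=-1)
    BB = B[:, None] * B[None, :]
    f = np.sqrt(r2 + BB * np.exp(-r2 / (4.0 * BB)))
    pref = -0.5 * (1.0 / eps_in - 1.0 / eps_out) * K_COULOMB
    pair = pref * q[:, None] * q[None, :] / f
    # ordered double sum: row i already carries atom i's self term plus half
    # of each unordered pair (the other half lives in the partner's row)
    per_atom = pair.sum(axis=1)
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Orient coordinates by principal axes with deterministic signs.

    The Shrake–Rupley point set is fixed in space, so raw areas would change
    slightly under rotation of the molecule; evaluating in a canonical frame
    makes SASA an exact function of internal geometry and hence the whole
    interaction energy exactly invariant under rigid motion.
    """
    c = coords - coords.mean(axis=0)
    if len(c) < 2:
        return c
    cov = c.T @ c
    _, vecs = np.linalg.eigh(cov)
    for j in range(3):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return c @ vecs


def sasa(
    atoms: Atoms,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Ų), Shrake–Rupley.

    ``radii`` defaults to the intrinsic GB radii (the parameter table's
    per-atom size); each atom's accessible sphere has radius R_i + probe.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    R = atoms.gb_radius if radii is None else np.asarray(radii, dtype=float)
    if np.any(R <= 0):
        raise ParameterizationError("all atomic radii must be > 0 for SASA")
    n = len(atoms)
    pts = sphere_points(n_points)
    ext = R + probe_radius
    areas = np.empty(n)
    coords = _canonical_frame(atoms.coords)
    for i in range(n):
        shell = coords[i] + ext[i] * pts
        # neighbors whose accessible spheres can clip atom i's shell
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        nb = (d < ext + ext[i]) & (np.arange(n) != i)
        if not np.any(nb):
            exposed = n_points
        else:
            nb_xyz = coords[nb]
            nb_r2 = ext[nb] ** 2
            d2 = ((shell[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < nb_r2[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * exposed / n_points
    return areas


def nonpolar_energy(
    areas: np.ndarray, gamma: float = SA_GAMMA, beta: float = SA_BETA
) -> float:
    """Non-polar solvation energy γ·ΣSASA + β (kcal/mol)."""
    return gamma * float(np.sum(areas)) + beta


# ---------------------------------------------------------------------------
# Per-residue tables
# ---------------------------------------------------------------------------

TABLE_INDEX = ("role", "subunit", "res_num")


@dataclass
class PerResidueEnergyTable:
    """Interaction-energy contributions decomposed per residue.

    ``df`` is indexed by (role, subunit, res_num) with columns ``index``
    (continuous 1..N subsystem numbering: Rα, Rβ, Lα, Lβ), ``res_name`` and
    the four components plus E_total.  Residue contributions sum to the
    subsystem totals for every component by construction.
    """

    df: pd.DataFrame
    subsystem: str = ""
    kind: str = ""
    frame: int | str = 0
    meta: dict = field(default_factory=dict)

    def totals(self) -> EnergyComponents:
        return EnergyComponents(*(float(self.df[c].sum()) for c in COMPONENTS))

    @property
    def total(self) -> float:
        return self.totals().E_total

    def component_frame(self) -> pd.DataFrame:
        return self.df[list(COMPONENTS) + ["E_total"]]

    def scaled(self, factor: float) -> "PerResidueEnergyTable":
        out = self.df.copy()
        for c in COMPONENTS + ("E_total",):
            out[c] = out[c] * factor
        return PerResidueEnergyTable(
            out, self.subsystem, self.kind, self.frame, dict(self.meta)
        )


def _make_table_df(
    keys: Sequence[tuple[str, str, int]],
    res_names: Sequence[str],
    comp: dict[str, np.ndarray],
) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(keys, names=TABLE_INDEX)
    df = pd.DataFrame(index=idx)
    df["index"] = np.arange(1, len(keys) + 1)
    df["res_name"] = list(res_names)
    for c in COMPONENTS:
        df[c] = comp[c]
    df["E_total"] = sum(df[c] for c in COMPONENTS)
    return df


# ---------------------------------------------------------------------------
# Interaction energy
# ---------------------------------------------------------------------------


def _check_parameterized(atoms: Atoms, label: str) -> None:
    bad = np.flatnonzero(~np.isfinite(atoms.charge) | (atoms.gb_radius <= 0))
    if bad.size:
        names = [
            f"{atoms.res_name[i]}/{atoms.atom_name[i]}" for i in bad[:10]
        ]
        raise ParameterizationError(
            f"{label}: missing/invalid parameters for atoms {names}"
        )


def interaction_energy(
    sub: Subsystem,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    sa_gamma: float = SA_GAMMA,
    sa_beta: float = SA_BETA,
    probe_radius: float = PROBE_RADIUS,
    sasa_points: int = 240,
) -> PerResidueEnergyTable:
    """Score one subsystem; return the per-residue interaction table.

    vdW and electrostatic contributions are the cross-molecular pair sums,
    half-assigned to each partner atom.  GB and SA contributions are per-atom
    complex-minus-isolated differences, so solvation may redistribute energy
    between receptor and ligand while the pairwise terms stay symmetric.
    """
    rec, lig = sub.receptor, sub.ligand
    _check_parameterized(rec, "receptor")
    _check_parameterized(lig, "ligand")

    e_vdw_m, e_ele_m = _cross_pair_matrices(rec, lig, eps_in)
    vdw_rec, vdw_lig = 0.5 * e_vdw_m.sum(axis=1), 0.5 * e_vdw_m.sum(axis=0)
    ele_rec, ele_lig = 0.5 * e_ele_m.sum(axis=1), 0.5 * e_ele_m.sum(axis=0)

    complex_atoms, roles = sub.all_atoms()
    nr = len(rec)

    # GB: per-atom shares, complex minus isolated
    _, gb_cplx = gb_energy(complex_atoms, eps_in=eps_in, eps_out=eps_out)
    _, gb_rec = gb_energy(rec, eps_in=eps_in, eps_out=eps_out)
    _, gb_lig = gb_energy(lig, eps_in=eps_in, eps_out=eps_out)
    gb_delta = gb_cplx - np.concatenate([gb_rec, gb_lig])

    # SA: per-atom buried area, complex minus isolated
    if sa_gamma != 0.0 or sa_beta != 0.0:
        sa_cplx = sasa(complex_atoms, probe_radius, sasa_points)
        sa_rec = sasa(rec, probe_radius, sasa_points)
        sa_lig = sasa(lig, probe_radius, sasa_points)
        sa_delta = sa_gamma * (sa_cplx - np.concatenate([sa_rec, sa_lig]))
        # β offset (complex minus two partners) assigned uniformly
        sa_delta += -sa_beta / len(complex_atoms)
    else:
        sa_delta = np.zeros(len(complex_atoms))

    per_atom = {
        "E_vdW": np.concatenate([vdw_rec, vdw_lig]),
        "E_ele": np.concatenate([ele_rec, ele_lig]),
        "E_GB": gb_delta,
        "E_SA": sa_delta,
    }

    keys = sub.residue_keys()
    res_names: list[str] = []
    comp = {c: np.zeros(len(keys)) for c in COMPONENTS}
    # map atoms to residue rows
    key_pos = {key: i for i, key in enumerate(keys)}
    atom_rows = np.empty(len(complex_atoms), dtype=int)
    for a in range(len(complex_atoms)):
        role = "R" if a < nr else "L"
        key = (
            role,
            str(complex_atoms.subunit[a]),
            int(complex_atoms.res_num[a]),
        )
        atom_rows[a] = key_pos[key]
    for c in COMPONENTS:
        np.add.at(comp[c], atom_rows, per_atom[c])
    for key in keys:
        role, subunit, res_num = key
        atoms = sub.role_atoms(role)
        m = (atoms.subunit == subunit) & (atoms.res_num == res_num)
        res_names.append(str(atoms.res_name[m][0]))

    df = _make_table_df(keys, res_names, comp)
    return PerResidueEnergyTable(
        df=df,
        subsystem=sub.label,
        kind=sub.kind,
        meta={
            "eps_in": eps_in,
            "eps_out": eps_out,
            "sa_gamma": sa_gamma,
            "sa_beta": sa_beta,
        },
    )


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class EnsembleTable:
    """Per-residue mean ± SD over trajectory frames.

    ``mean`` and ``sd`` are aligned per-residue frames; ``total_mean`` and
    ``total_sd`` are computed from the per-frame subsystem totals (not from
    summed per-residue SDs).  SDs are population SDs (ddof=0) over frames.
    """

    mean: PerResidueEnergyTable
    sd: pd.DataFrame
    total_mean: EnergyComponents
    total_sd: EnergyComponents
    grand_total_mean: float
    grand_total_sd: float
    n_frames: int


def ensemble_average(tables: Iterable[PerResidueEnergyTable]) -> EnsembleTable:
    """Average per-frame tables into mean ± SD (population SD over frames)."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("ensemble_average requires at least 2 frames")
    ref_idx = tables[0].df.index
    for t in tables[1:]:
        if not t.df.index.equals(ref_idx):
            raise ValueError("inconsistent residue sets across frames")
    cols = list(COMPONENTS) + ["E_total"]
    stack = np.stack([t.df[cols].to_numpy(float) for t in tables])  # (F, N, C)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    mean_df = tables[0].df.copy()
    sd_df = tables[0].df[cols].copy()
    for j, c in enumerate(cols):
        mean_df[c] = mean[:, j]
        sd_df[c] = sd[:, j]
    frame_totals = stack.sum(axis=1)  # (F, C)
    tot_mean = frame_totals.mean(axis=0)
    tot_sd = frame_totals.std(axis=0, ddof=0)
    mean_table = PerResidueEnergyTable(
        mean_df,
        subsystem=tables[0].subsystem,
        kind=tables[0].kind,
        frame="mean",
        meta=dict(tables[0].meta),
    )
    return EnsembleTable(
        mean=mean_table,
        sd=sd_df,
        total_mean=EnergyComponents(*tot_mean[:4]),
        total_sd=EnergyComponents(*tot_sd[:4]),
        grand_total_mean=float(tot_mean[4]),
        grand_total_sd=float(tot_sd[4]),
        n_frames=len(tables),
    )
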