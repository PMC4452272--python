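"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing here attempts to mimic real tubulin energetics beyond orders of
magnitude.  The generators provide:

* toy parameterized dimers — two labeled bead-residue subunits on a compact
  scaffold, with seeded charges (optionally constrained to a tubulin-like net
  negative charge) and a minimal bespoke Lennard-Jones/GB parameter preset
  that exercises every energy term;
* ideal or perturbed ring trajectories — frames of an ideal ring under an
  oscillating elliptical distortion (emulating the spontaneous
  circular-to-oval deformation of simulated rings) plus isotropic Gaussian
  jitter;
* mock per-residue energy tables — 13-subsystem table sets with planted
  structure (subunit-role cell sums, an M-loop-like block carrying a set
  fraction of the energy, an outward-skewed radial placement) and the planted
  ground truth recorded for recovery tests.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .energy import COMPONENTS, PerResidueEnergyTable, _make_table_df
from .lattice import Atoms, LatticeSpec, RingStructure, build_ring

__all__ = [
    "ToyDimerSpec",
    "make_toy_dimer",
    "make_ring_trajectory",
    "make_mock_tables",
]

#: Atom names cycled within a toy residue; the first is backbone-like so that
#: backbone selections are non-trivial on toy structures.
TOY_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE", "CZ")
TOY_RES_NAMES = ("ALA", "GLU", "LYS", "SER", "VAL", "ASP", "ARG", "THR")


@dataclass(frozen=True)
class ToyDimerSpec:
    """Recipe for a seeded toy dimer.

    ``residues_per_subunit`` bead residues of ``atoms_per_residue`` atoms are
    laid out per subunit on a compact helical scaffold spanning one monomer
    rise each (β at low z, α at high z — the package's lattice orientation
    convention).  Charges are drawn N(0, charge_sd) and shifted to hit
    ``net_charge`` exactly.
    """

    residues_per_subunit: int = 8
    atoms_per_residue: int = 3
    monomer_rise_h: float = 40.60
    scaffold_radius: float = 7.0
    net_charge: float = -4.0
    charge_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_subunit < 1:
            raise ValueError("residues_per_subunit must be >= 1")
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[Atoms, pd.DataFrame]:
    """Build a toy two-subunit dimer and its parameter table.

    Returns (atoms, parameter table).  The table has one row per
    (res_name, atom_name) pair actually present, in the delimited layout the
    IO module reads back, so toy systems round-trip through the standard
    parameterization path.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.monomer_rise_h
    n_res = spec.residues_per_subunit
    n_at = spec.atoms_per_residue

    coords, names, elements, res_names = [], [], [], []
    res_nums, subunits = [], []
    margin = 1.5  # keep beads off the periodic faces so interfaces have a gap
    for si, subunit in enumerate(("beta", "alpha")):  # β low z, α high z
        z0 = si * h
        for r in range(n_res):
            # residue centers on a coarse helix inside the monomer
            # one full scaffold turn per monomer with a common phase, so the
            # top of one monomer meets the bottom of the next azimuthally and
            # lattice neighbors form real contacts
            # residues are azimuthal bead rings stacked in z; the scaffold
            # radius bulges at the subunit center and tapers toward its ends
            # (an M-loop-like equator), so the closest lateral contact between
            # neighboring dimers tracks the subunit centers — the geometry
            # that makes the seam's α/β register flip detectable by distance
            frac = r / max(n_res - 1, 1)
            taper = 0.6 + 0.4 * np.sin(np.pi * frac)
            rho = spec.scaffold_radius * taper
            cz = z0 + margin + frac * (h - 2 * margin)
            rname = TOY_RES_NAMES[r % len(TOY_RES_NAMES)]
            for a in range(n_at):
                ang = 2.0 * np.pi * (a / n_at + 0.13 * r)  # staggered rings
                coords.append(
                    np.array(
                        [rho * np.cos(ang), rho * np.sin(ang), cz + 0.4 * (a % 2)]
                    )
                )
                names.append(TOY_ATOM_NAMES[a % len(TOY_ATOM_NAMES)])
                elements.append("C")
                res_names.append(rname)
                res_nums.append(r + 1)
                subunits.append(subunit)

    n = len(coords)
    charge = rng.normal(0.0, spec.charge_sd, size=n)
    charge += (spec.net_charge - charge.sum()) / n
    rmin2 = rng.uniform(1.7, 2.0, size=n)
    epsilon = rng.uniform(0.05, 0.2, size=n)
    gb_radius = rmin2 * 0.9
    gb_screen = np.full(n, 0.8)
    mass = np.full(n, 12.011)

    atoms = Atoms(
        coords=np.array(coords),
        atom_name=names,
        element=elements,
        res_name=res_names,
        res_num=res_nums,
        subunit=subunits,
        dimer_index=np.ones(n, dtype=int),
        charge=charge,
        rmin2=rmin2,
        epsilon=epsilon,
        gb_radius=gb_radius,
        gb_screen=gb_screen,
        mass=mass,
    )

    # per-atom parameter rows keyed (res_name, atom_name, subunit, res_num)
    params = pd.DataFrame(
        {
            "res_name": atoms.res_name,
            "atom_name": atoms.atom_name,
            "subunit": atoms.subunit,
            "res_num": atoms.res_num,
            "charge": atoms.charge,
            "rmin2": atoms.rmin2,
            "epsilon": atoms.epsilon,
            "gb_radius": atoms.gb_radius,
            "gb_screen": atoms.gb_screen,
            "mass": atoms.mass,
        }
    )
    return atoms, params


# ---------------------------------------------------------------------------
# Ring trajectories
# ---------------------------------------------------------------------------


def make_ring_trajectory(
    spec: LatticeSpec,
    dimer: Atoms,
    n_frames: int = 10,
    ovalization: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[RingStructure]:
    """Frames of an ideal ring under oscillating elliptical distortion.

    Frame t scales the ring cross-section to semi-axes R·(1 ± u_t) with
    u_t = (δ/R)·sin(2πt/n_frames), δ = ``ovalization`` in Å, then adds
    isotropic Gaussian jitter of SD ``noise_sigma`` Å.  δ = σ = 0 reproduces
    the ideal ring in every frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ideal = build_ring(spec, dimer)
    frames: list[RingStructure] = []
    for t in range(n_frames):
        u = (ovalization / spec.ring_radius) * np.sin(2.0 * np.pi * t / n_frames)
        atoms = ideal.atoms.copy()
        atoms.coords[:, 0] *= 1.0 + u
        atoms.coords[:, 1] *= 1.0 - u
        if noise_sigma > 0:
            atoms.coords += rng.normal(0.0, noise_sigma, size=atoms.coords.shape)
        frames.append(RingStructure(atoms=atoms, spec=spec, box=ideal.box))
    return frames


# ---------------------------------------------------------------------------
# Mock per-residue tables
# ---------------------------------------------------------------------------


@dataclass
class MockTableTruth:
    """Ground truth planted into a mock table set."""

    cell_totals: dict[str, float]  # 'L_beta', 'R_beta', 'L_alpha', 'R_alpha'
    grand_total: float
    outer_fraction: float | None
    block_label: str | None
    block_fraction: float | None
    radial_coords: pd.Series | None = field(default=None, repr=False)
    domain_truth: dict[str, float] | None = None


def make_mock_tables(
    n_subsystems: int = 13,
    n_residues_per_subunit: int = 20,
    cell_totals: dict[str, float] | None = None,
    outer_fraction: float | None = None,
    x_com: float = 30.0,
    block_range: tuple[int, int] | None = None,
    block_fraction: float | None = None,
    noise_sigma: float = 0.0,
    kind: str = "lateral",
    seed: int = 0,
) -> tuple[list[PerResidueEnergyTable], MockTableTruth]:
    """Generate 13 mock per-residue tables with planted ground truth.

    ``cell_totals`` plants the per-ring subunit/role 2×2 sums (defaults to a
    tubulin-like lateral matrix); ``outer_fraction``, if given, also plants
    radial residue coordinates such that exactly that fraction of each
    component lies at x ≥ x_com; ``block_range``/``block_fraction`` plant an
    M-loop-like residue block carrying a set fraction of each cell's energy.
    Gaussian noise of SD ``noise_sigma`` (per residue, per component) is
    added on top without re-balancing, so noiseless recovery is exact.
    """
    if n_subsystems != 13:
        raise ValueError("mock table sets model a 13-dimer ring")
    if block_fraction is not None and not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block_fraction must be within [0, 1]")
    if outer_fraction is not None and not 0.0 <= outer_fraction <= 1.0:
        raise ValueError("outer_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    cells = dict(
        cell_totals
        or {"L_beta": -25.0, "R_beta": -147.0, "L_alpha": -165.0, "R_alpha": -74.0}
    )

    n_res = n_residues_per_subunit
    keys = [
        (role, subunit, r + 1)
        for role, subunit in (("R", "alpha"), ("R", "beta"), ("L", "alpha"), ("L", "beta"))
        for r in range(n_res)
    ]
    res_names = ["ALA"] * len(keys)

    if outer_fraction is not None and block_fraction is not None:
        raise ValueError("plant either outer_fraction or block_fraction, not both")

    # per-residue weights within each cell (positive, seeded, fixed over
    # subsystems so the ring-level planted sums are exact by construction);
    # each cell's weights sum to 1, and a planted split (an M-loop-like block
    # or an outer radial group) carries exactly its set fraction
    outer_keys: set[tuple[str, str, int]] = set()
    weights: dict[tuple[str, str, int], float] = {}
    for role, subunit in (("R", "alpha"), ("R", "beta"), ("L", "alpha"), ("L", "beta")):
        w = rng.uniform(0.5, 1.5, size=n_res)
        if block_range is not None and block_fraction is not None:
            lo, hi = block_range
            in_group = np.array([lo <= r + 1 <= hi for r in range(n_res)])
            frac = block_fraction
        elif outer_fraction is not None:
            in_group = np.arange(n_res) < n_res // 2  # first half = outer
            frac = outer_fraction
            outer_keys |= {
                (role, subunit, r + 1) for r in range(n_res) if in_group[r]
            }
        else:
            in_group = None
            frac = None
        if in_group is not None and in_group.any() and (~in_group).any():
            w_in = w * in_group
            w_out = w * ~in_group
            w = frac * w_in / w_in.sum() + (1.0 - frac) * w_out / w_out.sum()
        else:
            w = w / w.sum()
        for r in range(n_res):
            weights[(role, subunit, r + 1)] = w[r]

    # fixed component split of each residue's total (sums to 1)
    comp_split = {"E_vdW": 0.6, "E_ele": 0.9, "E_GB": -0.6, "E_SA": 0.1}

    tables: list[PerResidueEnergyTable] = []
    for s in range(n_subsystems):
        comp = {c: np.zeros(len(keys)) for c in COMPONENTS}
        for i, key in enumerate(keys):
            role, subunit, _ = key
            cell = cells[f"{role}_{subunit}"]
            res_total = cell * weights[key] / n_subsystems
            for c in COMPONENTS:
                comp[c][i] = res_total * comp_split[c]
                if noise_sigma > 0:
                    comp[c][i] += rng.normal(0.0, noise_sigma)
        df = _make_table_df(keys, res_names, comp)
        label = "seam" if (kind == "lateral" and s == n_subsystems - 1) else f"{kind}_{s + 1:02d}"
        tables.append(PerResidueEnergyTable(df=df, subsystem=label, kind=kind))

    # planted radial placement matching the outer-group weight split exactly
    radial = None
    if outer_fraction is not None:
        xs = [x_com + 5.0 if k in outer_keys else x_com - 5.0 for k in keys]
        idx = pd.MultiIndex.from_tuples(keys, names=("role", "subunit", "res_num"))
        radial = pd.Series(xs, index=idx)

    grand = float(sum(cells.values()))
    truth = MockTableTruth(
        cell_totals=cells,
        grand_total=grand,
        outer_fraction=outer_fraction,
        block_label="M-loop" if block_range else None,
        block_fraction=block_fraction,
        radial_coords=radial,
        domain_truth=(
            {"M-loop": grand * block_fraction} if block_fraction is not None else None
        ),
    )
    return tables, truth
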