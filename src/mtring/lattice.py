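"""Idealized microtubule lattice construction.

A microtubule (MT) wall is a helical lattice of αβ-tubulin heterodimers.  The
most common geometry is the 13-protofilament, 3-start ("13_3") B lattice: going
once around the ring, the lateral neighbor transform is applied 13 times and the
accumulated axial rise equals three monomer lengths.  Because three monomer
rises (1.5 dimer repeats) is not an integer number of dimer repeats, the lattice
closes with a *seam*: one lateral interface where the neighboring protofilament
sits one monomer out of register, so that an α-subunit packs against a
β-subunit instead of the α–α / β–β packing found everywhere else.

This module builds one periodic MT ring (13 dimers, axially periodic with the
dimer repeat) from a single dimer template and enumerates the 26 two-dimer
subsystems used for interaction-energy scoring: 12 ordinary lateral pairs, one
lateral seam pair, and 13 longitudinal pairs (each dimer against its own axial
periodic image).

Axis and orientation conventions
--------------------------------
Coordinates are Cartesian Å, right handed, with the MT axis along z.  The
template dimer is placed with its β-subunit at low z and its α-subunit at high
z, so the +c axial periodic image of a dimer presents its β-subunit to the
receptor's α-subunit — the longitudinal inter-dimer interface therefore
involves the receptor's α and the ligand's β, matching the standard
receptor/ligand convention for MT energetics (the dimer whose α faces the
interface is the receptor in longitudinal subsystems; the dimer whose M-loop
faces the interface is the receptor in lateral subsystems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "Atoms",
    "LatticeSpec",
    "RingStructure",
    "Subsystem",
    "NeighborTransform",
    "build_ring",
    "neighbor_transform",
    "make_subsystem",
    "GDP_DIMER_REPEAT",
    "GTP_DIMER_REPEAT",
]

#: Axial dimer repeat distances (Å).  GTP at the exchangeable site lengthens
#: the dimer, expanding the repeat from 81.20 Å (GDP state) to 83.38 Å.
GDP_DIMER_REPEAT = 81.20
GTP_DIMER_REPEAT = 83.38

SUBUNITS = ("alpha", "beta")


class LabelingError(ValueError):
    """Raised when a structure lacks required subunit/dimer labels."""


class SpecError(ValueError):
    """Raised when a lattice specification is inconsistent."""


# ---------------------------------------------------------------------------
# Atom container
# ---------------------------------------------------------------------------

_STR_FIELDS = ("atom_name", "element", "res_name", "subunit")
_INT_FIELDS = ("res_num", "dimer_index")
_FLOAT_FIELDS = ("charge", "rmin2", "epsilon", "gb_radius", "gb_screen", "mass")


@dataclass
class Atoms:
    """Structure-of-arrays atom container with force-field parameters.

    ``coords`` is (n, 3) float64 in Å.  ``rmin2`` is the Lennard-Jones
    r_min/2 in Å, ``epsilon`` the well depth in kcal/mol, ``gb_radius`` the
    intrinsic generalized-Born radius in Å and ``gb_screen`` the dimensionless
    GB descreening scale.  ``res_num`` numbers residues within a subunit;
    ``dimer_index`` is 1..n_pf on a ring (1 on a bare template).
    """

    coords: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_num: np.ndarray
    subunit: np.ndarray
    dimer_index: np.ndarray
    charge: np.ndarray
    rmin2: np.ndarray
    epsilon: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in _STR_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype="U8"))
        for name in _INT_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in _FLOAT_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in _STR_FIELDS + _INT_FIELDS + _FLOAT_FIELDS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length != number of atoms")

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "Atoms":
        return Atoms(**{k: getattr(self, k).copy() for k in self._fields()})

    @staticmethod
    def _fields() -> tuple[str, ...]:
        return ("coords",) + _STR_FIELDS + _INT_FIELDS + _FLOAT_FIELDS

    def select(self, mask: np.ndarray) -> "Atoms":
        return Atoms(**{k: getattr(self, k)[mask] for k in self._fields()})

    @staticmethod
    def concat(parts: list["Atoms"]) -> "Atoms":
        return Atoms(
            **{
                k: np.concatenate([getattr(p, k) for p in parts])
                for k in Atoms._fields()
            }
        )

    # -- geometry ----------------------------------------------------------

    def translated(self, shift) -> "Atoms":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, dtype=float)
        return out

    def rotated_z(self, angle_rad: float) -> "Atoms":
        """Rotate about the +z axis through the origin."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out = self.copy()
        out.coords = out.coords @ rot.T
        return out

    def transformed(self, rotation: np.ndarray, translation) -> "Atoms":
        out = self.copy()
        out.coords = out.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def com(self) -> np.ndarray:
        """Mass-weighted center of mass."""
        w = self.mass
        if not np.any(w > 0):
            w = np.ones(len(self))
        return (self.coords * w[:, None]).sum(axis=0) / w.sum()

    # -- residue iteration -------------------------------------------------

    def residue_keys(self) -> list[tuple[int, str, int]]:
        """Ordered unique (dimer_index, subunit, res_num) keys."""
        seen: dict[tuple[int, str, int], None] = {}
        for d, s, r in zip(self.dimer_index, self.subunit, self.res_num):
            seen.setdefault((int(d), str(s), int(r)), None)
        return list(seen)

    def iter_residues(self) -> Iterator[tuple[tuple[int, str, int], "Atoms"]]:
        for key in self.residue_keys():
            d, s, r = key
            mask = (
                (self.dimer_index == d)
                & (self.subunit == s)
                & (self.res_num == r)
            )
            yield key, self.select(mask)


# ---------------------------------------------------------------------------
# Lattice specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of an idealized n_pf-protofilament, helix_start-start MT ring.

    Parameters
    ----------
    n_pf : number of protofilaments (13 for the canonical MT).
    helix_start : monomer rises accumulated over one full lateral turn
        (3 for the canonical B lattice).
    monomer_rise_h : axial monomer rise in Å; the dimer repeat is 2h.
    ring_radius : distance from the MT axis to each dimer's center of mass, Å.
    nucleotide_state : 'GDP' or 'GTP'; selects the dimer repeat
        (81.20 vs 83.38 Å) when ``monomer_rise_h`` is not given explicitly.
    """

    n_pf: int = 13
    helix_start: int = 3
    monomer_rise_h: float | None = None
    ring_radius: float = 115.0
    nucleotide_state: Literal["GDP", "GTP"] = "GDP"

    def __post_init__(self) -> None:
        if self.n_pf < 1:
            raise SpecError("n_pf must be >= 1")
        if self.helix_start < 1:
            raise SpecError("helix_start must be >= 1")
        if self.nucleotide_state not in ("GDP", "GTP"):
            raise SpecError("nucleotide_state must be 'GDP' or 'GTP'")
        if self.monomer_rise_h is None:
            repeat = (
                GDP_DIMER_REPEAT
                if self.nucleotide_state == "GDP"
                else GTP_DIMER_REPEAT
            )
            object.__setattr__(self, "monomer_rise_h", repeat / 2.0)
        if self.monomer_rise_h <= 0:
            raise SpecError("monomer_rise_h must be positive")
        if self.ring_radius <= 0:
            raise SpecError("ring_radius must be positive")

    @property
    def dimer_repeat_c(self) -> float:
        """Axial periodicity per dimer: c = 2h (Å)."""
        return 2.0 * self.monomer_rise_h

    @property
    def lateral_twist(self) -> float:
        """Rotation per lateral step, radians."""
        return 2.0 * np.pi / self.n_pf

    @property
    def lateral_rise(self) -> float:
        """Axial rise per lateral step: helix_start·h/n_pf (Å).

        n_pf consecutive lateral steps then accumulate exactly helix_start
        monomer rises — the helical-closure identity of an n_pf_start lattice.
        """
        return self.helix_start * self.monomer_rise_h / self.n_pf

    @property
    def seam_offset(self) -> float:
        """Axial registry mismatch at the seam, in Å.

        The helical continuation past protofilament n_pf sits at
        helix_start·h, but the available periodic images of protofilament 1
        sit at integer multiples of c = 2h; the seam neighbor is the image at
        (helix_start−1)·h, one monomer rise below registry.
        """
        return abs(
            self.helix_start * self.monomer_rise_h
            - (self.helix_start - 1) * self.monomer_rise_h
        )

    @property
    def seam_image_shift(self) -> float:
        """Axial shift applied to dimer 1 to build the seam ligand (Å)."""
        return (self.helix_start - 1) * self.monomer_rise_h

    def validate_seam(self) -> None:
        """The seam image must be a periodic image: (start−1)·h ≡ 0 mod c."""
        shift = self.seam_image_shift
        c = self.dimer_repeat_c
        if abs(shift / c - round(shift / c)) > 1e-9:
            raise SpecError(
                "seam is inconsistent with helical closure: "
                f"(helix_start-1)*h = {shift} is not a multiple of c = {c}; "
                "helix_start must be odd"
            )


@dataclass
class NeighborTransform:
    """Rigid transform carrying a dimer onto its lattice neighbor."""

    rotation_angle: float  # radians about +z
    axial_shift: float  # Å along +z

    def apply(self, atoms: Atoms) -> Atoms:
        out = atoms.rotated_z(self.rotation_angle)
        return out.translated((0.0, 0.0, self.axial_shift))


def neighbor_transform(
    spec: LatticeSpec, step_kind: Literal["lateral", "longitudinal"]
) -> NeighborTransform:
    """Rigid transform from dimer k to its lateral or longitudinal neighbor."""
    if step_kind == "lateral":
        return NeighborTransform(spec.lateral_twist, spec.lateral_rise)
    if step_kind == "longitudinal":
        return NeighborTransform(0.0, spec.dimer_repeat_c)
    raise ValueError(f"unknown step_kind: {step_kind!r}")


# ---------------------------------------------------------------------------
# Ring construction
# ---------------------------------------------------------------------------


@dataclass
class RingStructure:
    """One periodic MT ring: n_pf dimers on the helical lattice.

    ``box`` is the periodic cell (Lx, Ly, Lz) with Lz equal to the dimer
    repeat, so the ring tiles into an infinitely long MT under periodic
    boundary conditions.
    """

    atoms: Atoms
    spec: LatticeSpec
    box: tuple[float, float, float]

    def dimer(self, k: int) -> Atoms:
        if not 1 <= k <= self.spec.n_pf:
            raise IndexError(f"dimer index {k} out of range 1..{self.spec.n_pf}")
        return self.atoms.select(self.atoms.dimer_index == k)

    def dimer_com(self, k: int) -> np.ndarray:
        return self.dimer(k).com()


def build_ring(
    spec: LatticeSpec,
    template: Atoms,
    box_xy: float = 293.85,
) -> RingStructure:
    """Place n_pf copies of a dimer template on the helical lattice.

    Dimer k is the template rotated by (k−1)·2π/n_pf about the MT axis and
    raised by (k−1)·helix_start·h/n_pf, so one full lateral turn accumulates
    exactly helix_start monomer rises.  The template is first centered
    laterally at ``spec.ring_radius`` from the axis with its own z origin
    preserved (the template's α→β geometry is kept as given; see the module
    docstring for the orientation convention).

    Raises
    ------
    LabelingError
        If the template does not carry both 'alpha' and 'beta' subunit labels
        (a single-subunit template cannot form the α/β lattice contacts).
    """
    labels = set(np.unique(template.subunit))
    if not {"alpha", "beta"} <= labels:
        raise LabelingError(
            f"template must label both subunits 'alpha' and 'beta'; got {labels}"
        )
    # center the template's COM on (ring_radius, 0, original z)
    com = template.com()
    base = template.translated((spec.ring_radius - com[0], -com[1], 0.0))
    parts: list[Atoms] = []
    for k in range(1, spec.n_pf + 1):
        d = base.rotated_z((k - 1) * spec.lateral_twist)
        d = d.translated((0.0, 0.0, (k - 1) * spec.lateral_rise))
        d.dimer_index[:] = k
        parts.append(d)
    atoms = Atoms.concat(parts)
    return RingStructure(
        atoms=atoms, spec=spec, box=(box_xy, box_xy, spec.dimer_repeat_c)
    )


# ---------------------------------------------------------------------------
# Subsystems
# ---------------------------------------------------------------------------

SubsystemKind = Literal["lateral", "lateral_seam", "longitudinal"]

#: Continuous-numbering order of the four subunit roles in a subsystem.
ROLE_ORDER = (
    ("R", "alpha"),
    ("R", "beta"),
    ("L", "alpha"),
    ("L", "beta"),
)


@dataclass
class Subsystem:
    """A receptor dimer plus one (possibly periodic-image) ligand dimer.

    In lateral subsystems the receptor is dimer k and the ligand dimer k+1
    (receptor's M-loop faces the interface); at the seam the receptor is dimer
    n_pf and the ligand is the periodic image of dimer 1, one monomer rise out
    of register so that α packs against β.  In longitudinal subsystems the
    ligand is the receptor's own +c periodic image, so receptor and ligand are
    identical in composition and the interface involves the receptor's α and
    the ligand's β subunit.
    """

    receptor: Atoms
    ligand: Atoms
    kind: SubsystemKind
    index: int  # k; 13 (=n_pf) for the seam
    spec: LatticeSpec = field(repr=False, default=None)

    @property
    def label(self) -> str:
        if self.kind == "lateral_seam":
            return "seam"
        return f"{self.kind}_{self.index:02d}"

    def role_atoms(self, role: str) -> Atoms:
        return self.receptor if role == "R" else self.ligand

    def residue_keys(self) -> list[tuple[str, str, int]]:
        """Ordered (role, subunit, res_num) keys: Rα, Rβ, Lα, Lβ."""
        keys: list[tuple[str, str, int]] = []
        for role, subunit in ROLE_ORDER:
            atoms = self.role_atoms(role)
            for _, s, r in atoms.residue_keys():
                if s == subunit:
                    keys.append((role, subunit, r))
        return keys

    def continuous_numbering(self) -> dict[tuple[str, str, int], int]:
        """Map (role, subunit, res_num) → 1..N continuous subsystem index."""
        return {key: i + 1 for i, key in enumerate(self.residue_keys())}

    def all_atoms(self) -> tuple[Atoms, np.ndarray]:
        """Concatenate receptor+ligand; return atoms and their role labels."""
        atoms = Atoms.concat([self.receptor, self.ligand])
        roles = np.array(
            ["R"] * len(self.receptor) + ["L"] * len(self.ligand), dtype="U1"
        )
        return atoms, roles


def make_subsystem(
    ring: RingStructure, kind: SubsystemKind, k: int | None = None
) -> Subsystem:
    """Extract one scoring subsystem from a ring.

    ``k`` is required for 'lateral' (1..n_pf−1) and 'longitudinal'
    (1..n_pf); the seam has no k (receptor is dimer n_pf, ligand the periodic
    image of dimer 1).
    """
    spec = ring.spec
    n = spec.n_pf
    if kind == "lateral":
        if k is None or not 1 <= k <= n - 1:
            raise IndexError(f"lateral k must be in 1..{n - 1}, got {k}")
        return Subsystem(
            receptor=ring.dimer(k), ligand=ring.dimer(k + 1), kind=kind,
            index=k, spec=spec,
        )
    if kind == "lateral_seam":
        if n < 3:
            raise SpecError("a seam requires at least 3 protofilaments")
        spec.validate_seam()
        ligand = ring.dimer(1).translated((0.0, 0.0, spec.seam_image_shift))
        return Subsystem(
            receptor=ring.dimer(n), ligand=ligand, kind=kind, index=n,
            spec=spec,
        )
    if kind == "longitudinal":
        if k is None or not 1 <= k <= n:
            raise IndexError(f"longitudinal k must be in 1..{n}, got {k}")
        receptor = ring.dimer(k)
        ligand = receptor.translated((0.0, 0.0, spec.dimer_repeat_c))
        return Subsystem(
            receptor=receptor, ligand=ligand, kind=kind, index=k, spec=spec
        )
    raise ValueError(f"unknown subsystem kind: {kind!r}")


def enumerate_subsystems(ring: RingStructure) -> list[Subsystem]:
    """All 2·n_pf subsystems: n_pf−1 lateral, the seam, n_pf longitudinal."""
    n = ring.spec.n_pf
    subs = [make_subsystem(ring, "lateral", k) for k in range(1, n)]
    if n >= 3:
        subs.append(make_subsystem(ring, "lateral_seam"))
    subs += [make_subsystem(ring, "longitudinal", k) for k in range(1, n + 1)]
    return subs
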