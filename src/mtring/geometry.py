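"""Trajectory-level geometry observables: ring diameters and backbone RMSD.

Simulated MT rings deform spontaneously between circular and oval shapes.
Two nearly perpendicular cylinder diameters track this: Dx is the distance
between the center of mass of dimer 4 and the joint center of mass of dimers
10 and 11; Dy between dimer 1 and the joint COM of dimers 7 and 8.  Only the
projection onto the x–y plane is taken, since that is what measures the
cylinder cross-section.  On an ideal 13-gon of radius R both diameters equal
R·(1 + cos(π/13)), because the mid-chord of two adjacent vertices sits
diametrically opposite the reference vertex at radius R·cos(π/13).
"""

from __future__ import annotations

import numpy as np

from .lattice import Atoms, RingStructure

__all__ = ["diameters", "ideal_diameter", "backbone_rmsd", "kabsch"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


def _joint_com(ring: RingStructure, ks: tuple[int, ...]) -> np.ndarray:
    atoms = Atoms.concat([ring.dimer(k) for k in ks])
    return atoms.com()


def diameters(ring: RingStructure) -> tuple[float, float]:
    """(Dx, Dy) in Å from dimer centers of mass, x–y projection only."""
    labels = set(np.unique(ring.atoms.dimer_index))
    needed = {1, 4, 7, 8, 10, 11}
    if not needed <= labels:
        raise ValueError(f"ring is missing dimer labels {sorted(needed - labels)}")
    dx = _joint_com(ring, (4,)) - _joint_com(ring, (10, 11))
    dy = _joint_com(ring, (1,)) - _joint_com(ring, (7, 8))
    return float(np.hypot(dx[0], dx[1])), float(np.hypot(dy[0], dy[1]))


def ideal_diameter(radius: float, n_pf: int = 13) -> float:
    """Closed-form Dx = Dy on an ideal circular ring of the given COM radius."""
    return radius * (1.0 + np.cos(np.pi / n_pf))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation superposing centered ``mobile`` onto ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def backbone_rmsd(
    frame: Atoms,
    reference: Atoms,
    selection: str = "backbone",
    fit: bool = True,
) -> float:
    """RMSD of the selected atoms between two conformations, Å.

    ``selection`` is 'backbone' (atom names N, CA, C, O of protein residues;
    cofactors are excluded by lacking these names) or 'all'.  With
    ``fit=True`` (default) the frames are optimally superposed first, so any
    rigid-body motion contributes zero; with ``fit=False`` the raw deviation
    in the lab frame is reported.
    """
    if selection == "backbone":
        m1 = np.isin(frame.atom_name, BACKBONE_NAMES)
        m2 = np.isin(reference.atom_name, BACKBONE_NAMES)
    elif selection == "all":
        m1 = np.ones(len(frame), dtype=bool)
        m2 = np.ones(len(reference), dtype=bool)
    else:
        raise ValueError(f"unknown selection: {selection!r}")
    a = frame.coords[m1]
    b = reference.coords[m2]
    if a.shape != b.shape or len(a) == 0:
        raise ValueError(
            f"selection mismatch: {a.shape[0]} vs {b.shape[0]} atoms selected"
        )
    if fit:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a @ kabsch(a, b).T
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
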