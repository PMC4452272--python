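"""Readers, writers and run configuration.

All tabular output is tab-separated text with '.' decimals and a fixed column
order, prefixed by '#' header lines that carry provenance (including the
run-configuration hash), so two runs with equal config hashes produce equal
numeric content and outputs diff cleanly.

Per-residue energy tables use the plain-text layout of the classic
supplementary per-residue datasets: one residue per line with columns
index, role, subunit, res_num, res_name, E_vdW, E_ele, E_GB, E_SA, E_total.

PDB input/output goes through biotite.  The dimer index and subunit of each
atom are encoded in the chain field: one letter per (dimer, subunit) pair,
'A' = dimer 1 α, 'B' = dimer 1 β, 'C' = dimer 2 α, … (26 chains for a
13-dimer ring).  For external templates a chain→subunit mapping can be given
instead.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import DomainMap as _DomainMap
from .energy import COMPONENTS, PerResidueEnergyTable
from .lattice import Atoms

__all__ = [
    "RunConfig",
    "config_hash",
    "write_pdb",
    "read_pdb",
    "write_parameter_table",
    "read_parameter_table",
    "assign_parameters",
    "write_energy_table",
    "read_energy_table",
    "write_table",
    "load_default_domain_map",
    "load_domain_map",
    "load_reference_energetics",
]

DATA_DIR = Path(__file__).parent / "data"

# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration, serialized into every output header."""

    n_pf: int = 13
    helix_start: int = 3
    nucleotide_state: str = "GDP"
    monomer_rise_h: float | None = None
    ring_radius: float = 115.0
    eps_in: float = 1.0
    eps_out: float = 80.0
    sa_gamma: float = 0.0072
    sa_beta: float = 0.0
    probe_radius: float = 1.4
    sasa_points: int = 240
    bin_width: float = 3.0
    lumen_percentile: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = {
            "n_pf": self.n_pf >= 1,
            "helix_start": self.helix_start >= 1,
            "nucleotide_state": self.nucleotide_state in ("GDP", "GTP"),
            "eps_in": self.eps_in > 0,
            "eps_out": self.eps_out > 0,
            "probe_radius": self.probe_radius >= 0,
            "sasa_points": self.sasa_points >= 10,
            "bin_width": self.bin_width > 0,
            "lumen_percentile": 0 <= self.lumen_percentile <= 100,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration field(s): {', '.join(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration field(s): {sorted(unknown)}")
        return cls(**data)

    def lattice_spec(self):
        from .lattice import LatticeSpec

        return LatticeSpec(
            n_pf=self.n_pf,
            helix_start=self.helix_start,
            monomer_rise_h=self.monomer_rise_h,
            ring_radius=self.ring_radius,
            nucleotide_state=self.nucleotide_state,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def config_hash(config: RunConfig) -> str:
    """Deterministic short hash of the canonicalized configuration."""
    blob = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _header_lines(config: RunConfig | None, extra: dict | None = None) -> list[str]:
    lines = []
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
        lines.append(f"# config: {json.dumps(config.as_dict(), sort_keys=True)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_CHAINS = string.ascii_uppercase


def _chain_for(dimer_index: int, subunit: str) -> str:
    i = (dimer_index - 1) * 2 + (0 if subunit == "alpha" else 1)
    return _CHAINS[i % 26]


def write_pdb(atoms: Atoms, path: str | Path) -> None:
    """Write atoms as PDB, chain field encoding (dimer, subunit)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(len(atoms))
    arr.coord = atoms.coords.astype(np.float32)
    arr.atom_name = atoms.atom_name
    arr.element = atoms.element
    arr.res_name = atoms.res_name
    arr.res_id = atoms.res_num
    arr.chain_id = np.array(
        [
            _chain_for(int(d), str(s))
            for d, s in zip(atoms.dimer_index, atoms.subunit)
        ]
    )
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb(
    path: str | Path,
    chain_map: dict[str, tuple[int, str]] | None = None,
) -> Atoms:
    """Read a PDB into the package's atom container (parameters unset).

    ``chain_map`` maps chain IDs to (dimer_index, subunit); by default the
    package's own encoding is assumed (chain letter i ↔ dimer i//2+1,
    alternating α/β).  Parameters must be assigned afterwards with
    :func:`assign_parameters`.
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    n = arr.array_length()
    if chain_map is None:
        chain_map = {}
        for i, ch in enumerate(_CHAINS):
            chain_map[ch] = (i // 2 + 1, "alpha" if i % 2 == 0 else "beta")
    dimer_index = np.empty(n, dtype=int)
    subunit = np.empty(n, dtype="U8")
    for i, ch in enumerate(arr.chain_id):
        d, s = chain_map[str(ch)]
        dimer_index[i] = d
        subunit[i] = s
    nan = np.full(n, np.nan)
    return Atoms(
        coords=np.asarray(arr.coord, dtype=float),
        atom_name=arr.atom_name,
        element=arr.element,
        res_name=arr.res_name,
        res_num=np.asarray(arr.res_id, dtype=int),
        subunit=subunit,
        dimer_index=dimer_index,
        charge=nan.copy(),
        rmin2=nan.copy(),
        epsilon=nan.copy(),
        gb_radius=np.zeros(n),
        gb_screen=nan.copy(),
        mass=np.full(n, 12.011),
    )


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

PARAM_COLS = [
    "res_name",
    "atom_name",
    "subunit",
    "res_num",
    "charge",
    "rmin2",
    "epsilon",
    "gb_radius",
    "gb_screen",
    "mass",
]


def write_parameter_table(params: pd.DataFrame, path: str | Path) -> None:
    params[PARAM_COLS].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PARAM_COLS) - set(df.columns)
    if missing - {"subunit", "res_num", "mass"}:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def assign_parameters(atoms: Atoms, params: pd.DataFrame) -> Atoms:
    """Attach force-field parameters to atoms by lookup.

    Lookup is by (subunit, res_num, atom_name) when the table carries those
    columns (per-atom tables written next to toy structures), else by
    (res_name, atom_name).  Raises listing every unmatched atom.
    """
    out = atoms.copy()
    per_atom = {"subunit", "res_num"} <= set(params.columns)
    if per_atom:
        key_cols = ["subunit", "res_num", "atom_name"]
        keys = {
            (str(r.subunit), int(r.res_num), str(r.atom_name)): r
            for r in params.itertuples()
        }
        atom_keys = [
            (str(s), int(n), str(a))
            for s, n, a in zip(atoms.subunit, atoms.res_num, atoms.atom_name)
        ]
    else:
        key_cols = ["res_name", "atom_name"]
        keys = {
            (str(r.res_name), str(r.atom_name)): r for r in params.itertuples()
        }
        atom_keys = [
            (str(rn), str(a)) for rn, a in zip(atoms.res_name, atoms.atom_name)
        ]
    missing = [k for k in atom_keys if k not in keys]
    if missing:
        from .energy import ParameterizationError

        uniq = sorted(set(missing))[:20]
        raise ParameterizationError(
            f"no parameters for atoms keyed {key_cols}: {uniq}"
        )
    for i, k in enumerate(atom_keys):
        row = keys[k]
        out.charge[i] = row.charge
        out.rmin2[i] = row.rmin2
        out.epsilon[i] = row.epsilon
        out.gb_radius[i] = row.gb_radius
        out.gb_screen[i] = row.gb_screen
        if hasattr(row, "mass"):
            out.mass[i] = row.mass
    return out


# ---------------------------------------------------------------------------
# Per-residue energy tables (classic per-residue dataset layout)
# ---------------------------------------------------------------------------

ENERGY_COLS = ["index", "role", "subunit", "res_num", "res_name"] + list(
    COMPONENTS
) + ["E_total"]


def write_energy_table(
    table: PerResidueEnergyTable,
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    df = table.df.reset_index()[ENERGY_COLS]
    lines = _header_lines(
        config,
        {"subsystem": table.subsystem, "kind": table.kind, "frame": table.frame},
    )
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.9g")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + buf.getvalue())


def read_energy_table(path: str | Path) -> PerResidueEnergyTable:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(["role", "subunit", "res_num"])
    return PerResidueEnergyTable(
        df=df,
        subsystem=meta.get("subsystem", ""),
        kind=meta.get("kind", ""),
        frame=meta.get("frame", 0),
        meta=meta,
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    extra: dict | None = None,
    index: bool = True,
) -> None:
    """Generic tab-separated table writer with provenance header."""
    lines = _header_lines(config, extra)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, float_format="%.9g")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + buf.getvalue())


# ---------------------------------------------------------------------------
# Bundled data
# ---------------------------------------------------------------------------


def load_domain_map(path: str | Path) -> _DomainMap:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _DomainMap.from_dict(data)


def load_default_domain_map() -> _DomainMap:
    """The bundled tubulin secondary-structure domain map (editable data)."""
    return load_domain_map(DATA_DIR / "domains.yaml")


def load_reference_energetics() -> dict:
    """Published per-ring MM/GBSA reference values bundled as fixtures.

    Subunit contribution matrices, component groupings and profile splits for
    GDP- and GTP-state 13-protofilament microtubule ring models, used by the
    worked examples and the acceptance script.
    """
    with open(DATA_DIR / "reference_energetics.yaml") as fh:
        return yaml.safe_load(fh)
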