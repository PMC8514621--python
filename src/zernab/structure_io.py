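"""Molecular structure and surface point-cloud I/O.

Residue identity is the triple ``(chain id, residue number, insertion
code)`` with author (Chothia, for antibodies) numbering preserved
verbatim, because CDR boundaries are defined on those numbers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]

#: sentinel residue key for point clouds read from files without a
#: residue column; patch operations that need residue identity refuse these
UNKNOWN_RESIDUE: ResidueKey = ("", 0, "?")

CHAIN_ROLES = ("heavy", "light", "antigen", "unassigned")

# Bondi-style van der Waals radii (Angstrom), used when a PDB file carries
# no radii of its own.  Configurable via the radius_table argument.
DEFAULT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.7


class ParseError(ValueError):
    """Raised when a structure or point-cloud file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """One atom with the per-atom inputs the pipeline consumes."""

    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    radius: float         # Angstrom, > 0
    partial_charge: float  # elementary charges
    residue_key: ResidueKey
    residue_name: str
    het: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial}: radius must be > 0, got {self.radius}")


@dataclass
class Structure:
    """An ordered list of atoms plus chain role annotations."""

    atoms: list[Atom]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")

    # -- array views -------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key[0], None)
        return list(seen)

    def residues(self) -> dict[ResidueKey, list[int]]:
        """Ordered map residue_key -> indices of its atoms."""
        out: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def residue_names(self) -> dict[ResidueKey, str]:
        out: dict[ResidueKey, str] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, a.residue_name)
        return out

    def role_of(self, chain: str) -> str:
        return self.chain_roles.get(chain, "unassigned")

    def chains_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.chains if self.role_of(c) in roles]

    def atom_indices_for_roles(self, *roles: str) -> np.ndarray:
        keep = set(self.chains_with_role(*roles))
        return np.array([i for i, a in enumerate(self.atoms) if a.residue_key[0] in keep],
                        dtype=int)

    def subset(self, chains: Iterable[str]) -> "Structure":
        keep = set(chains)
        atoms = [a for a in self.atoms if a.residue_key[0] in keep]
        if not atoms:
            raise ValueError(f"no atoms on chains {sorted(keep)}")
        roles = {c: r for c, r in self.chain_roles.items() if c in keep}
        return Structure(atoms=atoms, chain_roles=roles)


@dataclass
class SurfacePointCloud:
    """Solvent-accessible surface points with per-point electrostatic values."""

    positions: np.ndarray              # (N, 3) Angstrom
    es_values: np.ndarray              # (N,)
    residue_keys: list[ResidueKey]
    probe_radius: float = 1.4
    source: str = "computed"           # {"computed", "file"}

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.es_values = np.asarray(self.es_values, dtype=float)
        n = len(self.positions)
        if n == 0:
            raise ValueError("surface point cloud is empty")
        if self.es_values.shape != (n,) or len(self.residue_keys) != n:
            raise ValueError("positions, es_values and residue_keys must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def has_residue_keys(self) -> bool:
        return all(k != UNKNOWN_RESIDUE for k in self.residue_keys)


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

_RESSEQ_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def _split_resseq(token: str, path, lineno: int) -> tuple[int, str]:
    m = _RESSEQ_RE.match(token)
    if not m:
        raise ParseError(f"{path}:{lineno}: cannot parse residue number {token!r}")
    return int(m.group(1)), m.group(2)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'\"*")
    if len(stripped) >= 2 and stripped[:2].upper() in DEFAULT_RADII:
        return stripped[:2].upper()
    return stripped[:1].upper()


def read_pqr(path) -> Structure:
    """Read a whitespace-delimited PQR file (PDB2PQR dialect).

    Records are ``ATOM/HETATM serial name resname [chain] resseq x y z
    charge radius``; the chain column is optional, and the residue number
    may carry an insertion code (``100A``).
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 10:
                raise ParseError(f"{path}:{lineno}: PQR record has {len(rec)} fields, "
                                 "expected at least 10 (missing charge/radius?)")
            # chain id present iff the field after resname is not a residue number
            if _RESSEQ_RE.match(rec[4]):
                chain, resseq_tok, rest = "", rec[4], rec[5:]
            else:
                chain, resseq_tok, rest = rec[4], rec[5], rec[6:]
            if len(rest) < 5:
                raise ParseError(f"{path}:{lineno}: missing coordinate/charge/radius fields")
            resnum, icode = _split_resseq(resseq_tok, path, lineno)
            try:
                x, y, z, q, r = (float(v) for v in rest[:5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            try:
                serial = int(rec[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad serial {rec[1]!r}") from exc
            atoms.append(Atom(
                serial=serial, name=rec[2], element=_guess_element(rec[2]),
                position=np.array([x, y, z]), radius=r, partial_charge=q,
                residue_key=(chain, resnum, icode), residue_name=rec[3],
                het=(rec[0] == "HETATM"),
            ))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms)


def write_pqr(structure: Structure, path) -> None:
    """Write a PQR file that :func:`read_pqr` round-trips to 4 decimals."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            chain, resnum, icode = a.residue_key
            rec = "HETATM" if a.het else "ATOM"
            chain_field = chain if chain else ""
            fh.write(f"{rec} {a.serial} {a.name} {a.residue_name} "
                     f"{chain_field}{' ' if chain_field else ''}{resnum}{icode} "
                     f"{a.position[0]:.4f} {a.position[1]:.4f} {a.position[2]:.4f} "
                     f"{a.partial_charge:.4f} {a.radius:.4f}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path, radius_table: dict[str, float] | None = None,
             charge_table: dict[tuple[str, str], float] | None = None,
             default_radius: float = DEFAULT_RADIUS) -> Structure:
    """Read PDB v3.3 ATOM/HETATM records, filling radii and charges from tables.

    Alternate locations are collapsed to the highest-occupancy conformer
    (tie: first encountered).  Atoms absent from ``radius_table`` receive
    ``default_radius`` (a warning is logged); atoms absent from
    ``charge_table`` receive charge 0.
    """
    from Bio.PDB import PDBParser  # deferred: Biopython import is slow

    radius_table = dict(DEFAULT_RADII if radius_table is None else radius_table)
    charge_table = {} if charge_table is None else charge_table
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            hetflag, resnum, icode = res.id
            key = (chain.id, resnum, icode.strip())
            for at in res.get_atoms():  # disordered atoms yield highest occupancy
                element = (at.element or _guess_element(at.get_name())).upper()
                if element in radius_table:
                    radius = radius_table[element]
                else:
                    logger.warning("element %r of atom %s not in radius table; "
                                   "using default %.2f A", element, at.get_name(),
                                   default_radius)
                    radius = default_radius
                charge = charge_table.get((res.get_resname(), at.get_name()), 0.0)
                atoms.append(Atom(
                    serial=at.get_serial_number() or len(atoms) + 1,
                    name=at.get_name(), element=element,
                    position=np.array(at.get_coord(), dtype=float),
                    radius=radius, partial_charge=charge,
                    residue_key=key, residue_name=res.get_resname(),
                    het=bool(hetflag.strip()),
                ))
    if not atoms:
        raise ParseError(f"{path}: no atoms parsed")
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# roles & point clouds
# ---------------------------------------------------------------------------

def assign_chain_roles(structure: Structure, heavy: str | None = None,
                       light: str | None = None,
                       antigen: Sequence[str] = ()) -> Structure:
    """Return a copy of *structure* with chain roles set; unlisted chains
    stay unassigned."""
    available = set(structure.chains)
    roles: dict[str, str] = {}
    for cid, role in [(heavy, "heavy"), (light, "light")]:
        if cid is not None:
            if cid not in available:
                raise ValueError(f"chain {cid!r} not in structure; available: "
                                 f"{sorted(available)}")
            roles[cid] = role
    for cid in antigen:
        if cid not in available:
            raise ValueError(f"chain {cid!r} not in structure; available: "
                             f"{sorted(available)}")
        roles[cid] = "antigen"
    return Structure(atoms=list(structure.atoms), chain_roles=roles)


def _format_key(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


def _parse_key(token: str, path, lineno: int) -> ResidueKey:
    parts = token.split(":")
    if len(parts) != 3:
        raise ParseError(f"{path}:{lineno}: bad residue key {token!r} "
                         "(expected chain:resnum:icode)")
    try:
        return (parts[0], int(parts[1]), parts[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad residue number in key {token!r}") from exc


def read_point_cloud(path) -> SurfacePointCloud:
    """Read ``x y z es_value [chain:resnum:icode]`` rows.

    Clouds without the residue column get sentinel keys; residue-aware
    operations (CDR patches, epitopes, decoys) refuse such clouds.
    """
    path = Path(path)
    pos, es, keys = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0].startswith("#"):
                continue
            if len(rec) < 4:
                raise ParseError(f"{path}:{lineno}: expected x y z es_value [residue]")
            try:
                pos.append([float(rec[0]), float(rec[1]), float(rec[2])])
                es.append(float(rec[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            keys.append(_parse_key(rec[4], path, lineno) if len(rec) > 4
                        else UNKNOWN_RESIDUE)
    if not pos:
        raise ParseError(f"{path}: empty point cloud")
    return SurfacePointCloud(positions=np.array(pos), es_values=np.array(es),
                             residue_keys=keys, source="file")


def write_point_cloud(cloud: SurfacePointCloud, path) -> None:
    with open(path, "w") as fh:
        for p, v, k in zip(cloud.positions, cloud.es_values, cloud.residue_keys):
            key_col = "" if k == UNKNOWN_RESIDUE else " " + _format_key(k)
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {v:.6g}{key_col}\n")
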