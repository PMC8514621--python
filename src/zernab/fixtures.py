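"""Synthetic surface and structure generators.

These generators make every pipeline stage testable without external
structure downloads:

* parametric surface patches (spherical caps, ellipsoid caps, bumpy
  Gaussian height fields) with per-pseudo-residue electrostatic values,
  emulating the convention that all surface points of a residue share one
  potential value;
* complementary patch pairs -- a surface and its mold, charge-inverted and
  re-posed by a random rigid motion, so that only rotation-invariant
  descriptors can reveal the match;
* labelled two-class patch datasets encoding the flat-versus-concave
  combining-site contrast between protein-binding and
  small-antigen-binding antibodies;
* a toy two-chain antibody + antigen "complex" of single-sphere
  pseudo-residues with Chothia-consistent CDR numbering and a designed
  6 A interface, for epitope/decoy/shell integration tests.

All generators are deterministic under their seed.  They emulate geometry
and sign structure, not real protein chemistry: pseudo-residues are rigid
spheres, charge patterns are idealised, and no attempt is made to mimic
real antibody loop conformations beyond the curvature contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .patches import SurfacePatch
from .structure_io import Atom, Structure, assign_chain_roles, write_pqr
from .zernike import DescriptorTriple, describe_patch

__all__ = [
    "make_patch", "make_complementary_pair", "make_classification_dataset",
    "make_toy_complex", "ToyComplex",
]

RESIDUE_BLOCK = 5  # surface points per pseudo-residue


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _fibonacci_cap(n_points: int, cap_angle: float) -> np.ndarray:
    """~n_points unit vectors covering the polar cap of half-angle cap_angle."""
    frac = (1.0 - math.cos(cap_angle)) / 2.0
    n_total = max(int(round(n_points / max(frac, 1e-9))), n_points)
    i = np.arange(n_total, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_total
    keep = z >= math.cos(cap_angle)
    z = z[keep]
    theta = 2.0 * math.pi * i[keep] / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _assign_pseudo_residues(points: np.ndarray) -> list[tuple[str, int, str]]:
    """Group points into spatially coherent 5-point pseudo-residues."""
    order = np.lexsort((points[:, 1], points[:, 0]))
    res_of = np.empty(len(points), dtype=int)
    res_of[order] = np.arange(len(points)) // RESIDUE_BLOCK
    return [("X", int(r) + 1, "") for r in res_of]


def _charge_values(points: np.ndarray, keys, pattern: str,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-pseudo-residue constant electrostatic values."""
    if pattern == "neutral":
        return np.zeros(len(points))
    uniq = sorted(set(keys))
    if pattern == "dipolar":
        centroids = {k: points[[i for i, kk in enumerate(keys) if kk == k]].mean(axis=0)
                     for k in uniq}
        res_val = {k: (1.0 if centroids[k][0] > 0 else -1.0) for k in uniq}
    elif pattern == "random":
        res_val = {k: float(rng.choice([-1.0, 1.0])) for k in uniq}
    elif pattern == "monopolar":
        res_val = {k: 1.0 for k in uniq}
    else:
        raise ValueError(f"unknown charge pattern {pattern!r}")
    return np.array([res_val[k] for k in keys])


def _bumpy_heights(xy: np.ndarray, rng: np.random.Generator, n_bumps: int,
                   amplitude: float, sigma_range=(1.5, 3.5),
                   extent: float = 8.0) -> np.ndarray:
    h = np.zeros(len(xy))
    for _ in range(n_bumps):
        c = rng.uniform(-0.7 * extent, 0.7 * extent, size=2)
        a = rng.uniform(-amplitude, amplitude)
        s = rng.uniform(*sigma_range)
        h += a * np.exp(-np.sum((xy - c) ** 2, axis=1) / (2.0 * s * s))
    return h


def make_patch(kind: str = "bumpy", charge_pattern: str = "neutral",
               n_points: int = 500, seed: int = 0, *,
               radius: float = 10.0, cap_angle: float = math.pi / 3.0,
               axes: tuple[float, float, float] = (12.0, 9.0, 7.0),
               extent: float = 8.0, n_bumps: int = 5,
               amplitude: float = 2.0, concave: bool = False,
               jitter: float = 0.0) -> SurfacePatch:
    """Parametric synthetic surface patch.

    ``sphere_cap``: points on a polar cap (cap_angle = pi gives the full
    sphere) of the given radius.  ``ellipsoid_cap``: the same cap scaled by
    per-axis radii.  ``bumpy``: a Gaussian-bump height field h(x, y) over a
    square of half-width ``extent``; ``concave=True`` bends the field onto a
    bowl.  Points carry per-pseudo-residue electrostatic values following
    ``charge_pattern`` (neutral / dipolar / random / monopolar).
    """
    rng = np.random.default_rng(seed)
    if kind == "sphere_cap":
        pts = radius * _fibonacci_cap(n_points, cap_angle)
    elif kind == "ellipsoid_cap":
        pts = _fibonacci_cap(n_points, cap_angle) * np.asarray(axes, float)
    elif kind == "bumpy":
        # scattered (not gridded) planar sampling, like real SAS point clouds;
        # a regular grid would alias against the voxel lattice
        xy = rng.uniform(-extent, extent, size=(n_points, 2))
        z = _bumpy_heights(xy, rng, n_bumps, amplitude, extent=extent)
        if concave:
            z = z + np.sum(xy ** 2, axis=1) / (2.0 * radius)
        pts = np.column_stack([xy, z])
    else:
        raise ValueError(f"unknown patch kind {kind!r}")
    if jitter > 0:
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    keys = _assign_pseudo_residues(pts)
    es = _charge_values(pts, keys, charge_pattern, rng)
    return SurfacePatch(positions=pts, es_values=es, residue_keys=keys,
                        kind="synthetic")


def make_complementary_pair(gap: float = 0.0, seed: int = 0,
                            n_points: int = 600, n_bumps: int = 6,
                            amplitude: float = 2.5,
                            ) -> tuple[SurfacePatch, SurfacePatch]:
    """A bumpy patch A and its mold B.

    B shares A's contact geometry offset by ``gap`` along the surface
    normal direction, carries the inverted charge pattern, and is re-posed
    by a random rigid motion -- so only rotation/translation-invariant
    descriptors can recognise the complementarity.
    """
    rng = np.random.default_rng(seed)
    a = make_patch("bumpy", charge_pattern="random", n_points=n_points,
                   seed=seed, n_bumps=n_bumps, amplitude=amplitude)
    b_pts = a.positions + np.array([0.0, 0.0, gap])
    rot = _random_rotation(rng)
    b_pts = b_pts @ rot.T + rng.uniform(-30.0, 30.0, size=3)
    b = SurfacePatch(positions=b_pts, es_values=-a.es_values,
                     residue_keys=list(a.residue_keys), kind="synthetic")
    return a, b


def make_classification_dataset(n_per_class: int = 25, seed: int = 0,
                                order_max: int = 20, dim: int = 64,
                                n_points: int = 500,
                                curvature_contrast: float = 1.0,
                                shell_fractions: tuple[float, ...] = (1.0,),
                                ) -> list:
    """Labelled two-class synthetic CDR-like dataset.

    The "protein" class emulates flat combining sites: gently bumpy,
    low-curvature fields with a balanced dipolar charge pattern.  The
    "nonprotein" class emulates concave pockets binding small antigens:
    strongly curved bowls with a predominantly single-sign charge pattern.
    ``curvature_contrast`` scales the geometric difference (0 makes the two
    classes identically distributed, a null dataset).

    Returns a list of :class:`~zernab.classify.AntibodyEntry`, with
    descriptor triples per requested shell fraction (shells are taken
    around the patch center, mimicking concentric paratope shells).
    """
    from .classify import AntibodyEntry

    rng = np.random.default_rng(seed)
    entries = []
    for label, cls_idx in (("protein", 0), ("nonprotein", 1)):
        for i in range(n_per_class):
            s = int(rng.integers(2 ** 31))
            if cls_idx == 0:
                bowl = 80.0      # nearly flat
                amp = 1.0
                pattern = "dipolar" if curvature_contrast > 0 else "random"
            else:
                bowl = 80.0 - 72.0 * curvature_contrast   # deep bowl at contrast 1
                amp = 1.0 + 1.5 * curvature_contrast
                pattern = "random"
            patch = make_patch("bumpy", charge_pattern=pattern,
                               n_points=n_points, seed=s, concave=True,
                               radius=bowl, amplitude=amp, n_bumps=4)
            descs: dict[float, DescriptorTriple] = {}
            for frac in shell_fractions:
                descs[frac] = describe_patch(_central_fraction(patch, frac),
                                             order_max=order_max, dim=dim)
            entries.append(AntibodyEntry(id=f"{label[:4]}_{i:03d}", label=label,
                                         descriptors=descs))
    return entries


def _central_fraction(patch: SurfacePatch, fraction: float) -> SurfacePatch:
    if fraction >= 1.0:
        return patch
    center = patch.positions.mean(axis=0)
    n = int(np.ceil(fraction * len(patch)))
    idx = np.sort(np.argsort(np.linalg.norm(patch.positions - center, axis=1),
                             kind="stable")[:n])
    return SurfacePatch(positions=patch.positions[idx],
                        es_values=patch.es_values[idx],
                        residue_keys=[patch.residue_keys[i] for i in idx],
                        kind="synthetic")


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    """A synthetic antibody (chains H, L) bound to a spherical antigen (A)."""

    structure: Structure   # all chains, roles assigned

    @property
    def antibody(self) -> Structure:
        return self.structure.subset(["H", "L"])

    @property
    def antigen(self) -> Structure:
        return self.structure.subset(["A"])

    def write(self, out_dir) -> tuple[Path, Path]:
        """Write antibody and antigen PQR files (plus the combined complex,
        which the role-aware CLI commands consume)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ab_path = out_dir / "toy_antibody.pqr"
        ag_path = out_dir / "toy_antigen.pqr"
        write_pqr(self.antibody, ab_path)
        write_pqr(self.antigen, ag_path)
        write_pqr(self.structure, out_dir / "toy_complex.pqr")
        return ab_path, ag_path


_CHARGE_OF = {"ASP": -0.6, "GLU": -0.6, "LYS": 0.6, "ARG": 0.6}
_AG_RESNAMES = ("ALA", "SER", "ASP", "THR", "LYS", "GLY", "ASN", "GLU")
_AB_RESNAMES = ("SER", "TYR", "ASP", "GLY", "ARG", "THR", "ASN", "TRP")

# Chothia CDR position ranges used to number the toy antibody
_TOY_CDR_NUMBERS = {
    "H": list(range(26, 33)) + list(range(52, 57)) + list(range(95, 103)),
    "L": list(range(24, 35)) + list(range(50, 57)) + list(range(89, 98)),
}
_TOY_FRAMEWORK = {"H": list(range(1, 9)), "L": list(range(1, 9))}


def make_toy_complex(seed: int = 0, n_antigen_residues: int = 60,
                     antigen_radius: float = 10.0,
                     interface_gap: float = 5.0,
                     atom_radius: float = 1.9) -> ToyComplex:
    """Build the toy two-chain antibody + antigen complex.

    The antigen is a convex shell of single-sphere pseudo-residues on a
    sphere of ``antigen_radius``, with a large core atom sealing the
    interior against the solvent probe.  The packing (60 residues of
    1.9 A spheres on a 10 A sphere) leaves each shell residue an exposed
    cap of roughly 0.35-0.55 nm^2, the solvent exposure range typical of
    surface residues on small protein antigens.  The antibody's CDR
    pseudo-residues, Chothia-numbered on chains H and L, sit on a cap
    facing the antigen's north pole at an ``interface_gap`` of 5 A, inside
    the 6 A epitope cutoff; framework residues sit further back.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1

    # antigen shell
    dirs = _fibonacci_cap(n_antigen_residues, math.pi)  # full sphere
    dirs = dirs[:n_antigen_residues]
    for i, d in enumerate(dirs):
        pos = antigen_radius * d + rng.normal(scale=0.15, size=3)
        resname = _AG_RESNAMES[i % len(_AG_RESNAMES)]
        atoms.append(Atom(serial=serial, name="CA", element="C", position=pos,
                          radius=atom_radius,
                          partial_charge=_CHARGE_OF.get(resname, 0.0),
                          residue_key=("A", i + 1, ""), residue_name=resname))
        serial += 1
    # core atom sealing the interior
    atoms.append(Atom(serial=serial, name="CB", element="C",
                      position=np.zeros(3), radius=antigen_radius - 3.0,
                      partial_charge=0.0, residue_key=("A", 999, ""),
                      residue_name="GLY"))
    serial += 1

    # antibody CDR cap above the north pole
    ab_shell = antigen_radius + interface_gap  # center-to-center to polar residues
    cap_dirs = _fibonacci_cap(64, math.radians(38.0))
    half = {}
    half["L"] = [d for d in cap_dirs if d[0] < 0]
    half["H"] = [d for d in cap_dirs if d[0] >= 0]
    for chain in ("H", "L"):
        numbers = _TOY_CDR_NUMBERS[chain]
        ds = half[chain]
        for j, num in enumerate(numbers):
            d = ds[j % len(ds)]
            pos = ab_shell * d + rng.normal(scale=0.1, size=3)
            resname = _AB_RESNAMES[(j + (chain == "L")) % len(_AB_RESNAMES)]
            atoms.append(Atom(serial=serial, name="CA", element="C",
                              position=pos, radius=atom_radius,
                              partial_charge=_CHARGE_OF.get(resname, 0.0),
                              residue_key=(chain, num, ""),
                              residue_name=resname))
            serial += 1
        # framework residues, further from the antigen
        for j, num in enumerate(_TOY_FRAMEWORK[chain]):
            ang = math.radians(44.0 + 6.0 * j)
            sgn = -1.0 if chain == "L" else 1.0
            pos = np.array([sgn * (ab_shell + 4.0) * math.sin(ang),
                            0.3 * j * sgn,
                            (ab_shell + 4.0) * math.cos(ang)])
            atoms.append(Atom(serial=serial, name="CA", element="C",
                              position=pos + rng.normal(scale=0.1, size=3),
                              radius=atom_radius, partial_charge=0.0,
                              residue_key=(chain, num, ""), residue_name="GLY"))
            serial += 1

    structure = Structure(atoms=atoms)
    structure = assign_chain_roles(structure, heavy="H", light="L", antigen=["A"])
    return ToyComplex(structure=structure)
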