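"""Solvent-accessible surface sampling, residue SASA and surface electrostatics.

The surface is sampled Shrake-Rupley style: a deterministic Fibonacci
spiral of test points on each atom's probe-inflated sphere, with points
buried inside any neighbouring inflated sphere discarded.  Surviving
points form the solvent-accessible surface (SAS) point cloud, and the
surviving fraction per atom gives its SASA.

Per-point electrostatic values follow the convention that every surface
point of a residue carries that residue's single potential value.  The
default potential is a screened Coulomb sum over all partial charges,
evaluated at the residue's side-chain centroid:

    phi(R) = sum_j q_j * exp(-d_j / lambda) / (epsilon * d_j)

with Debye-like screening length lambda = 8 A and epsilon = 80.  Only the
sign pattern of phi survives the downstream +/- voxel binarization, so any
potential source with the right sign structure is interchangeable here;
externally computed per-point potentials can be supplied instead.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueKey, Structure, SurfacePointCloud

__all__ = [
    "sample_sas", "residue_sasa", "relative_sasa", "assign_electrostatics",
    "MAX_SASA_NM2",
]

# Theoretical per-residue maximum SASA (Tien et al. style reference values),
# in nm^2, used to normalise residue SASA into relative SASA.
MAX_SASA_NM2 = {
    "ALA": 1.29, "ARG": 2.74, "ASN": 1.95, "ASP": 1.93, "CYS": 1.67,
    "GLN": 2.25, "GLU": 2.23, "GLY": 1.04, "HIS": 2.24, "ILE": 1.97,
    "LEU": 2.01, "LYS": 2.36, "MET": 2.24, "PHE": 2.40, "PRO": 1.59,
    "SER": 1.55, "THR": 1.72, "TRP": 2.85, "TYR": 2.63, "VAL": 1.74,
}

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN"}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform n-point set on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _sas_sample(structure: Structure, probe: float, points_per_atom: int):
    """Shared sampler: returns (points, point_atom_index, retained_per_atom)."""
    centers = structure.positions
    radii = structure.radii
    inflated = radii + probe
    unit = _fibonacci_sphere(points_per_atom)
    tree = cKDTree(centers)
    max_inflated = inflated.max()

    all_pts, all_atom_idx = [], []
    retained = np.zeros(len(centers), dtype=int)
    for i, (c, ri) in enumerate(zip(centers, inflated)):
        pts = c + ri * unit
        # candidate blockers: any atom whose inflated sphere can reach these points
        nbrs = [j for j in tree.query_ball_point(c, ri + max_inflated) if j != i]
        keep = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            keep &= d2 >= inflated[j] ** 2
        retained[i] = int(keep.sum())
        if retained[i]:
            all_pts.append(pts[keep])
            all_atom_idx.append(np.full(retained[i], i))
    if all_pts:
        points = np.vstack(all_pts)
        atom_idx = np.concatenate(all_atom_idx)
    else:
        points = np.empty((0, 3))
        atom_idx = np.empty(0, dtype=int)
    return points, atom_idx, retained


def sample_sas(structure: Structure, probe: float = 1.4,
               points_per_atom: int = 256) -> SurfacePointCloud:
    """Sample the solvent-accessible surface of *structure* as a point cloud.

    Every point lies on the probe-inflated sphere of its parent atom and
    carries that atom's residue key; electrostatic values start at 0.
    """
    points, atom_idx, _ = _sas_sample(structure, probe, points_per_atom)
    if len(points) == 0:
        raise ValueError("structure has no solvent-accessible surface")
    keys = [structure.atoms[i].residue_key for i in atom_idx]
    return SurfacePointCloud(positions=points, es_values=np.zeros(len(points)),
                             residue_keys=keys, probe_radius=probe,
                             source="computed")


def residue_sasa(structure: Structure, probe: float = 1.4,
                 points_per_atom: int = 256) -> dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area in nm^2.

    SASA(atom) = (retained points / sampled points) * 4 pi (r + probe)^2,
    summed over the residue's atoms; 1 nm^2 = 100 A^2.
    """
    _, _, retained = _sas_sample(structure, probe, points_per_atom)
    inflated = structure.radii + probe
    area_a2 = retained / points_per_atom * 4.0 * math.pi * inflated ** 2
    out: dict[ResidueKey, float] = {}
    for a, area in zip(structure.atoms, area_a2):
        out[a.residue_key] = out.get(a.residue_key, 0.0) + area / 100.0
    return out


def relative_sasa(structure: Structure, probe: float = 1.4,
                  points_per_atom: int = 256,
                  reference: dict[str, float] | None = None,
                  unknown_res_ref: float | None = None) -> dict[ResidueKey, float]:
    """Residue SASA divided by its per-amino-acid reference maximum.

    Unknown residue names raise unless ``unknown_res_ref`` (nm^2) supplies
    a fallback reference area.
    """
    reference = MAX_SASA_NM2 if reference is None else reference
    sasa = residue_sasa(structure, probe, points_per_atom)
    names = structure.residue_names()
    out: dict[ResidueKey, float] = {}
    for key, area in sasa.items():
        name = names[key]
        if name in reference:
            ref = reference[name]
        elif unknown_res_ref is not None:
            ref = unknown_res_ref
        else:
            raise KeyError(
                f"no reference maximum SASA for residue {name!r}; pass "
                "unknown_res_ref or extend the reference table")
        out[key] = area / ref
    return out


def _side_chain_centroid(structure: Structure, atom_indices: list[int]) -> np.ndarray:
    pos = structure.positions
    side = [i for i in atom_indices if structure.atoms[i].name.upper() not in _BACKBONE]
    idx = side if side else atom_indices
    return pos[idx].mean(axis=0)


def residue_potentials(structure: Structure, epsilon: float = 80.0,
                       screen: float = 8.0, min_distance: float = 1.0,
                       ) -> dict[ResidueKey, float]:
    """Screened-Coulomb potential of every residue at its side-chain centroid.

    Distances below ``min_distance`` (A) are clamped to avoid the
    self-interaction singularity of the residue's own atoms; this keeps the
    residue's own charge dominant without divergence.
    """
    pos = structure.positions
    q = structure.charges
    out: dict[ResidueKey, float] = {}
    for key, idx in structure.residues().items():
        center = _side_chain_centroid(structure, idx)
        d = np.linalg.norm(pos - center, axis=1)
        d = np.maximum(d, min_distance)
        out[key] = float(np.sum(q * np.exp(-d / screen) / (epsilon * d)))
    return out


def assign_electrostatics(cloud: SurfacePointCloud, structure: Structure,
                          mode: str = "residue_coulomb",
                          epsilon: float = 80.0, screen: float = 8.0,
                          per_point_values: np.ndarray | None = None,
                          ) -> SurfacePointCloud:
    """Attach electrostatic values to a surface point cloud.

    ``residue_coulomb``: each residue gets one screened-Coulomb potential
    value (see :func:`residue_potentials`) shared by all its surface points.
    ``per_point_file``: caller-supplied values, one per point, e.g. from an
    external Poisson-Boltzmann or generalized-Born calculation.
    """
    if mode == "per_point_file":
        if per_point_values is None:
            raise ValueError("per_point_file mode requires per_point_values")
        values = np.asarray(per_point_values, dtype=float)
        if values.shape != (len(cloud),):
            raise ValueError(f"expected {len(cloud)} per-point values, "
                             f"got {values.shape}")
    elif mode == "residue_coulomb":
        if cloud.source != "computed":
            raise ValueError("residue_coulomb mode requires a cloud computed "
                             "from the structure (source='computed')")
        phi = residue_potentials(structure, epsilon=epsilon, screen=screen)
        values = np.array([phi[k] for k in cloud.residue_keys])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SurfacePointCloud(positions=cloud.positions.copy(), es_values=values,
                             residue_keys=list(cloud.residue_keys),
                             probe_radius=cloud.probe_radius, source=cloud.source)
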