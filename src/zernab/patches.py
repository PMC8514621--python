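"""Surface patch extraction: CDR patches, paratope shells, native epitopes,
pivot residues and SASA-matched decoy epitopes.

All patches are residue-level selections of a surface point cloud: a
residue is in or out, and the patch carries every surface point of its
residues.  Residue-residue distance is the minimum heavy-atom pair
distance; the representative atom of a residue (for pivots and radial
cutoffs) is its C-alpha, falling back to its first atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueKey, Structure, SurfacePointCloud
from .surface import relative_sasa, residue_sasa

__all__ = [
    "SurfacePatch", "DecoyParams", "CHOTHIA_CDR_RANGES",
    "cdr_patch", "native_epitope", "pivot_residue", "generate_decoys",
    "electrostatic_extension", "shell_patch", "interface_centerpoint",
]

PATCH_KINDS = ("cdr", "shell", "epitope_geom", "epitope_elec",
               "decoy_geom", "decoy_elec", "synthetic")

#: Chothia CDR position ranges (inclusive); keys are (chain role, loop name).
CHOTHIA_CDR_RANGES: dict[str, list[tuple[str, int, int]]] = {
    "light": [("L1", 24, 34), ("L2", 50, 56), ("L3", 89, 97)],
    "heavy": [("H1", 26, 32), ("H2", 52, 56), ("H3", 95, 102)],
}


@dataclass
class SurfacePatch:
    """A residue-level subset of a surface point cloud."""

    positions: np.ndarray              # (N, 3) Angstrom
    es_values: np.ndarray              # (N,)
    residue_keys: list[ResidueKey]
    kind: str
    pivot: ResidueKey | None = None
    shell_fraction: float | None = None
    overlap_with_native: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.es_values = np.asarray(self.es_values, dtype=float)
        if self.kind not in PATCH_KINDS:
            raise ValueError(f"unknown patch kind {self.kind!r}")
        if len(self.positions) == 0:
            raise ValueError("patch must contain at least one point")
        if (self.shell_fraction is not None) != (self.kind == "shell"):
            raise ValueError("shell_fraction is present iff kind == 'shell'")
        if self.kind.startswith(("epitope", "decoy")) and self.pivot is None:
            raise ValueError(f"{self.kind} patch requires a pivot residue")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def residues(self) -> set[ResidueKey]:
        return set(self.residue_keys)


def _patch_from_residues(cloud: SurfacePointCloud, residues: set[ResidueKey],
                         kind: str, **kw) -> SurfacePatch:
    mask = np.array([k in residues for k in cloud.residue_keys])
    if not mask.any():
        raise ValueError("selected residues contribute no surface points")
    keys = [k for k, m in zip(cloud.residue_keys, mask) if m]
    return SurfacePatch(positions=cloud.positions[mask],
                        es_values=cloud.es_values[mask],
                        residue_keys=keys, kind=kind, **kw)


def _require_residue_keys(cloud: SurfacePointCloud, op: str) -> None:
    if not cloud.has_residue_keys:
        raise ValueError(f"{op} requires a point cloud with residue keys "
                         "(clouds loaded without a residue column are refused)")


# ---------------------------------------------------------------------------
# CDR patch
# ---------------------------------------------------------------------------

def cdr_patch(structure: Structure, cloud: SurfacePointCloud,
              ranges: dict[str, list[tuple[str, int, int]]] | None = None,
              include_het: bool = False) -> SurfacePatch:
    """One combined surface patch over all six (Chothia-numbered) CDR loops.

    Residues on the heavy/light chains whose author number falls in any CDR
    range are selected (insertion-coded residues such as H100A belong to the
    range of their base number).  HETATM-only residues (e.g. hapten ligands)
    are excluded unless ``include_het``.
    """
    _require_residue_keys(cloud, "cdr_patch")
    ranges = CHOTHIA_CDR_RANGES if ranges is None else ranges
    role_chains = {role: structure.chains_with_role(role) for role in ("heavy", "light")}
    if not role_chains["heavy"] and not role_chains["light"]:
        raise ValueError("no chains with heavy/light roles assigned")
    if not role_chains["light"]:
        warnings.warn("no light chain assigned; CDR patch uses heavy-chain loops only")
    if not role_chains["heavy"]:
        warnings.warn("no heavy chain assigned; CDR patch uses light-chain loops only")

    het_only = set()
    if not include_het:
        by_res: dict[ResidueKey, bool] = {}
        for a in structure.atoms:
            by_res[a.residue_key] = by_res.get(a.residue_key, True) and a.het
        het_only = {k for k, v in by_res.items() if v}

    selected: set[ResidueKey] = set()
    for role, chains in role_chains.items():
        for key in structure.residues():
            chain, num, _ = key
            if chain not in chains or key in het_only:
                continue
            if any(lo <= num <= hi for _, lo, hi in ranges[role]):
                selected.add(key)
    if not selected:
        raise ValueError("no residues fall in any CDR range; is the antibody "
                         "Chothia-numbered?")
    return _patch_from_residues(cloud, selected, kind="cdr")


# ---------------------------------------------------------------------------
# epitopes & pivots
# ---------------------------------------------------------------------------

def _min_distance_to_set(structure: Structure, query_idx: np.ndarray,
                         target_idx: np.ndarray) -> dict[ResidueKey, float]:
    """Per-residue (of query atoms) minimum heavy-atom distance to target atoms."""
    pos = structure.positions
    tree = cKDTree(pos[target_idx])
    d, _ = tree.query(pos[query_idx])
    out: dict[ResidueKey, float] = {}
    for i, dist in zip(query_idx, d):
        key = structure.atoms[i].residue_key
        out[key] = min(out.get(key, np.inf), float(dist))
    return out


def native_epitope(structure: Structure, antigen_cloud: SurfacePointCloud,
                   cutoff: float = 6.0, kind: str = "epitope_geom") -> SurfacePatch:
    """Antigen residues whose minimum inter-atomic distance to any antibody
    atom is below *cutoff* (6 A geometric, 15 A electrostatic)."""
    _require_residue_keys(antigen_cloud, "native_epitope")
    ab_idx = structure.atom_indices_for_roles("heavy", "light")
    ag_idx = structure.atom_indices_for_roles("antigen")
    if len(ab_idx) == 0 or len(ag_idx) == 0:
        raise ValueError("structure needs both antibody (heavy/light) and "
                         "antigen chain roles")
    dmin = _min_distance_to_set(structure, ag_idx, ab_idx)
    selected = {k for k, d in dmin.items() if d < cutoff}
    if not selected:
        raise ValueError(f"no contact at cutoff {cutoff} A")
    patch = _patch_from_residues(antigen_cloud, selected, kind=kind,
                                 pivot=("", 0, "tmp"))
    patch.pivot = pivot_residue(patch, structure)
    return patch


def _representative_positions(structure: Structure,
                              residues: list[ResidueKey]) -> np.ndarray:
    """C-alpha position per residue, falling back to the first atom."""
    res_atoms = structure.residues()
    pos = structure.positions
    out = []
    for key in residues:
        idx = res_atoms[key]
        ca = [i for i in idx if structure.atoms[i].name.upper() == "CA"]
        out.append(pos[ca[0] if ca else idx[0]])
    return np.array(out)


def pivot_residue(patch: SurfacePatch, structure: Structure) -> ResidueKey:
    """The patch residue with the lowest mean representative-atom distance
    to all patch residues."""
    residues = sorted(patch.residues)
    rep = _representative_positions(structure, residues)
    d = np.linalg.norm(rep[:, None, :] - rep[None, :, :], axis=-1)
    return residues[int(np.argmin(d.mean(axis=1)))]


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoyParams:
    """Decoy-generation constraints.

    The pivot window defaults to SASA = 0.48 +/- 0.33 nm^2 (mean and sd of
    native-epitope pivot SASA) with a half-sd acceptance window; growth adds
    solvent-exposed residues (relative SASA > 0.2) until the decoy reaches
    the native patch's global SASA; decoys overlapping the native epitope by
    more than 50% are rejected and resampled.
    """

    pivot_sasa_mean: float = 0.48        # nm^2
    pivot_sasa_sd: float = 0.33          # nm^2
    pivot_window_halfwidth: float = 0.5  # in sd units
    rsasa_min: float = 0.2
    max_overlap: float = 0.5
    elec_radius: float = 15.0            # Angstrom

    def __post_init__(self):
        for name in ("pivot_sasa_mean", "pivot_sasa_sd", "pivot_window_halfwidth",
                     "rsasa_min", "max_overlap", "elec_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_overlap > 1:
            raise ValueError("max_overlap must be <= 1")

    @property
    def pivot_window(self) -> tuple[float, float]:
        hw = self.pivot_window_halfwidth * self.pivot_sasa_sd
        return (self.pivot_sasa_mean - hw, self.pivot_sasa_mean + hw)


def _patch_overlap(a: set[ResidueKey], b: set[ResidueKey]) -> float:
    """Residue overlap as |A & B| / min(|A|, |B|) (the strictest convention)."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def generate_decoys(antigen: Structure, cloud: SurfacePointCloud,
                    native: SurfacePatch, params: DecoyParams | None = None,
                    n_decoys: int = 10, seed: int = 0,
                    max_attempts: int = 1000,
                    probe: float = 1.4) -> list[SurfacePatch]:
    """SASA-matched decoy epitopes on the antigen surface.

    Each decoy starts from a pivot drawn uniformly among solvent-exposed
    residues whose SASA lies in the pivot window, grows by repeatedly adding
    the spatially nearest not-yet-included residue with relative SASA above
    ``rsasa_min`` until the decoy's summed SASA first reaches the native
    patch's, and is rejected (and resampled) if its residue overlap with the
    native epitope exceeds ``max_overlap``.  Deterministic under ``seed``.
    """
    if native.pivot is None:
        raise ValueError("native patch has no pivot residue")
    _require_residue_keys(cloud, "generate_decoys")
    params = DecoyParams() if params is None else params

    sasa = residue_sasa(antigen, probe=probe)
    rsasa = relative_sasa(antigen, probe=probe, unknown_res_ref=None
                          if _all_standard(antigen) else 1.5)
    lo, hi = params.pivot_window
    eligible = sorted(k for k, s in sasa.items()
                      if lo <= s <= hi and rsasa.get(k, 0.0) > params.rsasa_min)
    if not eligible:
        raise ValueError(f"no residue has SASA in the pivot window "
                         f"[{lo:.3f}, {hi:.3f}] nm^2")
    growable = {k for k, r in rsasa.items() if r > params.rsasa_min}
    native_res = native.residues
    native_sasa = sum(sasa.get(k, 0.0) for k in native_res)
    total_growable_sasa = sum(sasa[k] for k in growable)
    if total_growable_sasa < native_sasa:
        raise ValueError("antigen exposed surface is too small to match the "
                         "native epitope SASA")

    all_keys = sorted(growable)
    rep = _representative_positions(antigen, all_keys)
    key_index = {k: i for i, k in enumerate(all_keys)}

    rng = np.random.default_rng(seed)
    decoys: list[SurfacePatch] = []
    for _ in range(n_decoys):
        for attempt in range(1, max_attempts + 1):
            pivot = eligible[rng.integers(len(eligible))]
            members = {pivot}
            total = sasa[pivot]
            # grow nearest-to-current-patch-first (representative-atom
            # distance), until the native SASA is first crossed
            in_patch = np.zeros(len(all_keys), dtype=bool)
            in_patch[key_index[pivot]] = True
            dmin = np.linalg.norm(rep - rep[key_index[pivot]], axis=1)
            while total < native_sasa:
                dview = np.where(in_patch, np.inf, dmin)
                j = int(np.argmin(dview))
                if not np.isfinite(dview[j]):
                    break  # no growable residue left
                in_patch[j] = True
                members.add(all_keys[j])
                total += sasa[all_keys[j]]
                dmin = np.minimum(dmin, np.linalg.norm(rep - rep[j], axis=1))
            if total < native_sasa:
                continue  # could not reach target from this pivot
            overlap = _patch_overlap(members, native_res)
            if overlap > params.max_overlap:
                continue
            try:
                patch = _patch_from_residues(cloud, members, kind="decoy_geom",
                                             pivot=pivot,
                                             overlap_with_native=overlap)
            except ValueError:
                continue
            decoys.append(patch)
            break
        else:
            raise RuntimeError(f"decoy resampling budget exhausted after "
                               f"{max_attempts} attempts "
                               f"({len(decoys)}/{n_decoys} decoys generated)")
    return decoys


def _all_standard(structure: Structure) -> bool:
    from .surface import MAX_SASA_NM2
    return all(n in MAX_SASA_NM2 for n in structure.residue_names().values())


def electrostatic_extension(decoy: SurfacePatch, structure: Structure,
                            cloud: SurfacePointCloud,
                            radius: float = 15.0,
                            charged_only: bool = False,
                            charge_threshold: float = 0.1) -> SurfacePatch:
    """Extend a geometric patch for the electrostatic channel by adding the
    residues within *radius* of the pivot's representative atom (optionally
    only residues with net |charge| above ``charge_threshold``)."""
    if decoy.pivot is None:
        raise ValueError("patch has no pivot residue")
    _require_residue_keys(cloud, "electrostatic_extension")
    all_keys = sorted(structure.residues())
    rep = _representative_positions(structure, all_keys)
    pivot_pos = _representative_positions(structure, [decoy.pivot])[0]
    d = np.linalg.norm(rep - pivot_pos, axis=1)
    extra = {k for k, dist in zip(all_keys, d) if dist <= radius}
    if charged_only:
        res_atoms = structure.residues()
        charges = structure.charges
        extra = {k for k in extra
                 if abs(charges[res_atoms[k]].sum()) > charge_threshold}
    members = decoy.residues | extra
    kind = "epitope_elec" if decoy.kind.startswith("epitope") else "decoy_elec"
    return _patch_from_residues(cloud, members, kind=kind, pivot=decoy.pivot,
                                overlap_with_native=decoy.overlap_with_native)


# ---------------------------------------------------------------------------
# paratope shells
# ---------------------------------------------------------------------------

def interface_centerpoint(structure: Structure, n_atoms: int = 10) -> np.ndarray:
    """Centroid b of the *n_atoms* antibody atoms closest to any antigen atom."""
    ab_idx = structure.atom_indices_for_roles("heavy", "light")
    ag_idx = structure.atom_indices_for_roles("antigen")
    if len(ab_idx) == 0 or len(ag_idx) == 0:
        raise ValueError("interface centerpoint needs antibody and antigen roles")
    pos = structure.positions
    tree = cKDTree(pos[ag_idx])
    d, _ = tree.query(pos[ab_idx])
    nearest = ab_idx[np.argsort(d, kind="stable")[:n_atoms]]
    return pos[nearest].mean(axis=0)


def shell_patch(cdr: SurfacePatch, center: np.ndarray,
                fraction: float) -> SurfacePatch:
    """The ``ceil(fraction * N)`` CDR surface points nearest to the interface
    centerpoint *b*; fraction 1.0 reproduces the full CDR patch."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    center = np.asarray(center, dtype=float)
    n = int(np.ceil(fraction * len(cdr)))
    d = np.linalg.norm(cdr.positions - center, axis=1)
    idx = np.argsort(d, kind="stable")[:n]
    idx = np.sort(idx)
    return SurfacePatch(positions=cdr.positions[idx],
                        es_values=cdr.es_values[idx],
                        residue_keys=[cdr.residue_keys[i] for i in idx],
                        kind="shell", shell_fraction=fraction)
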