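"""3D Zernike moments and rotation-invariant descriptors.

A scalar field f on the unit ball is expanded in the orthonormal Zernike
basis Z_nlm(r, theta, phi) = R_nl(r) Y_lm(theta, phi), where Y_lm are
complex spherical harmonics (Condon-Shortley phase) and R_nl is the radial
polynomial with even n - l, normalised so that the basis is orthonormal
over the unit ball.  The expansion coefficients

    C_nlm = integral_{|r| <= 1} f(r) conj(Z_nlm) dr

are computed two ways:

* :func:`zernike_moments` — the production path.  Geometric (monomial)
  moments of the voxel field are accumulated by separable tensor
  contractions, then combined with a cached monomial-coefficient table of
  the Zernike polynomials.  The radial coefficients come from exact
  rational Gram-Schmidt orthonormalisation of {r^l, r^{l+2}, ...}, and the
  angular part from the Cartesian expansion of the solid harmonics
  r^l Y_lm.
* :func:`moments_oracle` — a direct Riemann sum over voxel centers with
  the basis evaluated pointwise from Jacobi polynomials and SciPy's
  spherical harmonics.  Deliberately independent of the production path;
  used as the reference in tests.

The rotation invariants are the per-(n, l) norms

    D_nl = sqrt( sum_m |C_nlm|^2 )

ordered lexicographically in (n, l) with l <= n and n - l even, so a
higher-order descriptor vector has every lower-order vector as a prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import eval_jacobi, sph_harm_y

from .voxelize import VoxelGrid, fit_to_unit_sphere, voxelize_electrostatics, voxelize_shape

__all__ = [
    "descriptor_length", "nl_pairs", "ZernikeMoments", "ZernikeDescriptor",
    "DescriptorTriple", "zernike_moments", "moments_oracle", "invariants",
    "describe_patch", "descriptor_from_values",
]

#: maximum expansion order accepted by default; beyond this the float64
#: monomial-moment route loses accuracy
MAX_STABLE_ORDER = 46


def nl_pairs(order_max: int) -> list[tuple[int, int]]:
    """Lexicographic (n, l) index pairs with l <= n and n - l even."""
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    return [(n, l) for n in range(order_max + 1)
            for l in range(n % 2, n + 1, 2)]


def descriptor_length(order_max: int) -> int:
    """Number of invariants D_nl up to order_max: sum_n (floor(n/2) + 1)."""
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    return sum(n // 2 + 1 for n in range(order_max + 1))


# ---------------------------------------------------------------------------
# basis coefficient tables (production path)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _radial_coefficients(l: int, k_max: int) -> tuple[tuple[float, ...], ...]:
    """Coefficients c_v of R_nl(r) = sum_v c_v r^(l + 2v) for k = 0..k_max
    (n = l + 2k), from exact rational Gram-Schmidt with weight r^2 on [0, 1].

    Monic orthogonal polynomials are built exactly in Fractions, then
    normalised to unit norm; the leading coefficient is positive.
    """
    # polynomials as dicts {power v: Fraction} over r^(l+2v)
    def inner(p, q):
        return sum(cp * cq * Fraction(1, l + 2 * a + l + 2 * b + 3)
                   for a, cp in p.items() for b, cq in q.items())

    basis: list[dict[int, Fraction]] = []
    norms: list[Fraction] = []
    out = []
    for k in range(k_max + 1):
        v = {k: Fraction(1)}
        for u, n2 in zip(basis, norms):
            c = inner(v, u) / n2
            for a, cu in u.items():
                v[a] = v.get(a, Fraction(0)) - c * cu
        n2 = inner(v, v)
        basis.append(v)
        norms.append(n2)
        s = 1.0 / math.sqrt(float(n2))
        out.append(tuple(float(v.get(a, Fraction(0))) * s for a in range(k + 1)))
    return tuple(out)


@lru_cache(maxsize=None)
def _solid_harmonic_monomials(l: int, m: int) -> tuple[tuple[tuple[int, int, int], complex], ...]:
    """Monomial expansion of r^l Y_lm (m >= 0) as ((a, b, c), coeff) pairs.

    Uses the Cartesian expansion of the Racah solid harmonic

        r^l Y_lm = sqrt((2l+1)/(4 pi)) * sqrt((l+m)! (l-m)!) *
                   sum_{p+q+s=l, p-q=m} (-(x+iy)/2)^p ((x-iy)/2)^q z^s / (p! q! s!)

    which carries the Condon-Shortley phase.
    """
    assert 0 <= m <= l
    pref = math.sqrt((2 * l + 1) / (4 * math.pi)) * math.sqrt(
        math.factorial(l + m) * math.factorial(l - m))
    coeffs: dict[tuple[int, int, int], complex] = {}
    for p in range(m, l + 1):
        q = p - m
        s = l - p - q
        if s < 0:
            break
        c0 = pref * (-0.5) ** p * 0.5 ** q / (
            math.factorial(p) * math.factorial(q) * math.factorial(s))
        # expand (x + iy)^p (x - iy)^q z^s
        for u in range(p + 1):
            for v in range(q + 1):
                a = u + v                      # power of x
                b = (p - u) + (q - v)          # power of y
                c = c0 * math.comb(p, u) * math.comb(q, v) \
                    * (1j) ** (p - u) * (-1j) ** (q - v)
                key = (a, b, s)
                coeffs[key] = coeffs.get(key, 0.0 + 0.0j) + c
    return tuple((k, v) for k, v in coeffs.items() if v != 0)


@lru_cache(maxsize=None)
def _r2_power_monomials(v: int) -> tuple[tuple[tuple[int, int, int], float], ...]:
    """Monomials of (x^2 + y^2 + z^2)^v with multinomial coefficients."""
    out = []
    for a in range(v + 1):
        for b in range(v - a + 1):
            c = v - a - b
            coef = math.factorial(v) / (
                math.factorial(a) * math.factorial(b) * math.factorial(c))
            out.append(((2 * a, 2 * b, 2 * c), float(coef)))
    return tuple(out)


@lru_cache(maxsize=None)
def _zernike_monomials(n: int, l: int, m: int):
    """Sparse monomial representation of Z_nlm (m >= 0): (idx array, coeff array)."""
    k = (n - l) // 2
    radial = _radial_coefficients(l, k)[k]
    harm = _solid_harmonic_monomials(l, m)
    coeffs: dict[tuple[int, int, int], complex] = {}
    for v, cv in enumerate(radial):
        if cv == 0.0:
            continue
        for (ra, rb, rc), cr in _r2_power_monomials(v):
            for (ha, hb, hc), ch in harm:
                key = (ra + ha, rb + hb, rc + hc)
                coeffs[key] = coeffs.get(key, 0.0 + 0.0j) + cv * cr * ch
    idx = np.array(list(coeffs.keys()), dtype=int)
    vals = np.array(list(coeffs.values()), dtype=complex)
    return idx, vals


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

@dataclass
class ZernikeMoments:
    """Complex moments C_nlm for m >= 0 (m < 0 follows from conjugate symmetry:
    C_nl(-m) = (-1)^m conj(C_nlm) for real fields)."""

    order_max: int
    data: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    channel: str | None = None

    def get(self, n: int, l: int, m: int) -> complex:
        arr = self.data[(n, l)]
        if m >= 0:
            return complex(arr[m])
        return (-1) ** (-m) * complex(np.conj(arr[-m]))


def _geometric_moments(grid: VoxelGrid, order_max: int) -> np.ndarray:
    """Monomial moments M[a, b, c] = integral over the unit ball of
    f * x^a y^b z^c, by separable contraction over voxel centers."""
    dim = grid.dim
    x = grid.voxel_centers_1d()
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij", sparse=True)
    mask = (xx ** 2 + yy ** 2 + zz ** 2) <= 1.0
    f = np.where(mask, grid.values, 0.0)
    powers = np.vander(x, order_max + 1, increasing=True)  # (dim, N+1)
    t1 = np.tensordot(powers, f, axes=(0, 0))              # (N+1, dim, dim)
    t2 = np.einsum("ajk,jb->abk", t1, powers)              # (N+1, N+1, dim)
    m = np.einsum("abk,kc->abc", t2, powers)               # (N+1, N+1, N+1)
    return m * grid.edge ** 3


def zernike_moments(grid: VoxelGrid, order_max: int) -> ZernikeMoments:
    """Zernike moments of a voxel grid up to ``order_max`` (production path)."""
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    if order_max > MAX_STABLE_ORDER:
        raise ValueError(f"order_max {order_max} beyond stability bound "
                         f"{MAX_STABLE_ORDER}")
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values")
    geo = _geometric_moments(grid, order_max)
    out = ZernikeMoments(order_max=order_max, channel=grid.channel)
    for n, l in nl_pairs(order_max):
        arr = np.zeros(l + 1, dtype=complex)
        for m in range(l + 1):
            idx, vals = _zernike_monomials(n, l, m)
            arr[m] = np.sum(np.conj(vals) * geo[idx[:, 0], idx[:, 1], idx[:, 2]])
        out.data[(n, l)] = arr
    return out


def moments_oracle(grid: VoxelGrid, order_max: int) -> ZernikeMoments:
    """Direct Riemann-sum moments: per (n, l, m), sum over voxel centers
    inside the unit ball of f * conj(Z_nlm) * voxel volume, with the basis
    evaluated pointwise (Jacobi radial polynomial x SciPy spherical
    harmonics).  Test-only reference; independent of the monomial route."""
    x = grid.voxel_centers_1d()
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
    inside = (r <= 1.0) & (grid.values != 0)
    f = grid.values[inside]
    rr = r[inside]
    theta = np.arccos(np.clip(np.divide(zz[inside], rr, out=np.zeros_like(rr),
                                        where=rr > 0), -1.0, 1.0))
    phi = np.arctan2(yy[inside], xx[inside])
    voxvol = grid.edge ** 3
    out = ZernikeMoments(order_max=order_max, channel=grid.channel)
    for n, l in nl_pairs(order_max):
        k = (n - l) // 2
        # R_nl(r) = sqrt(2n + 3) r^l P_k^(0, l + 1/2)(2 r^2 - 1): unit norm
        # against weight r^2 on [0, 1], positive leading coefficient
        radial = math.sqrt(2 * n + 3) * rr ** l * eval_jacobi(
            k, 0.0, l + 0.5, 2.0 * rr ** 2 - 1.0)
        arr = np.zeros(l + 1, dtype=complex)
        for m in range(l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            arr[m] = np.sum(f * radial * np.conj(ylm)) * voxvol
        out.data[(n, l)] = arr
    return out


# ---------------------------------------------------------------------------
# invariants & descriptors
# ---------------------------------------------------------------------------

@dataclass
class ZernikeDescriptor:
    """Rotation-invariant descriptor vector D_nl, lexicographic in (n, l)."""

    order_max: int
    values: np.ndarray
    channel: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (descriptor_length(self.order_max),):
            raise ValueError("descriptor length does not match order_max")
        if np.any(self.values < 0):
            raise ValueError("invariants must be non-negative")

    @property
    def nl(self) -> list[tuple[int, int]]:
        return nl_pairs(self.order_max)

    def truncate(self, order_max: int) -> "ZernikeDescriptor":
        """Descriptor at a lower order: a prefix of the (n, l)-ordered vector."""
        if order_max > self.order_max:
            raise ValueError("cannot truncate to a higher order")
        return ZernikeDescriptor(order_max=order_max,
                                 values=self.values[:descriptor_length(order_max)],
                                 channel=self.channel)

    def __len__(self) -> int:
        return len(self.values)


def descriptor_from_values(values, order_max: int,
                           channel: str | None = None) -> ZernikeDescriptor:
    """Build a descriptor from a raw (n, l)-ordered non-negative vector."""
    return ZernikeDescriptor(order_max=order_max, values=np.asarray(values, float),
                             channel=channel)


def invariants(moments: ZernikeMoments) -> ZernikeDescriptor:
    """D_nl = sqrt(sum_m |C_nlm|^2), using conjugate symmetry for m < 0."""
    vals = []
    for n, l in nl_pairs(moments.order_max):
        arr = moments.data[(n, l)]
        s = abs(arr[0]) ** 2 + 2.0 * np.sum(np.abs(arr[1:]) ** 2)
        vals.append(math.sqrt(s))
    return ZernikeDescriptor(order_max=moments.order_max,
                             values=np.array(vals), channel=moments.channel)


@dataclass
class DescriptorTriple:
    """Shape + positive/negative electrostatic descriptors of one patch."""

    shape: ZernikeDescriptor
    elec_pos: ZernikeDescriptor
    elec_neg: ZernikeDescriptor

    @property
    def order_max(self) -> int:
        return self.shape.order_max

    def truncate(self, order_max: int) -> "DescriptorTriple":
        return DescriptorTriple(self.shape.truncate(order_max),
                                self.elec_pos.truncate(order_max),
                                self.elec_neg.truncate(order_max))


def describe_patch(patch, order_max: int = 20, dim: int = 128,
                   es_mode: str = "binary", fill: float = 0.8,
                   reach: float = 1.7) -> DescriptorTriple:
    """Full patch-to-descriptors pipeline: unit-sphere fit, voxelization of
    the shape and +/- electrostatic channels, moments, invariants."""
    scaled, record = fit_to_unit_sphere(patch.positions, fill=fill)
    shape_grid = voxelize_shape(scaled, dim=dim, reach=reach, scale_record=record)
    pos_grid, neg_grid = voxelize_electrostatics(scaled, patch.es_values, dim=dim,
                                                 mode=es_mode, scale_record=record)
    return DescriptorTriple(
        shape=invariants(zernike_moments(shape_grid, order_max)),
        elec_pos=invariants(zernike_moments(pos_grid, order_max)),
        elec_neg=invariants(zernike_moments(neg_grid, order_max)),
    )
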