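"""Rotation-invariant 3D Zernike descriptors of voxelized scalar fields.

A scalar function sampled on a cubic grid inside the unit ball is expanded
in the Zernike-Canterakis basis; the per-(n,l) norms of the moment vectors
are invariant under rotation and form the descriptor.

The moments are computed through geometric (monomial) moments and the
Cartesian polynomial expansion of the basis functions, which is exact and
much faster than evaluating the basis at every voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "VoxelGrid",
    "ZernikeMoments",
    "ZernikeDescriptor",
    "descriptor_length",
    "valid_nl_pairs",
    "voxelize_points",
    "voxelize_channels",
    "zernike_moments",
    "zernike_invariants",
    "compute_descriptor",
    "save_descriptors_text",
    "load_descriptors_text",
    "save_descriptors_npz",
    "load_descriptors_npz",
]

MAX_ORDER = 20


# ---------------------------------------------------------------------------
# domain types


@dataclass
class VoxelGrid:
    """Cubic scalar field.

    ``values[i, j, k]`` is the sample at the voxel whose center, in
    normalized coordinates, is ``(i + 0.5 - dim/2) * (2/dim)`` (and likewise
    for j, k): the grid spans ``[-1, 1]^3`` with the unit ball inscribed.
    ``spacing`` and ``origin`` record the world-coordinate (angstrom)
    placement of the grid for provenance; they do not affect moments.
    """

    dim: int
    spacing: float
    origin: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.dim, self.dim, self.dim):
            raise ValueError(
                f"values shape {self.values.shape} does not match dim {self.dim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        self.origin = np.asarray(self.origin, dtype=float)

    def axis_coords(self) -> np.ndarray:
        """Normalized voxel-center coordinates along one axis."""
        return (np.arange(self.dim) + 0.5 - self.dim / 2.0) * (2.0 / self.dim)

    def voxel_volume(self) -> float:
        return (2.0 / self.dim) ** 3

    def max_nonzero_radius(self) -> float:
        c = self.axis_coords()
        r2 = c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2
        nz = self.values != 0.0
        if not nz.any():
            return 0.0
        return float(np.sqrt(r2[nz].max()))


@dataclass
class ZernikeMoments:
    """Complex moments Omega_nlm for all valid (n, l, m) up to ``order``."""

    order: int
    entries: dict = field(default_factory=dict)

    def __getitem__(self, key) -> complex:
        n, l, m = key
        _check_nlm(n, l, m, self.order)
        return self.entries[(n, l, m)]

    def check_conjugate_symmetry(self, tol: float = 1e-10) -> bool:
        scale = max(abs(v) for v in self.entries.values()) or 1.0
        for (n, l, m), v in self.entries.items():
            if m < 0:
                continue
            w = self.entries[(n, l, -m)]
            if abs(w - ((-1) ** m) * np.conj(v)) > tol * scale:
                return False
        return True


@dataclass
class ZernikeDescriptor:
    """Vector of invariants F_nl in fixed (n ascending, l ascending) order."""

    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = descriptor_length(self.order)
        if self.values.shape != (expected,):
            raise ValueError(
                f"descriptor for order {self.order} must have length {expected}, "
                f"got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("invariants are vector norms and must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _check_nlm(n: int, l: int, m: int, order: int) -> None:
    if not (0 <= n <= order and 0 <= l <= n and (n - l) % 2 == 0 and -l <= m <= l):
        raise KeyError(f"invalid (n, l, m) = ({n}, {l}, {m}) for order {order}")


def valid_nl_pairs(order: int) -> list:
    """All (n, l) with 0 <= l <= n <= order and (n - l) even, in fixed order."""
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def descriptor_length(order: int) -> int:
    """Number of (n, l) invariant components for a given maximum order."""
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    return sum(n // 2 + 1 for n in range(order + 1))


# ---------------------------------------------------------------------------
# voxelization


def _normalize_points(points: np.ndarray, ball_fill: float):
    centroid = points.mean(axis=0)
    centered = points - centroid
    rmax = float(np.sqrt((centered**2).sum(axis=1).max()))
    scale = ball_fill / rmax if rmax > 0 else 1.0
    return centered * scale, centroid, scale


def voxelize_channels(
    points: np.ndarray,
    channels: np.ndarray,
    dim: int = 64,
    ball_fill: float = 0.7,
) -> list:
    """Voxelize several per-point value channels on a shared grid geometry.

    Each point is assigned to its nearest voxel; points landing in the same
    voxel have their values averaged. Returns one VoxelGrid per channel row.
    """
    points = np.asarray(points, dtype=float)
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] == 0:
        raise ValueError("points must be a nonempty (N, 3) array")
    if not np.all(np.isfinite(points)):
        raise ValueError("point coordinates must be finite")
    if channels.shape[1] != points.shape[0]:
        raise ValueError("each channel needs one value per point")
    if dim < 8:
        raise ValueError(f"dim must be >= 8, got {dim}")
    if not 0 < ball_fill <= 1:
        raise ValueError(f"ball_fill must be in (0, 1], got {ball_fill}")

    scaled, centroid, scale = _normalize_points(points, ball_fill)
    # nearest voxel: invert center coordinate (i + 0.5 - dim/2) * 2/dim
    idx = np.floor(scaled * (dim / 2.0) + dim / 2.0).astype(int)
    idx = np.clip(idx, 0, dim - 1)
    flat = idx[:, 0] * dim * dim + idx[:, 1] * dim + idx[:, 2]
    counts = np.bincount(flat, minlength=dim**3).astype(float)
    occupied = counts > 0

    spacing = (2.0 / dim) / scale if scale > 0 else 2.0 / dim
    origin = centroid - (dim / 2.0) * spacing

    grids = []
    for ch in channels:
        sums = np.bincount(flat, weights=ch, minlength=dim**3)
        vals = np.zeros(dim**3)
        vals[occupied] = sums[occupied] / counts[occupied]
        grids.append(
            VoxelGrid(dim=dim, spacing=spacing, origin=origin,
                      values=vals.reshape(dim, dim, dim))
        )
    return grids


def voxelize_points(
    points: np.ndarray,
    values: np.ndarray = None,
    dim: int = 64,
    ball_fill: float = 0.7,
) -> VoxelGrid:
    """Map scattered points into a unit-ball-normalized cubic grid.

    The grid is centered on the point centroid and scaled so the farthest
    point sits at radius ``ball_fill``. ``values`` defaults to 1 per point
    (binary shape channel).
    """
    points = np.asarray(points, dtype=float)
    if values is None:
        values = np.ones(len(points))
    return voxelize_channels(points, np.asarray(values)[None, :], dim, ball_fill)[0]


# ---------------------------------------------------------------------------
# Cartesian polynomial expansion of the Zernike-Canterakis basis
#
# Z_nlm(x) = sum_nu q[k,l,nu] * |x|^(2 nu) * r^l Y_lm(x),  k = (n - l) / 2,
# with the solid harmonic r^l Y_lm expanded into monomials x^r y^s z^t.
# Rational parts are carried as exact Fractions; a single irrational
# prefactor per (n, l, m) is applied in floating point at the end.


def _binom(a: int, b: int) -> int:
    return math.comb(a, b) if 0 <= b <= a else 0


@lru_cache(maxsize=None)
def _chi_coefficients(n: int, l: int, m: int):
    """Monomial coefficients chi[(r,s,t)] of Z_nlm, m >= 0.

    Returns (exponents (K,3) int array, complex coefficient array (K,)).
    """
    assert m >= 0
    k = (n - l) // 2

    # irrational prefactor: sqrt((2l+1)/(4 pi)) * sqrt((l+m)!(l-m)!)
    #                       * sqrt((2n+3)/3)
    pref = math.sqrt((2 * l + 1) / (4.0 * math.pi))
    pref *= math.sqrt(float(math.factorial(l + m)) * float(math.factorial(l - m)))
    pref *= math.sqrt((2 * n + 3) / 3.0)

    acc: dict = {}

    def add(r: int, s: int, t: int, re: Fraction, im: Fraction) -> None:
        key = (r, s, t)
        cre, cim = acc.get(key, (Fraction(0), Fraction(0)))
        acc[key] = (cre + re, cim + im)

    # i^p as (re, im) Fractions
    ipow = [(Fraction(1), Fraction(0)), (Fraction(0), Fraction(1)),
            (Fraction(-1), Fraction(0)), (Fraction(0), Fraction(-1))]

    for nu in range(k + 1):
        q_rat = (
            Fraction((-1) ** (k + nu), 4**k)
            * _binom(2 * k, k)
            * _binom(k, nu)
            * _binom(2 * (k + l + nu) + 1, 2 * k)
            / _binom(k + l + nu, k)
        )
        # (x^2 + y^2 + z^2)^nu -> trinomial
        for a in range(nu + 1):
            for b in range(nu - a + 1):
                g = nu - a - b
                tri = Fraction(math.factorial(nu),
                               math.factorial(a) * math.factorial(b) * math.factorial(g))
                # solid harmonic r^l Y_lm (m >= 0), Condon-Shortley phase:
                # sum_j (-(x+iy)/2)^(m+j) ((x-iy)/2)^j z^(l-m-2j)
                #       / ((m+j)! j! (l-m-2j)!)
                for j in range((l - m) // 2 + 1):
                    denom = Fraction(
                        1,
                        math.factorial(m + j) * math.factorial(j)
                        * math.factorial(l - m - 2 * j),
                    )
                    base = q_rat * tri * denom * Fraction((-1) ** (m + j), 2 ** (m + 2 * j))
                    tz = l - m - 2 * j
                    # (x + iy)^(m+j) (x - iy)^j
                    for p in range(m + j + 1):
                        c1 = _binom(m + j, p)  # x^p (iy)^(m+j-p)
                        for u in range(j + 1):
                            c2 = _binom(j, u)  # x^u (-iy)^(j-u)
                            ppow = (m + j - p) + (j - u)  # total power of i
                            sgn = (-1) ** (j - u)
                            re_i, im_i = ipow[ppow % 4]
                            coef = base * c1 * c2 * sgn
                            add(2 * a + p + u, 2 * b + (m + j - p) + (j - u), 2 * g + tz,
                                coef * re_i, coef * im_i)

    exps = np.array(sorted(acc.keys()), dtype=int).reshape(-1, 3)
    coefs = np.array(
        [complex(float(acc[tuple(e)][0]), float(acc[tuple(e)][1])) * pref
         for e in exps]
    )
    keep = coefs != 0
    return exps[keep], coefs[keep]


def geometric_moments(grid: VoxelGrid, order: int) -> np.ndarray:
    """Monomial moments M[r, s, t] = sum f * x^r y^s z^t * dV, r+s+t <= order."""
    c = grid.axis_coords()
    powers = c[None, :] ** np.arange(order + 1)[:, None]  # (order+1, dim)
    m = np.einsum("ri,sj,tk,ijk->rst", powers, powers, powers, grid.values,
                  optimize=True)
    return m * grid.voxel_volume()


def zernike_moments(grid: VoxelGrid, order: int = 15) -> ZernikeMoments:
    """3D Zernike moments of a unit-ball-normalized grid, up to ``order``.

    Rejects grids with nonzero voxels outside the unit ball (the expansion
    is only defined inside it).
    """
    if order < 0 or order > MAX_ORDER:
        raise ValueError(f"order must be in [0, {MAX_ORDER}], got {order}")
    rmax = grid.max_nonzero_radius()
    if rmax > 1.0 + 1e-9:
        raise ValueError(
            f"grid is not unit-ball normalized: nonzero voxel at radius {rmax:.4f}"
        )
    moments = geometric_moments(grid, order)
    entries: dict = {}
    for n, l in valid_nl_pairs(order):
        for m in range(l + 1):
            exps, coefs = _chi_coefficients(n, l, m)
            vals = moments[exps[:, 0], exps[:, 1], exps[:, 2]]
            om = (3.0 / (4.0 * math.pi)) * np.sum(np.conj(coefs) * vals)
            entries[(n, l, m)] = complex(om)
            if m > 0:
                entries[(n, l, -m)] = ((-1) ** m) * complex(np.conj(om))
    return ZernikeMoments(order=order, entries=entries)


def zernike_invariants(moments: ZernikeMoments) -> ZernikeDescriptor:
    """Descriptor F_nl = || (Omega_nlm)_m ||_2 for each valid (n, l)."""
    vals = []
    for n, l in valid_nl_pairs(moments.order):
        s = sum(abs(moments.entries[(n, l, m)]) ** 2 for m in range(-l, l + 1))
        vals.append(math.sqrt(s))
    return ZernikeDescriptor(order=moments.order, values=np.array(vals))


def compute_descriptor(grid: VoxelGrid, order: int = 15) -> ZernikeDescriptor:
    """Moments + invariants in one call."""
    return zernike_invariants(zernike_moments(grid, order))


# ---------------------------------------------------------------------------
# serialization: one descriptor per row, header records order and channel


def save_descriptors_text(path, descriptors, channel: str = "shape") -> None:
    descriptors = list(descriptors)
    if not descriptors:
        raise ValueError("nothing to save")
    order = descriptors[0].order
    if any(d.order != order for d in descriptors):
        raise ValueError("all descriptors in one file must share an order")
    with open(path, "w") as fh:
        fh.write(f"# order={order} channel={channel} length={len(descriptors[0])}\n")
        for d in descriptors:
            fh.write(" ".join(repr(float(v)) for v in d.values) + "\n")


def load_descriptors_text(path):
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing descriptor header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        order = int(meta["order"])
        descs = [
            ZernikeDescriptor(order=order,
                              values=np.array([float(t) for t in line.split()]))
            for line in fh
            if line.strip()
        ]
    return descs, meta["channel"]


def save_descriptors_npz(path, descriptors, channel: str = "shape") -> None:
    descriptors = list(descriptors)
    if not descriptors:
        raise ValueError("nothing to save")
    order = descriptors[0].order
    if any(d.order != order for d in descriptors):
        raise ValueError("all descriptors in one file must share an order")
    arr = np.stack([d.values for d in descriptors])
    np.savez(path, values=arr, order=np.array(order), channel=np.array(channel))


def load_descriptors_npz(path):
    with np.load(path) as data:
        order = int(data["order"])
        channel = str(data["channel"])
        descs = [ZernikeDescriptor(order=order, values=row) for row in data["values"]]
    return descs, channel
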