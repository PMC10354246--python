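"""Encoding of continuous variables as unit-modulus-spectrum vectors.

A point x in R^m maps to the d-vector obtained by taking the inverse DFT of
exp(i*A@x), where A is a d-by-m matrix of spatial frequencies whose rows
occur in +/- pairs around one all-zero row, so the spectrum is conjugate
symmetric and the encoding is real.  Binding two encodings adds the
underlying points.  The dot product of two encodings approximates a
product-of-sincs kernel, which supports a rectified-linear kernel-density
readout and a maximum-a-posteriori decode back to coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .vsa import SemanticPointer


class ConfigError(ValueError):
    pass


class DecodeFailure(RuntimeError):
    """All rectified lattice similarities are zero; no decode is available."""


class EmptyRegionError(ValueError):
    pass


class EncoderMismatchError(ValueError):
    pass


@dataclass
class SSP:
    """A d-vector living in (or near) the manifold of point encodings."""

    values: np.ndarray
    encoder: "SSPEncoder"
    clean: bool = True

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self):
        return self.values.size


def _as_vector(v) -> np.ndarray:
    if isinstance(v, (SSP, SemanticPointer)):
        return np.asarray(v, dtype=float)
    return np.asarray(v, dtype=float)


class SSPEncoder:
    """Frequency matrix plus domain metadata for a continuous encoding.

    Parameters are normally produced by :func:`make_encoder`.  ``A_half``
    holds the (d-1)/2 independent frequency rows; the full matrix is
    ``[0; A_half; -A_half reversed]`` to keep the spectrum conjugate
    symmetric.  ``domain_bounds`` is an (m, 2) array of lower/upper limits
    used by similarity maps, region encodings, and the probability readout.
    """

    def __init__(
        self,
        A_half: np.ndarray,
        length_scale,
        domain_bounds,
        style: str = "random",
        seed: int | None = None,
    ):
        A_half = np.atleast_2d(np.asarray(A_half, dtype=float))
        self.A_half = A_half
        self.n_half = A_half.shape[0]
        self.d = 2 * self.n_half + 1
        self.m = A_half.shape[1]
        self.length_scale = np.broadcast_to(
            np.asarray(length_scale, dtype=float), (self.m,)
        ).copy()
        self.domain_bounds = np.asarray(domain_bounds, dtype=float).reshape(self.m, 2)
        self.style = style
        self.seed = seed
        self.dft_convention = "inverse-carries-1/d"

    @property
    def A(self) -> np.ndarray:
        """Full d x m frequency matrix: zero row, +rows, mirrored -rows."""
        return np.vstack(
            [np.zeros((1, self.m)), self.A_half, -self.A_half[::-1]]
        )

    # -- encoding ----------------------------------------------------------
    def encode_vec(self, x) -> np.ndarray:
        """Encode one point (m,) to a (d,) vector or a batch (n, m) -> (n, d)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim <= 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.m:
            raise ConfigError(
                f"points have dimension {X.shape[1]}, encoder expects {self.m}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("points must be finite")
        phases = X @ self.A_half.T  # (n, n_half)
        F = np.empty((X.shape[0], self.n_half + 1), dtype=complex)
        F[:, 0] = 1.0
        F[:, 1:] = np.exp(1j * phases)
        out = np.fft.irfft(F, n=self.d, axis=1)
        return out[0] if single else out

    def encode(self, x) -> SSP:
        return SSP(self.encode_vec(x), self, clean=True)

    def identity_vec(self) -> np.ndarray:
        return self.encode_vec(np.zeros(self.m))

    # -- lattice helpers ---------------------------------------------------
    def grid(self, resolution: int):
        """Axis vectors and flattened lattice points over the domain bounds."""
        if resolution < 2:
            raise ConfigError("grid resolution must be >= 2")
        axes = [
            np.linspace(lo, hi, resolution) for lo, hi in self.domain_bounds
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        points = np.stack([m.ravel() for m in mesh], axis=-1)
        return axes, points

    def similarity_map(self, v, grid_resolution: int = 101):
        """Dot products of ``v`` with point encodings on a lattice.

        Returns ``(axes, field)`` where ``field`` has shape
        ``(grid_resolution,) * m``.
        """
        axes, points = self.grid(grid_resolution)
        Phi = self.encode_vec(points)
        field = Phi @ _as_vector(v)
        return axes, field.reshape((grid_resolution,) * self.m)

    def encode_region(
        self,
        indicator: Callable[[np.ndarray], np.ndarray],
        n_quadrature: int = 101,
    ) -> np.ndarray:
        """Riemann-sum encoding of {x : indicator(x)} over the domain.

        ``indicator`` maps an (n, m) array of points to a boolean mask.
        The sum over in-region lattice cells is scaled by the cell volume,
        approximating the integral of the point encoding over the region.
        """
        axes, points = self.grid(n_quadrature)
        mask = np.asarray(indicator(points), dtype=bool).ravel()
        if not mask.any():
            raise EmptyRegionError("indicator is false everywhere on the lattice")
        cell = np.prod([ax[1] - ax[0] for ax in axes])
        Phi = self.encode_vec(points[mask])
        return Phi.sum(axis=0) * cell

    def similarity_map_to_csv(self, v, path, grid_resolution: int = 101):
        """Write the similarity lattice as CSV columns x, y[, z], value."""
        import pandas as pd

        axes, field = self.similarity_map(v, grid_resolution)
        _, points = self.grid(grid_resolution)
        cols = ["x", "y", "z"][: self.m]
        data = {c: points[:, i] for i, c in enumerate(cols)}
        data["value"] = field.ravel()
        pd.DataFrame(data).to_csv(path, index=False)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "m": self.m,
            "seed": self.seed,
            "style": self.style,
            "length_scale": self.length_scale.tolist(),
            "domain_bounds": self.domain_bounds.tolist(),
            "A_half": self.A_half.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SSPEncoder":
        return cls(
            np.asarray(data["A_half"], dtype=float),
            np.asarray(data["length_scale"], dtype=float),
            np.asarray(data["domain_bounds"], dtype=float),
            style=data.get("style", "random"),
            seed=data.get("seed"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SSPEncoder":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_encoder(
    d: int,
    m: int,
    length_scale=0.1,
    seed: int = 0,
    style: str = "random",
    domain_bounds=None,
) -> SSPEncoder:
    """Build an encoder with conjugate-symmetric row structure.

    ``style="random"`` samples the (d-1)/2 independent frequency rows
    i.i.d. uniform in the box [-pi/l, pi/l]^m (per-axis length scale l),
    whose expected similarity profile is a product of sinc lobes with first
    zero at distance l.  ``style="hexagonal"`` (m=2 only) tiles the rows on
    triplets of wave vectors at 120-degree separation over several scales,
    which yields hexagonally symmetric downstream firing maps.
    """
    if d % 2 == 0 or d < 3:
        raise ConfigError("d must be odd and >= 3")
    if m < 1:
        raise ConfigError("m must be >= 1")
    ls = np.broadcast_to(np.asarray(length_scale, dtype=float), (m,))
    if np.any(ls <= 0):
        raise ConfigError("length scales must be positive")
    if domain_bounds is None:
        domain_bounds = np.tile([-1.0, 1.0], (m, 1))
    n_half = (d - 1) // 2
    rng = np.random.default_rng(seed)
    if style == "random":
        A_half = rng.uniform(-np.pi, np.pi, size=(n_half, m)) / ls
    elif style == "hexagonal":
        if m != 2:
            raise ConfigError("hexagonal style requires m=2")
        A_half = _hexagonal_rows(n_half, ls, rng)
    else:
        raise ConfigError(f"unknown encoder style {style!r}")
    return SSPEncoder(A_half, ls, domain_bounds, style=style, seed=seed)


def _hexagonal_rows(n_half: int, ls: np.ndarray, rng: np.random.Generator):
    """Wave-vector triplets at 120 degrees over geometrically spaced scales."""
    n_triplets = n_half // 3
    k_max = np.pi / ls.min()
    scales = k_max * np.geomspace(0.25, 1.0, max(n_triplets, 1))
    rows = []
    for t in range(n_triplets):
        theta = rng.uniform(0, 2 * np.pi / 3)
        for k in range(3):
            ang = theta + 2 * np.pi * k / 3
            rows.append(scales[t] * np.array([np.cos(ang), np.sin(ang)]))
    for _ in range(n_half - 3 * n_triplets):
        rows.append(rng.uniform(-k_max, k_max, size=2))
    return np.asarray(rows)


@dataclass
class ProbabilityReadout:
    """Rectified-similarity density readout with a fitted bias.

    ``density(M, x) = max(scale * (phi(x) . M) - xi, 0)``.  ``scale`` is the
    kernel normalization 1/prod(length_scale) — the similarity kernel of a
    point encoding integrates to ~prod(length_scale), so this factor gives a
    single kernel roughly unit mass.  ``xi`` is then a positive bias fitted
    so the density of a single point encoding integrates to exactly one
    over the bounded domain lattice (the computable surrogate for the
    all-space normalization).
    """

    encoder: SSPEncoder
    xi: float
    scale: float
    axes: list
    points: np.ndarray
    Phi: np.ndarray
    cell_volume: float
    resolution: int

    def field(self, v) -> np.ndarray:
        """Raw similarity lattice (no scaling or rectification)."""
        return self.Phi @ np.asarray(_as_vector(v), dtype=self.Phi.dtype)

    def rectified_field(self, v) -> np.ndarray:
        return np.maximum(self.scale * self.field(v) - self.xi, 0.0)

    def integrate(self, v) -> float:
        return float(self.rectified_field(v).sum() * self.cell_volume)

    def density(self, M, x) -> float:
        """Rectified kernel density of belief vector M at point x."""
        if isinstance(M, SSP) and M.encoder is not self.encoder:
            raise EncoderMismatchError("belief vector built with another encoder")
        val = self.scale * float(
            np.dot(self.encoder.encode_vec(x), _as_vector(M))
        ) - self.xi
        return max(val, 0.0)

    def density_field(self, M) -> np.ndarray:
        return self.rectified_field(M).reshape(
            (self.resolution,) * self.encoder.m
        )

    def fit_xi(self, M, target: float = 1.0, iters: int = 200) -> float:
        """Per-belief rectification bias: the smallest shift making the
        rectified field integrate to ``target`` on the lattice.

        The stored ``xi`` is fitted once for a single point encoding (the
        position-belief case); a diffuse belief (e.g. the mean of many point
        encodings) needs its own bias — possibly negative — to be a proper
        density.
        """
        f = self.scale * self.field(M)
        volume = self.cell_volume * len(f)

        def mass(xi):
            return np.maximum(f - xi, 0.0).sum() * self.cell_volume

        lo = min(0.0, float(f.min()) - (target / volume) - 1.0)
        hi = float(f.max())
        if mass(lo) < target:
            lo -= (target - mass(lo)) / volume + 1.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if mass(mid) > target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def kde_density_field(self, M) -> np.ndarray:
        """Kernel-density field of a belief vector, normalized to unit mass."""
        xi = self.fit_xi(M)
        out = np.maximum(self.scale * self.field(M) - xi, 0.0)
        return out.reshape((self.resolution,) * self.encoder.m)

    def map_decode(self, v) -> np.ndarray:
        """Argmax of the similarity lattice, refined per axis by a quadratic.

        Raises :class:`DecodeFailure` when the rectified field is identically
        zero (the vector carries no mass anywhere on the lattice).
        """
        vec = _as_vector(v)
        if not np.any(vec):
            raise DecodeFailure("zero vector cannot be decoded")
        f = self.field(vec)
        # failure criterion on the unit-normalized vector so the decode is
        # invariant to positive rescaling of v
        if self.scale * f.max() / np.linalg.norm(vec) - self.xi <= 0:
            raise DecodeFailure("rectified similarity field is zero everywhere")
        m = self.encoder.m
        shape = (self.resolution,) * m
        idx = np.unravel_index(int(np.argmax(f)), shape)
        f = f.reshape(shape)
        out = np.empty(m)
        for ax in range(m):
            axis = self.axes[ax]
            i = idx[ax]
            x0 = axis[i]
            step = axis[1] - axis[0]
            if 0 < i < len(axis) - 1:
                lo = f[tuple(j - (ax == a) for a, j in enumerate(idx))]
                hi = f[tuple(j + (ax == a) for a, j in enumerate(idx))]
                mid = f[idx]
                denom = lo - 2 * mid + hi
                if denom < 0:
                    delta = float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))
                    x0 = x0 + delta * step
            out[ax] = x0
        return out

    def cleanup(self, v) -> SSP:
        """Project a vector onto the encoding manifold (decode + re-encode)."""
        return self.encoder.encode(self.map_decode(v))


def fit_normalization(
    enc: SSPEncoder, grid_resolution: int | None = None, dtype=np.float64
) -> ProbabilityReadout:
    """Fit the rectification bias by bisection on the domain lattice.

    The bias is chosen so that the rectified similarity field of a single
    point encoding (placed at the domain center) integrates to 1 +/- 1e-3.
    """
    if grid_resolution is None:
        grid_resolution = 101 if enc.m <= 2 else 35
    axes, points = enc.grid(grid_resolution)
    Phi = enc.encode_vec(points).astype(dtype)
    cell = float(np.prod([ax[1] - ax[0] for ax in axes]))
    center = enc.domain_bounds.mean(axis=1)
    scale = float(1.0 / np.prod(enc.length_scale))
    f = scale * (Phi @ enc.encode_vec(center).astype(dtype))

    def mass(xi):
        return np.maximum(f - xi, 0.0).sum() * cell

    lo, hi = 0.0, float(f.max())
    if mass(lo) < 1.0:
        raise ConfigError(
            "rectified mass below 1 even at zero bias; the domain lattice "
            "is too coarse or the kernel too narrow for this domain"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mass(mid) > 1.0:
            lo = mid
        else:
            hi = mid
        if abs(mass(mid) - 1.0) < 1e-6:
            break
    xi = 0.5 * (lo + hi)
    return ProbabilityReadout(
        encoder=enc,
        xi=float(xi),
        scale=scale,
        axes=axes,
        points=points,
        Phi=Phi,
        cell_volume=cell,
        resolution=grid_resolution,
    )


# Functional aliases mirroring the object API.
def similarity_map(enc: SSPEncoder, v, grid_resolution: int = 101):
    return enc.similarity_map(v, grid_resolution)


def encode_region(enc: SSPEncoder, indicator, n_quadrature: int = 101):
    return enc.encode_region(indicator, n_quadrature)


def density(readout: ProbabilityReadout, M, x):
    return readout.density(M, x)


def map_decode(readout: ProbabilityReadout, v):
    return readout.map_decode(v)


def cleanup(readout: ProbabilityReadout, v):
    return readout.cleanup(v)
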