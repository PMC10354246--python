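"""Holographic-reduced-representation algebra on real vectors.

Symbols and composed structures are plain d-dimensional real vectors.
Binding is circular convolution (Hadamard product in the Fourier domain),
bundling is addition, the inverse is the index-reversal involution, and
similarity is the cosine (or raw dot product).  The DFT convention with the
1/d factor on the inverse transform is used throughout the package, so
unitary vectors (unit-modulus spectrum) have unit Euclidean norm.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np


class DimensionMismatchError(ValueError):
    """Operands of a binding/bundling/similarity call differ in length."""


class NameCollisionError(KeyError):
    """A vocabulary name was registered twice."""


class UndefinedSimilarityError(ValueError):
    """Cosine similarity was requested for a zero-norm vector."""


def _values(x) -> np.ndarray:
    if isinstance(x, SemanticPointer):
        return x.v
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("semantic pointers are 1-D vectors")
    return v


class SemanticPointer:
    """A d-dimensional real vector standing for a symbol or composition.

    Supports the algebra through operators: ``a * b`` binds, ``a + b``
    bundles, ``~a`` is the involution inverse, ``a | b`` is the cosine
    similarity.
    """

    __slots__ = ("v", "label")

    def __init__(self, values, label: str | None = None):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("semantic pointer must be a 1-D vector of length >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("semantic pointer entries must be finite")
        self.v = v
        self.label = label

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.v.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.v, dtype=dtype)

    def __repr__(self) -> str:
        name = self.label or "?"
        return f"SemanticPointer({name}, d={self.v.size})"

    @property
    def d(self) -> int:
        return self.v.size

    def norm(self) -> float:
        return float(np.linalg.norm(self.v))

    def normalized(self) -> "SemanticPointer":
        return normalize(self)

    def dot(self, other) -> float:
        return float(np.dot(self.v, _values(other)))

    # -- operators ---------------------------------------------------------
    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return SemanticPointer(self.v * other, self.label)
        return bind(self, other)

    def __rmul__(self, other):
        if isinstance(other, (int, float)):
            return SemanticPointer(self.v * other, self.label)
        return bind(other, self)

    def __add__(self, other):
        return bundle([self, other])

    def __sub__(self, other):
        return SemanticPointer(self.v - _values(other))

    def __neg__(self):
        return SemanticPointer(-self.v, self.label)

    def __invert__(self):
        return inverse(self)

    def __or__(self, other) -> float:
        return similarity(self, other)


def identity(d: int) -> SemanticPointer:
    """The binding identity: 1 in position 0, zero elsewhere."""
    v = np.zeros(d)
    v[0] = 1.0
    return SemanticPointer(v, label="I")


def bind(a, b) -> SemanticPointer:
    """Circular convolution of two pointers, computed via the DFT."""
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise DimensionMismatchError(
            f"cannot bind vectors of length {va.size} and {vb.size}"
        )
    d = va.size
    out = np.fft.irfft(np.fft.rfft(va) * np.fft.rfft(vb), n=d)
    return SemanticPointer(out)


def bundle(pointers: Sequence) -> SemanticPointer:
    """Element-wise sum of a non-empty list of pointers (no renormalization)."""
    ptrs = list(pointers)
    if not ptrs:
        raise ValueError("bundle requires a non-empty list of pointers")
    vs = [_values(p) for p in ptrs]
    d = vs[0].size
    for v in vs[1:]:
        if v.size != d:
            raise DimensionMismatchError("bundled pointers must share one dimension")
    return SemanticPointer(np.sum(vs, axis=0))


def inverse(a) -> SemanticPointer:
    """Involution inverse [a_1, a_d, a_{d-1}, ..., a_2].

    Equals complex conjugation of every DFT coefficient; exact inverse of
    binding for unitary pointers, approximate otherwise.
    """
    v = _values(a)
    return SemanticPointer(np.concatenate([v[:1], v[:0:-1]]))


def normalize(a) -> SemanticPointer:
    v = _values(a)
    n = np.linalg.norm(v)
    if n == 0:
        raise UndefinedSimilarityError("cannot normalize the zero vector")
    return SemanticPointer(v / n, getattr(a, "label", None))


def similarity(a, b, mode: str = "cosine") -> float:
    """Cosine similarity (default) or raw dot product of two pointers."""
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise DimensionMismatchError(
            f"cannot compare vectors of length {va.size} and {vb.size}"
        )
    dot = float(np.dot(va, vb))
    if mode == "dot":
        return dot
    if mode != "cosine":
        raise ValueError(f"unknown similarity mode {mode!r}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine similarity of a zero-norm vector")
    return dot / (na * nb)


def make_unitary(a) -> SemanticPointer:
    """Project a pointer onto the unitary set (unit-modulus spectrum)."""
    v = _values(a)
    F = np.fft.rfft(v)
    mags = np.abs(F)
    if np.any(mags == 0):
        raise ValueError("pointer has a zero DFT coefficient; cannot unitarize")
    return SemanticPointer(np.fft.irfft(F / mags, n=v.size))


def is_unitary(a, tol: float = 1e-9) -> bool:
    v = _values(a)
    return bool(np.allclose(np.abs(np.fft.rfft(v)), 1.0, atol=tol))


class Vocabulary:
    """A seeded table of named semantic pointers of one dimension."""

    def __init__(self, dimension: int, seed: int = 0):
        if dimension < 2:
            raise ValueError("vocabulary dimension must be >= 2")
        self.dimension = int(dimension)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self._table: dict[str, SemanticPointer] = {}

    def __contains__(self, name: str) -> bool:
        return name in self._table

    def __getitem__(self, name: str) -> SemanticPointer:
        return self._table[name]

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def keys(self):
        return self._table.keys()

    def items(self):
        return self._table.items()

    def add(self, name: str, pointer) -> SemanticPointer:
        if name in self._table:
            raise NameCollisionError(f"name {name!r} already in vocabulary")
        v = _values(pointer)
        if v.size != self.dimension:
            raise DimensionMismatchError(
                f"pointer of length {v.size} in a d={self.dimension} vocabulary"
            )
        sp = SemanticPointer(v, label=name)
        self._table[name] = sp
        return sp

    def random_pointer(self, name: str, unitary: bool = True) -> SemanticPointer:
        """Draw a new unit-norm pointer from the seeded rng and register it.

        With ``unitary=True`` the vector is built from i.i.d. uniform phases
        on the upper half-spectrum (mirrored conjugate), so every DFT
        coefficient has unit modulus and binding with it preserves norms.
        """
        if name in self._table:
            raise NameCollisionError(f"name {name!r} already in vocabulary")
        d = self.dimension
        if unitary:
            n_half = (d - 1) // 2
            phases = self.rng.uniform(-np.pi, np.pi, size=n_half)
            F = np.empty(d // 2 + 1, dtype=complex)
            F[0] = 1.0
            F[1 : n_half + 1] = np.exp(1j * phases)
            if d % 2 == 0:  # Nyquist coefficient must be real
                F[-1] = self.rng.choice([-1.0, 1.0])
            v = np.fft.irfft(F, n=d)
        else:
            v = self.rng.standard_normal(d)
            v /= np.linalg.norm(v)
        return self.add(name, v)

    def populate(self, names: Iterable[str], unitary: bool = True) -> None:
        for name in names:
            if name not in self._table:
                self.random_pointer(name, unitary=unitary)

    def parse(self, expression: str) -> SemanticPointer:
        """Evaluate an algebra expression such as ``"BLUE*TRIANGLE"``.

        Supported operators: ``*`` (bind), ``+`` (bundle), ``~`` (inverse),
        and parentheses.  Names must exist in the vocabulary.
        """
        namespace = {name: sp for name, sp in self._table.items()}
        try:
            result = eval(expression, {"__builtins__": {}}, namespace)  # noqa: S307
        except NameError as exc:
            raise KeyError(f"unknown symbol in expression {expression!r}: {exc}")
        if isinstance(result, SemanticPointer):
            return result
        return SemanticPointer(np.asarray(result, dtype=float))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "dimension": self.dimension,
                "seed": self.seed,
                "symbols": {n: sp.v.tolist() for n, sp in self._table.items()},
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        data = json.loads(text)
        vocab = cls(data["dimension"], data.get("seed", 0))
        for name, values in data["symbols"].items():
            vocab.add(name, values)
        return vocab

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())
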