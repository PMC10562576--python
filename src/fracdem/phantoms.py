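"""Binary 3-D phantoms with analytically known box-counting dimension."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fractal import VoxelMask

__all__ = ["PhantomSpec", "make_phantom", "theoretical_fd", "PHANTOM_KINDS"]

PHANTOM_KINDS = ("cube", "slab", "line", "menger")

_THEORETICAL = {
    "cube": 3.0,
    "slab": 2.0,
    "line": 1.0,
    "menger": math.log(20) / math.log(3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom description: ``size`` for cube/slab/line, ``iterations`` for menger."""

    kind: str
    size: int | None = None
    iterations: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "menger":
            if self.iterations is None or not 1 <= self.iterations <= 5:
                raise ValueError("menger requires 1 <= iterations <= 5")
        else:
            if self.size is None or self.size < 8:
                raise ValueError(f"{self.kind} requires size >= 8")

    @property
    def theoretical_fd(self) -> float:
        return _THEORETICAL[self.kind]


def theoretical_fd(kind: str) -> float:
    """Analytic box-counting dimension of a phantom kind."""
    try:
        return _THEORETICAL[kind]
    except KeyError:
        raise ValueError(f"unknown phantom kind {kind!r}") from None


def _menger(iterations: int) -> np.ndarray:
    # standard recursion: keep the 20 of 27 subcubes touching at most one
    # centre coordinate; grid is 3**iterations so the construction is exact
    grid = np.ones((1, 1, 1), dtype=bool)
    for _ in range(iterations):
        n = grid.shape[0]
        nxt = np.zeros((3 * n, 3 * n, 3 * n), dtype=bool)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    if (a == 1) + (b == 1) + (c == 1) >= 2:
                        continue
                    nxt[a * n : (a + 1) * n, b * n : (b + 1) * n, c * n : (c + 1) * n] = grid
        grid = nxt
    return grid


def make_phantom(spec: PhantomSpec) -> VoxelMask:
    """Deterministically build the phantom described by ``spec``."""
    if spec.kind == "cube":
        occ = np.ones((spec.size,) * 3, dtype=bool)
    elif spec.kind == "slab":
        occ = np.ones((spec.size, spec.size, 1), dtype=bool)
    elif spec.kind == "line":
        occ = np.ones((spec.size, 1, 1), dtype=bool)
    else:
        occ = _menger(spec.iterations)
    return VoxelMask(occupancy=occ)
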