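"""Binned free-energy surfaces over one or two order parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = ["FESAxis", "FreeEnergySurface"]


@dataclass(frozen=True)
class FESAxis:
    """One binned order-parameter axis: bin centres plus a label."""

    name: str
    centers: np.ndarray

    @property
    def nbins(self) -> int:
        return len(self.centers)

    @property
    def edges(self) -> np.ndarray:
        c = np.asarray(self.centers, dtype=float)
        mid = 0.5 * (c[1:] + c[:-1])
        first = c[0] - (mid[0] - c[0]) if len(c) > 1 else c[0] - 0.5
        last = c[-1] + (c[-1] - mid[-1]) if len(c) > 1 else c[0] + 0.5
        return np.concatenate([[first], mid, [last]])

    @classmethod
    def from_range(cls, name: str, lo: float, hi: float, nbins: int) -> "FESAxis":
        edges = np.linspace(lo, hi, nbins + 1)
        return cls(name=name, centers=0.5 * (edges[1:] + edges[:-1]))


@dataclass
class FreeEnergySurface:
    """Free energy F (kcal/mol) binned over 1–2 order parameters.

    ``values`` is min-shifted so the lowest occupied bin is 0; unoccupied
    bins are flagged in ``occupied`` and hold ``np.inf`` rather than an
    extrapolated value.
    """

    axes: Sequence[FESAxis]
    values: np.ndarray
    occupied: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.axes) not in (1, 2):
            raise InputError("only 1D and 2D surfaces are supported")
        expected = tuple(ax.nbins for ax in self.axes)
        if self.values.shape != expected:
            raise InputError(f"values shape {self.values.shape} != axes {expected}")
        if self.occupied is None:
            self.occupied = np.isfinite(self.values)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        self.min_shift()

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def min_shift(self) -> None:
        """Shift so the lowest occupied bin sits at zero."""
        if self.occupied.any():
            self.values = self.values - self.values[self.occupied].min()
            self.values[~self.occupied] = np.inf

    def marginal(self, axis_name: str, kbt: float) -> "FreeEnergySurface":
        """Boltzmann-weighted marginal of a 2D surface onto one axis."""
        if self.ndim != 2:
            raise InputError("marginal requires a 2D surface")
        names = [ax.name for ax in self.axes]
        if axis_name not in names:
            raise InputError(f"no axis named {axis_name!r}")
        keep = names.index(axis_name)
        drop = 1 - keep
        with np.errstate(over="ignore"):
            weights = np.where(self.occupied, np.exp(-self.values / kbt), 0.0)
        p = weights.sum(axis=drop)
        with np.errstate(divide="ignore"):
            f = -kbt * np.log(p)
        return FreeEnergySurface(axes=[self.axes[keep]], values=f,
                                 occupied=p > 0, meta=dict(self.meta))

    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        """Write as 2/3-column text: axis value(s), F; unoccupied bins skipped."""
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# axes: {' '.join(ax.name for ax in self.axes)}\n")
            fh.write("# F in kcal/mol, min-shifted to 0\n")
            if self.ndim == 1:
                for x, f, occ in zip(self.axes[0].centers, self.values, self.occupied):
                    if occ:
                        fh.write(f"{x:.9g} {f:.9g}\n")
            else:
                for i, x in enumerate(self.axes[0].centers):
                    for j, y in enumerate(self.axes[1].centers):
                        if self.occupied[i, j]:
                            fh.write(f"{x:.9g} {y:.9g} {self.values[i, j]:.9g}\n")
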