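"""Coordinate-level kernels: superposition, RMSD, dihedrals, centroids.

These are pure functions over :class:`Conformation`, the package's labelled
single-frame coordinate container.  All distances are in Å, angles in
degrees.  The superposition is the closed-form least-squares rigid fit
(SVD-based, with reflection correction so the returned matrix is always a
proper rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InputError

__all__ = [
    "Conformation",
    "SuperposeResult",
    "superpose",
    "rmsd",
    "dihedral",
    "centroid",
]


@dataclass
class Conformation:
    """Labelled atomic coordinates for a single frame.

    Parameters
    ----------
    coords
        (N, 3) array of positions in Å.
    atom_names
        N atom names following PDB conventions (``CA``, ``NH1``, ...).
    residue_ids
        N integer residue identifiers (1-based, as in PDB files).
    residue_names
        N residue names (``ARG``, ``TRP``, ...).
    chain_ids
        N chain identifiers.
    masses
        Optional N masses in amu; defaults to 1.0 for every atom so that
        mass-weighted operations degrade gracefully to uniform weighting.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"coords must be (N, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 1:
            raise InputError("a Conformation needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coords contain non-finite values")
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        for name in ("atom_names", "residue_ids", "residue_names", "chain_ids", "masses"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise InputError(f"{name} has length {arr.shape[0]}, expected {n}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        """Copy sharing all labels but with new coordinates."""
        return replace(self, coords=np.array(coords, dtype=float))

    def select(
        self,
        atom_names: Iterable[str] | None = None,
        residue_ids: Iterable[int] | None = None,
        chain_ids: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Return sorted indices of atoms matching every given criterion."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= np.isin(self.atom_names.astype(str), list(atom_names))
        if residue_ids is not None:
            mask &= np.isin(self.residue_ids, list(residue_ids))
        if chain_ids is not None:
            mask &= np.isin(self.chain_ids.astype(str), list(chain_ids))
        return np.flatnonzero(mask)

    def ca_indices(self, exclude_residue_ids: Iterable[int] | None = None) -> np.ndarray:
        """Indices of Cα atoms, optionally excluding some residues."""
        idx = self.select(atom_names=["CA"])
        if exclude_residue_ids is not None:
            excl = set(int(r) for r in exclude_residue_ids)
            idx = idx[[self.residue_ids[i] not in excl for i in idx]]
        return idx


class SuperposeResult(NamedTuple):
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, post-fit over the masked atoms


def _resolve_mask(mask: Sequence[int] | np.ndarray | None, n: int) -> np.ndarray:
    if mask is None:
        return np.arange(n)
    idx = np.asarray(mask)
    if idx.dtype == bool:
        if idx.shape[0] != n:
            raise InputError("boolean mask length does not match atom count")
        idx = np.flatnonzero(idx)
    idx = idx.astype(int)
    if idx.size == 0:
        raise InputError("empty selection mask")
    if idx.min() < 0 or idx.max() >= n:
        raise InputError("mask index out of range")
    return idx


def _kabsch(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted least-squares proper rotation mapping centred x onto centred y.

    Returns (rotation, x_center, y_center, rmsd). The reflection branch of
    the SVD solution is corrected so det(R) = +1 always.
    """
    w = weights / weights.sum()
    xc = (w[:, None] * x).sum(axis=0)
    yc = (w[:, None] * y).sum(axis=0)
    x0 = x - xc
    y0 = y - yc
    cov = (w[:, None] * x0).T @ y0
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    e0 = (w[:, None] * (x0**2 + y0**2)).sum()
    msd = max(e0 - 2.0 * (s * diag).sum(), 0.0)
    return rot, xc, yc, float(np.sqrt(msd))


def superpose(
    mobile: Conformation,
    reference: Conformation,
    mask: Sequence[int] | np.ndarray | None = None,
    mass_weighted: bool = False,
) -> SuperposeResult:
    """Optimal rigid fit of ``mobile`` onto ``reference`` over ``mask``.

    The returned transform maps mobile coordinates as ``R @ x + t``; the
    rotation is always proper (det = +1).  Raises
    :class:`DegenerateGeometryError` when fewer than 3 atoms are selected or
    the selection is collinear, in which case the rotation is not unique.
    """
    idx = _resolve_mask(mask, mobile.n_atoms)
    if reference.n_atoms != mobile.n_atoms:
        # masks are positional: both structures must share atom ordering
        idx_r = _resolve_mask(mask, reference.n_atoms)
        if idx_r.shape != idx.shape:
            raise InputError("mask selects different atom counts in mobile and reference")
    if idx.size < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    x = mobile.coords[idx]
    y = reference.coords[idx]
    # collinearity: second singular value of the centred cloud vanishes
    sv = np.linalg.svd(x - x.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("selection is (near-)collinear; rotation ill-defined")
    w = mobile.masses[idx] if mass_weighted else np.ones(idx.size)
    rot, xc, yc, fit_rmsd = _kabsch(x, y, w)
    trans = yc - rot @ xc
    return SuperposeResult(rotation=rot, translation=trans, rmsd=fit_rmsd)


def rmsd(
    a: Conformation,
    b: Conformation,
    mask: Sequence[int] | np.ndarray | None = None,
    fit: bool = True,
    mass_weighted: bool = False,
) -> float:
    """Root-mean-square deviation between corresponding masked atoms, in Å.

    With ``fit=True`` (default) an optimal superposition is performed first,
    matching the convention of Cα RMSD between aligned structures.  The
    default is non-mass-weighted; pass ``mass_weighted=True`` to weight by
    atomic masses.
    """
    idx = _resolve_mask(mask, a.n_atoms)
    if fit:
        return superpose(a, b, idx, mass_weighted=mass_weighted).rmsd
    x = a.coords[idx]
    y = b.coords[idx]
    w = a.masses[idx] if mass_weighted else np.ones(idx.size)
    w = w / w.sum()
    return float(np.sqrt((w * ((x - y) ** 2).sum(axis=1)).sum()))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1–p2–p3–p4 in degrees, IUPAC convention.

    cis (eclipsed) = 0°, trans (anti) = 180°; range (−180, 180].  Invariant
    under global rotation and translation of the four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("three consecutive dihedral points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    # map -180 to +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def centroid(
    c: Conformation,
    mask: Sequence[int] | np.ndarray | None = None,
    weighting: str = "uniform",
) -> np.ndarray:
    """Weighted mean position of the masked atoms.

    ``weighting`` is ``"uniform"`` or ``"mass"`` (centre of mass using the
    conformation's masses).
    """
    idx = _resolve_mask(mask, c.n_atoms)
    if weighting == "uniform":
        w = np.ones(idx.size)
    elif weighting == "mass":
        w = c.masses[idx]
    else:
        raise InputError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return (w[:, None] * c.coords[idx]).sum(axis=0)
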