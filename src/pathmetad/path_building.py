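"""From biased trajectories to an ordered set of path reference states.

The pipeline: run several independent ratchet-biased (ABMD) simulations
from the inactive toward the active state, pool the frames, compute the
pairwise fit-RMSD dissimilarity matrix over the path mask, cluster with
average-linkage (UPGMA) agglomerative clustering, cut the tree at
``k_cut`` clusters, and pick ``n_refs`` cluster medoids homogeneously
covering the pathway (equal spacing in cumulative consecutive-medoid RMSD
arc length, endpoints always included), numbered from the inactive end.

The linkage itself is delegated to scipy.cluster.hierarchy; cluster
representatives are medoids (the member with minimal mean dissimilarity
to its cluster), which keeps references inside sampled conformation
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import geometry
from .biasing import RatchetState, ratchet_bias
from .errors import InputError
from .geometry import Conformation
from .path_cv import PathReferenceSet, _batched_sq_fit_rmsd
from .toy_systems import baoab_step, overdamped_step

__all__ = [
    "DissimilarityMatrix",
    "ClusterTree",
    "pairwise_rmsd",
    "average_linkage",
    "select_references",
    "run_abmd",
    "AbmdPool",
]

#: χ is expressed in nm at the ratchet boundary so the elastic constant
#: carries its conventional kcal/(mol·nm²) units; internal RMSDs stay in Å.
ANGSTROM_PER_NM = 10.0


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise fit-RMSD matrix (Å) with frame provenance labels."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InputError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) > 1e-10) or np.any(v < -1e-12):
            raise InputError("dissimilarities must be non-negative with zero diagonal")
        self.values = v
        if not self.labels:
            self.labels = list(range(v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_rmsd(frames: Sequence[Conformation], mask=None, labels=None) -> DissimilarityMatrix:
    """All-against-all superposed RMSD over ``mask``, batched per row."""
    if len(frames) < 2:
        raise InputError("need at least two frames")
    idx = np.asarray(mask, dtype=int) if mask is not None else np.arange(frames[0].n_atoms)
    block = np.stack([f.coords[idx] for f in frames])
    block = block - block.mean(axis=1, keepdims=True)
    n = len(frames)
    d = np.zeros((n, n))
    for i in range(n - 1):
        sq = _batched_sq_fit_rmsd(block[i], block[i + 1:])
        d[i, i + 1:] = np.sqrt(sq)
        d[i + 1:, i] = d[i, i + 1:]
    return DissimilarityMatrix(values=d, labels=list(labels) if labels is not None else [])


@dataclass
class ClusterTree:
    """Average-linkage merge history with a flat-cut view.

    ``merges`` is the scipy linkage matrix: each row merges two clusters at
    a linkage height; heights are non-decreasing (average linkage is
    monotone).  The originating dissimilarity matrix is retained so that
    medoid extraction does not recompute RMSDs.
    """

    merges: np.ndarray
    matrix: DissimilarityMatrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat clusters at ``k`` groups, labelled 0..k−1 by first occurrence."""
        if not 1 <= k <= self.matrix.n:
            raise InputError(f"cannot cut {self.matrix.n} frames into {k} clusters")
        raw = fcluster(self.merges, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        out = np.empty_like(raw)
        for i, lab in enumerate(raw):
            out[i] = remap.setdefault(lab, len(remap))
        return out


def average_linkage(mat: DissimilarityMatrix) -> ClusterTree:
    """UPGMA agglomerative clustering of the dissimilarity matrix."""
    if mat.n < 2:
        raise InputError("clustering needs at least two frames")
    z = linkage(squareform(mat.values, checks=False), method="average")
    return ClusterTree(merges=z, matrix=mat)


def _medoid(mat: np.ndarray, members: np.ndarray) -> int:
    sub = mat[np.ix_(members, members)]
    return int(members[np.argmin(sub.mean(axis=1))])


def select_references(
    tree: ClusterTree,
    frames: Sequence[Conformation],
    k_cut: int = 30,
    n_refs: int = 10,
    endpoints: tuple[Conformation, Conformation] | None = None,
    mask=None,
    gamma: float = 4.0,
) -> PathReferenceSet:
    """Cut the tree, order cluster medoids along the pathway, pick n_refs.

    Medoids are ordered by the progression coordinate
    RMSD(medoid, inactive) − RMSD(medoid, active); ``n_refs`` of them are
    chosen at approximately equal spacing in cumulative consecutive-medoid
    RMSD arc length, always including the medoids nearest the two
    endpoints, and numbered j = 1 from the inactive end.
    """
    if not k_cut >= n_refs >= 2:
        raise InputError("need k_cut ≥ n_refs ≥ 2")
    if endpoints is None:
        raise InputError("endpoints (inactive, active) conformations are required")
    inactive, active = endpoints
    labels = tree.cut(k_cut)
    occupied = np.unique(labels)
    if occupied.size < n_refs:
        raise InputError(
            f"only {occupied.size} occupied clusters for {n_refs} references"
        )
    medoids = np.array([
        _medoid(tree.matrix.values, np.flatnonzero(labels == c)) for c in occupied
    ])
    prog = np.array([
        geometry.rmsd(frames[m], inactive, mask=mask)
        - geometry.rmsd(frames[m], active, mask=mask)
        for m in medoids
    ])
    medoids = medoids[np.argsort(prog)]
    # cumulative arc length over ordered medoids
    seg = np.array([
        geometry.rmsd(frames[a], frames[b], mask=mask)
        for a, b in zip(medoids[:-1], medoids[1:])
    ])
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_refs)
    chosen: list[int] = []
    for t in targets:
        order = np.argsort(np.abs(arc - t))
        pick = next(int(i) for i in order if int(i) not in chosen)
        chosen.append(pick)
    chosen = sorted(chosen)
    chosen[0], chosen[-1] = 0, len(medoids) - 1  # endpoints always included
    refs = [frames[medoids[i]] for i in chosen]
    return PathReferenceSet(refs=refs, gamma=gamma,
                            mask=np.asarray(mask, dtype=int) if mask is not None else None)


# ---------------------------------------------------------------------------
# ABMD


@dataclass
class AbmdPool:
    """Pooled frames from independent ratchet-biased runs, with provenance."""

    frames: list[Conformation]
    provenance: pd.DataFrame  # columns: run, step, time, chi
    chi_series: list[np.ndarray]  # per-run χ trace (nm)
    stagnant_runs: list[int]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def progress_frames(self) -> list[Conformation]:
        """Frames at which χ set a new running minimum, pooled over runs.

        A thermalised run dwells in basins, so the raw pool over-represents
        them; the progress envelope — the frames where the ratchet's
        running best improved — traces the transition itself and is the
        recommended input for pathway clustering.
        """
        out: list[Conformation] = []
        runs = self.provenance["run"].to_numpy()
        chis = self.provenance["chi"].to_numpy()
        for run in np.unique(runs):
            idx = np.flatnonzero(runs == run)
            best = np.inf
            for i in idx:
                if chis[i] < best - 1e-12:
                    best = chis[i]
                    out.append(self.frames[i])
        return out


def run_abmd(
    system,
    target: Conformation,
    k: float = 10.0,
    n_runs: int = 10,
    seed: int = 0,
    steps: int = 2000,
    dt: float = 0.01,
    diffusion: float = 1.0,
    temperature: float = 300.0,
    mask=None,
    chi_target: float = 0.0,
    stride: int = 10,
    patience: int | None = None,
    integrator: str = "overdamped",
    friction: float = 1.0,
) -> AbmdPool:
    """Independent ratchet-biased runs driving χ = fit-RMSD(target) to χ₀.

    ``system`` is a Cartesian toy system (e.g.
    :class:`~pathmetad.toy_systems.MiniReceptorSystem`).  χ is the
    superposed RMSD to ``target`` over ``mask``, expressed in nm so the
    elastic constant ``k`` keeps its conventional kcal/(mol·nm²) units;
    the default χ₀ = 0 drives all runs to the target.  Runs whose running
    best fails to improve for ``patience`` recorded frames are flagged as
    stagnant but retained in the pool.  Langevin dynamics (overdamped by
    default, inertial BAOAB with ``integrator="baoab"``), seeded per run
    from ``seed``.
    """
    if n_runs < 1:
        raise InputError("need at least one run")
    template = system.conformation(system.initial_coords)
    idx = np.asarray(mask, dtype=int) if mask is not None else np.arange(template.n_atoms)
    ref_block = target.coords[idx] - target.coords[idx].mean(axis=0)
    n_masked = idx.size
    if patience is None:
        patience = max(50, steps // (stride * 2))

    def chi_and_gradient(x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = x.reshape(-1, 3)
        xm = coords[idx]
        x0 = xm - xm.mean(axis=0)
        d, rots = _batched_sq_fit_rmsd(x0, ref_block[None], return_rotations=True)
        chi_ang = float(np.sqrt(max(d[0], 1e-300)))
        grad_sq = np.zeros_like(coords)
        # envelope theorem at the optimal rotation R: ∂d/∂x_i = (2/M)(x0_i − Rᵀy_i)
        grad_sq[idx] = (2.0 / n_masked) * (x0 - ref_block @ rots[0])
        # χ in nm; dχ/dx = d(√d)/dx / 10 = grad_sq / (2χ_Å) / 10
        chi_nm = chi_ang / ANGSTROM_PER_NM
        dchi = grad_sq / (2.0 * max(chi_ang, 1e-12)) / ANGSTROM_PER_NM
        return chi_nm, dchi.ravel()

    frames: list[Conformation] = []
    prov_rows = []
    chi_series: list[np.ndarray] = []
    stagnant: list[int] = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, run]))
        x = np.array(system.initial_coords, dtype=float)
        chi0, _ = chi_and_gradient(x)
        rstate = RatchetState.initialize(chi0, chi_target, k)
        trace = []
        best_age = 0
        last_best = rstate.running_best
        flagged = False

        def total_force(xx: np.ndarray) -> np.ndarray:
            nonlocal rstate
            chi, dchi = chi_and_gradient(xx)
            energy, dedchi, rstate = ratchet_bias(chi, rstate)
            f = system.force(xx)
            if dedchi != 0.0:
                f = f - dedchi * dchi
            return f

        f = total_force(x)
        if integrator == "baoab":
            masses = np.asarray(getattr(system, "masses", np.ones(x.size)), dtype=float)
            from .constants import KB_KCAL, KCAL_PER_MOL_TO_AMU_A2_PS2

            v = rng.standard_normal(x.shape) * np.sqrt(
                KB_KCAL * temperature * KCAL_PER_MOL_TO_AMU_A2_PS2 / masses
            )
        for step in range(1, steps + 1):
            if integrator == "baoab":
                x, v, f = baoab_step(x, v, f, total_force, dt, friction, temperature, masses, rng)
            else:
                x, f = overdamped_step(x, total_force, dt, diffusion, temperature, rng, f=f)
            if step % stride == 0:
                chi, _ = chi_and_gradient(x)
                if rstate.running_best < last_best - 1e-9:
                    last_best = rstate.running_best
                    best_age = 0
                else:
                    best_age += 1
                if best_age >= patience and not flagged:
                    flagged = True
                trace.append(chi)
                frames.append(template.with_coords(x.reshape(-1, 3)))
                prov_rows.append({"run": run, "step": step, "time": step * dt, "chi": chi})
        chi_series.append(np.array(trace))
        if flagged:
            stagnant.append(run)
    return AbmdPool(
        frames=frames,
        provenance=pd.DataFrame(prov_rows),
        chi_series=chi_series,
        stagnant_runs=stagnant,
    )
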