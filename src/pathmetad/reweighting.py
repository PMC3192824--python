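"""Unbiasing metadynamics trajectories and projecting free energies.

A metadynamics trajectory samples e^{−β(F+V)} rather than e^{−βF}, so
statistics over observables that were not biased directly (the activation
descriptors d_IL, χ_TS, Δd_TM6, or the path variables themselves) must be
reweighted.  Two schemes are provided and cross-validated:

* ``final_bias`` — weight ∝ exp(+V_final(cv)/k_BT) using the converged
  bias; simple and adequate once the well-tempered bias has stopped
  evolving appreciably.
* ``time_dependent`` — weight ∝ exp(+[V(cv, t) − c(t)]/k_BT), where the
  running offset c(t) is the standard well-tempered estimator
  c(t) = (1/β)·ln[ ∫ exp(β·γ/(γ−1)·V) / ∫ exp(β/(γ−1)·V) ] (γ = bias
  factor), evaluated on a grid after every hill.  This uses each frame's
  instantaneous bias, so early frames (deposited under a shallow bias)
  are weighted consistently with late ones.

Both schemes normalise the weights to mean 1.  Projected surfaces are
−k_BT·ln of the weighted histogram, min-shifted.  No Jacobian correction
is applied to angular axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import KB_KCAL
from .errors import InputError
from .fes import FESAxis, FreeEnergySurface

__all__ = [
    "FrameRecord",
    "frames_from_trajectory",
    "frame_weights",
    "project_fes",
    "find_basins_and_barriers",
    "BasinTable",
]


@dataclass
class FrameRecord:
    """Per-frame CV values, bias, observables and reweighting weight."""

    time: float  # ps
    cv: np.ndarray  # (k,)
    bias: float  # kcal/mol, V(cv, t) at this frame's time
    observables: dict[str, float] = field(default_factory=dict)
    weight: float = np.nan


def frames_from_trajectory(traj, observables: Mapping[str, np.ndarray] | None = None) -> list[FrameRecord]:
    """Convert a :class:`~pathmetad.biasing.MetadTrajectory` to frame records.

    ``observables`` maps names to per-frame arrays (e.g. descriptor series
    computed from recorded coordinates).
    """
    obs = observables or {}
    for name, arr in obs.items():
        if len(arr) != traj.n_frames:
            raise InputError(f"observable {name!r} has {len(arr)} values for {traj.n_frames} frames")
    return [
        FrameRecord(
            time=float(traj.times[i]),
            cv=np.asarray(traj.cvs[i], dtype=float),
            bias=float(traj.bias[i]),
            observables={k: float(v[i]) for k, v in obs.items()},
        )
        for i in range(traj.n_frames)
    ]


def _wt_offset_series(state, grid_pts: np.ndarray) -> np.ndarray:
    """c(t) after each hill, on the given CV grid points.

    Uses the well-tempered relation between the evolving bias and the free
    energy: c(t) = (1/β) ln[ Σ e^{βγ/(γ−1)V} / Σ e^{β/(γ−1)V} ].  The bias
    grid is maintained incrementally hill by hill, so memory stays
    O(grid) regardless of the number of hills.
    """
    cfg = state.cfg
    beta = 1.0 / (KB_KCAL * cfg.temperature)
    bf = cfg.bias_factor
    centers = state.centers()
    widths = state.widths()
    heights = state.heights()
    v_grid = np.zeros(grid_pts.shape[0])
    out = np.empty(state.n_hills)
    for h in range(state.n_hills):
        d2 = ((grid_pts - centers[h]) ** 2 / (2.0 * widths[h] ** 2)).sum(axis=1)
        v_grid += heights[h] * np.exp(-d2)
        a = beta * bf / (bf - 1.0) * v_grid
        b = beta / (bf - 1.0) * v_grid
        amax = a.max()
        bmax = b.max()
        log_num = amax + np.log(np.exp(a - amax).sum())
        log_den = bmax + np.log(np.exp(b - bmax).sum())
        out[h] = (log_num - log_den) / beta
    return out


def frame_weights(
    frames: Sequence[FrameRecord],
    state,
    scheme: str = "final_bias",
    grid_bins: int = 120,
) -> np.ndarray:
    """Statistical weights undoing the metadynamics bias, normalised to mean 1.

    ``state`` is the :class:`~pathmetad.biasing.BiasState` of the run (only
    its hills and well-tempered parameters are used).  See the module
    docstring for the two schemes.
    """
    if not frames:
        raise InputError("no frames to reweight")
    if scheme not in ("final_bias", "time_dependent"):
        raise InputError(f"unknown reweighting scheme {scheme!r}")
    kbt = KB_KCAL * state.cfg.temperature
    cvs = np.array([f.cv for f in frames])
    if not np.all(np.isfinite(cvs)):
        raise InputError("non-finite CV values in frames")
    if state.n_hills == 0:
        w = np.ones(len(frames))
    elif scheme == "final_bias":
        v = np.asarray(state.evaluate(cvs), dtype=float)
        if not np.all(np.isfinite(v)):
            raise InputError("non-finite bias at some frames")
        log_w = v / kbt
        log_w -= log_w.max()
        w = np.exp(log_w)
    elif scheme == "time_dependent":
        times = np.array([f.time for f in frames])
        hill_times = np.asarray(state.times)
        if not np.all(np.diff(times) >= 0):
            raise InputError("time_dependent scheme needs time-ordered frames")
        # V(cv_f, t_f): each hill contributes to the frames recorded at or
        # after its deposition; accumulate hill by hill (O(frames) memory)
        centers = state.centers()
        widths = state.widths()
        heights = state.heights()
        k_f = np.searchsorted(hill_times, times, side="right")
        # first frame index receiving each hill (k_f is non-decreasing)
        first_frame = np.searchsorted(k_f, np.arange(1, state.n_hills + 1), side="left")
        v_at_frames = np.zeros(len(frames))
        for h in range(state.n_hills):
            i = first_frame[h]
            if i >= len(frames):
                break
            d2 = ((cvs[i:] - centers[h]) ** 2 / (2.0 * widths[h] ** 2)).sum(axis=1)
            v_at_frames[i:] += heights[h] * np.exp(-d2)
        # grid for c(t): span of the sampled CVs
        lo = cvs.min(axis=0)
        hi = cvs.max(axis=0)
        pad = 0.05 * (hi - lo + 1e-12)
        axes = [np.linspace(l - p, h + p, grid_bins) for l, h, p in zip(lo, hi, pad)]
        if cvs.shape[1] == 1:
            grid_pts = axes[0][:, None]
        else:
            mesh = np.meshgrid(*axes, indexing="ij")
            grid_pts = np.column_stack([m.ravel() for m in mesh])
        c_series = _wt_offset_series(state, grid_pts)
        c_at_frames = np.where(k_f > 0, c_series[np.maximum(k_f - 1, 0)], 0.0)
        log_w = (v_at_frames - c_at_frames) / kbt
        log_w -= log_w.max()
        w = np.exp(log_w)
    else:
        raise InputError(f"unknown reweighting scheme {scheme!r}")
    w = w / w.mean()
    for f, wi in zip(frames, w):
        f.weight = float(wi)
    return w


def _frame_values(frames: Sequence[FrameRecord], name: str, cv_names: Sequence[str]) -> np.ndarray:
    names = list(cv_names)
    if name in names:
        i = names.index(name)
        return np.array([f.cv[i] for f in frames])
    try:
        return np.array([f.observables[name] for f in frames])
    except KeyError:
        raise InputError(f"no CV or observable named {name!r}") from None


def project_fes(
    frames: Sequence[FrameRecord],
    weights: np.ndarray,
    axes_spec: Sequence[tuple],
    cv_names: Sequence[str] = ("s", "z"),
    temperature: float = 300.0,
) -> FreeEnergySurface:
    """Weighted-histogram free energy over 1–2 order parameters.

    ``axes_spec`` is a list of ``(name, nbins)`` or ``(name, nbins,
    (lo, hi))`` tuples; names refer to biasing CVs (via ``cv_names``) or to
    frame observables.  F = −k_BT·ln(p), min-shifted; empty bins are
    flagged as unoccupied, never extrapolated.
    """
    if len(axes_spec) not in (1, 2):
        raise InputError("only 1D and 2D projections supported")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(frames):
        raise InputError("weights length must match frames")
    cols = []
    edges = []
    axes = []
    for spec in axes_spec:
        name, nbins = spec[0], int(spec[1])
        vals = _frame_values(frames, name, cv_names)
        if len(spec) > 2 and spec[2] is not None:
            lo, hi = spec[2]
        else:
            lo, hi = float(vals.min()), float(vals.max())
            if hi <= lo:
                hi = lo + 1e-9
        e = np.linspace(lo, hi, nbins + 1)
        cols.append(vals)
        edges.append(e)
        axes.append(FESAxis(name=name, centers=0.5 * (e[1:] + e[:-1])))
    sample = np.column_stack(cols)
    hist, _ = np.histogramdd(sample, bins=edges, weights=weights)
    total = hist.sum()
    if total <= 0:
        raise InputError("no samples fall inside the requested axes ranges")
    occupied = hist > 0
    if occupied.sum() == 1 and hist.size > 1:
        import warnings

        warnings.warn("all weight concentrated in a single bin", stacklevel=2)
    kbt = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(hist / total)
    f[~occupied] = np.inf
    return FreeEnergySurface(axes=axes, values=f, occupied=occupied,
                             meta={"temperature": temperature, "n_frames": len(frames)})


# ---------------------------------------------------------------------------
# basin / barrier analysis


@dataclass
class BasinTable:
    """Local minima and the barriers between adjacent pairs.

    ``minima`` has columns (axis location(s), F, starred); ``transitions``
    has, for each adjacent pair of minima, the saddle free energy and the
    barrier height measured from the lower of the two minima.  The most
    stable basin is starred; when two basins are within 0.05 kcal/mol the
    one at the lower first-axis value is starred (deterministic
    tie-break).
    """

    minima: pd.DataFrame
    transitions: pd.DataFrame

    def starred(self) -> pd.Series:
        return self.minima[self.minima["starred"]].iloc[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# minima\n")
            self.minima.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            fh.write("# transitions\n")
            self.transitions.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _minimax_barrier(f: np.ndarray, i: int, j: int) -> tuple[int, float]:
    lo, hi = (i, j) if i < j else (j, i)
    seg = f[lo : hi + 1]
    k = int(np.argmax(seg)) + lo
    return k, float(f[k])


def find_basins_and_barriers(
    fes: FreeEnergySurface,
    min_depth: float = 0.2,
    basin_labels: Sequence[tuple] | None = None,
) -> BasinTable:
    """Locate local minima and the barriers separating adjacent ones.

    1D: minima are bins whose prominence (relative to the shallower
    adjacent saddle) exceeds ``min_depth`` kcal/mol; the barrier between an
    adjacent pair is the maximum F on the segment between them minus the
    lower minimum.  2D: callers pass ``basin_labels`` as approximate
    (x, y) basin seeds; minima are refined to the lowest bin near each
    seed and barriers are min-max path heights over the occupied-bin
    adjacency graph (the lowest level at which the two basins connect).
    """
    if fes.ndim == 1:
        return _basins_1d(fes, min_depth)
    if basin_labels is None:
        raise InputError("2D basin analysis needs approximate basin seed locations")
    return _basins_2d(fes, basin_labels)


def _basins_1d(fes: FreeEnergySurface, min_depth: float) -> BasinTable:
    from scipy.signal import find_peaks

    x = fes.axes[0].centers
    f = fes.values.copy()
    occ = fes.occupied
    big = np.nanmax(f[occ]) + 10.0 * max(min_depth, 1.0) if occ.any() else 0.0
    f_filled = np.where(occ, f, big)
    # pad so boundary minima are detectable
    padded = np.concatenate([[f_filled[0] + 2 * big + 1], f_filled, [f_filled[-1] + 2 * big + 1]])
    idx, _ = find_peaks(-padded, prominence=min_depth)
    idx = idx - 1
    idx = np.array([i for i in idx if occ[i]], dtype=int)
    name = fes.axes[0].name
    if idx.size == 0:
        return BasinTable(
            minima=pd.DataFrame(columns=[name, "F", "starred"]),
            transitions=pd.DataFrame(columns=[f"{name}_saddle", "F_saddle", "barrier"]),
        )
    order = np.argsort(x[idx])
    idx = idx[order]
    fmins = f[idx]
    starred = _star(fmins, x[idx])
    minima = pd.DataFrame({name: x[idx], "F": fmins, "starred": starred})
    rows = []
    for a, b in zip(idx[:-1], idx[1:]):
        k, fsad = _minimax_barrier(f_filled, a, b)
        rows.append({
            f"{name}_saddle": x[k],
            "F_saddle": fsad,
            "barrier": fsad - min(f[a], f[b]),
        })
    return BasinTable(minima=minima, transitions=pd.DataFrame(rows))


def _star(fmins: np.ndarray, locs: np.ndarray, tol: float = 0.05) -> np.ndarray:
    starred = np.zeros(len(fmins), dtype=bool)
    candidates = np.flatnonzero(fmins <= fmins.min() + tol)
    starred[candidates[np.argmin(locs[candidates])]] = True
    return starred


def _basins_2d(fes: FreeEnergySurface, seeds: Sequence[tuple]) -> BasinTable:
    xc, yc = fes.axes[0].centers, fes.axes[1].centers
    f = fes.values
    occ = fes.occupied
    basins = []
    for sx, sy in seeds:
        i0 = int(np.argmin(np.abs(xc - sx)))
        j0 = int(np.argmin(np.abs(yc - sy)))
        # refine to the lowest occupied bin within a local window
        wi = max(2, len(xc) // 10)
        wj = max(2, len(yc) // 10)
        ii = slice(max(0, i0 - wi), min(len(xc), i0 + wi + 1))
        jj = slice(max(0, j0 - wj), min(len(yc), j0 + wj + 1))
        sub = np.where(occ[ii, jj], f[ii, jj], np.inf)
        k = np.unravel_index(np.argmin(sub), sub.shape)
        basins.append((k[0] + ii.start, k[1] + jj.start))
    fmins = np.array([f[b] for b in basins])
    locs = np.array([xc[b[0]] for b in basins])
    starred = _star(fmins, locs)
    minima = pd.DataFrame({
        fes.axes[0].name: [xc[b[0]] for b in basins],
        fes.axes[1].name: [yc[b[1]] for b in basins],
        "F": fmins,
        "starred": starred,
    })
    rows = []
    for a, b in zip(basins[:-1], basins[1:]):
        fsad = _minimax_connect(f, occ, a, b)
        rows.append({"F_saddle": fsad, "barrier": fsad - min(f[a], f[b])})
    return BasinTable(minima=minima, transitions=pd.DataFrame(rows))


def _minimax_connect(f: np.ndarray, occ: np.ndarray, a: tuple, b: tuple) -> float:
    """Lowest F level at which bins a and b join, via union-find percolation."""
    shape = f.shape
    flat = np.flatnonzero(occ.ravel())
    order = flat[np.argsort(f.ravel()[flat])]
    parent = {}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u, v):
        parent[find(u)] = find(v)

    ia = a[0] * shape[1] + a[1]
    ib = b[0] * shape[1] + b[1]
    added = set()
    for u in order:
        parent[u] = u
        added.add(u)
        i, j = divmod(u, shape[1])
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                v = ni * shape[1] + nj
                if v in added:
                    union(u, v)
        if ia in added and ib in added and find(ia) == find(ib):
            return float(f.ravel()[u])
    return float("inf")
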