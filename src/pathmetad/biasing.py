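"""Adaptive biasing: ratchet (adiabatic-bias) rule and well-tempered metadynamics.

Two bias rules are implemented:

* **Ratchet / adiabatic bias.**  A harmonic penalty on an order parameter
  χ that acts only when χ(t) − χ₀ exceeds the minimum value it has reached
  so far: progress toward the target is free, backsliding is penalised by
  ½k(χ − χ₀ − best)².

* **Well-tempered metadynamics.**  Repulsive Gaussians of width σ_i are
  deposited every τ ps along the collective variables; each new hill's
  height is w·exp(−V/(k_B ΔT)) where V is the bias already accumulated at
  the deposition point, so hills shrink where much bias exists and the
  total bias converges smoothly.  The free energy is then estimated as
  F = −(T+ΔT)/ΔT · V, min-shifted.

Bias evaluation during dynamics goes through an auto-expanding grid cache
(linear interpolation on a fine grid, spacing σ/12 by default); the exact
Gaussian summation is always available and is what hill heights are
computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .constants import KB_KCAL, KCAL_PER_MOL_TO_AMU_A2_PS2
from .errors import ConfigError, InputError, IntegrationError
from .fes import FESAxis, FreeEnergySurface
from .toy_systems import baoab_step, overdamped_step

__all__ = [
    "RatchetState",
    "ratchet_bias",
    "WellTemperedConfig",
    "HillRecord",
    "BiasState",
    "wt_hill_height",
    "deposit_hill",
    "evaluate_bias",
    "free_energy_estimate",
    "run_metadynamics",
    "convergence_monitor",
    "MetadTrajectory",
]


# ---------------------------------------------------------------------------
# ratchet


@dataclass(frozen=True)
class RatchetState:
    """State of the ratchet bias on one order parameter.

    ``running_best`` is min over the past of χ(t) − χ₀ and is
    non-increasing in time.
    """

    chi_target: float
    k: float  # kcal/(mol · unit²), units of χ
    running_best: float

    @classmethod
    def initialize(cls, chi0_value: float, chi_target: float, k: float) -> "RatchetState":
        if k < 0:
            raise ConfigError("ratchet elastic constant must be non-negative")
        return cls(chi_target=chi_target, k=k, running_best=chi0_value - chi_target)


def ratchet_bias(chi: float, state: RatchetState) -> tuple[float, float, RatchetState]:
    """Ratchet bias energy at χ, its dE/dχ, and the updated state.

    When χ − χ₀ improves on the running best the bias is zero and the best
    is updated; otherwise the harmonic penalty ½k(χ − χ₀ − best)² applies
    and the best is unchanged.
    """
    excess = (chi - state.chi_target) - state.running_best
    if excess <= 0.0:
        return 0.0, 0.0, replace(state, running_best=chi - state.chi_target)
    energy = 0.5 * state.k * excess**2
    return energy, state.k * excess, state


# ---------------------------------------------------------------------------
# well-tempered metadynamics


@dataclass(frozen=True)
class WellTemperedConfig:
    """Well-tempered metadynamics parameters.

    Defaults follow the standard receptor-activation setup: initial hill
    height w = 0.4 kcal/mol, deposition interval τ = 8 ps, ΔT = 10·T at
    T = 300 K, hill widths (σ_s, σ_z) = (0.1, 1 Å²).
    """

    w: float = 0.4  # kcal/mol
    tau: float = 8.0  # ps
    temperature: float = 300.0  # K
    delta_t: float = 3000.0  # K
    sigma: tuple[float, ...] = (0.1, 1.0)
    cv_names: tuple[str, ...] = ("s", "z")

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ConfigError("hill height w must be non-negative")
        if self.tau <= 0 or self.temperature <= 0 or self.delta_t <= 0:
            raise ConfigError("tau, temperature and delta_t must be positive")
        if any(s <= 0 for s in self.sigma):
            raise ConfigError("hill widths must be positive")
        if len(self.cv_names) != len(self.sigma):
            raise ConfigError("cv_names and sigma must have equal length")

    @property
    def bias_factor(self) -> float:
        return (self.temperature + self.delta_t) / self.temperature

    @property
    def n_cv(self) -> int:
        return len(self.sigma)


@dataclass(frozen=True)
class HillRecord:
    time: float  # ps
    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float  # kcal/mol


def wt_hill_height(bias_at_center: float, cfg: WellTemperedConfig) -> float:
    """Height of the next hill given the bias already present at its centre:
    w·exp(−V/(k_B ΔT)).  Strictly decreasing in the accumulated bias."""
    if bias_at_center < 0:
        raise InputError("accumulated bias cannot be negative")
    return cfg.w * np.exp(-bias_at_center / (KB_KCAL * cfg.delta_t))


class _BiasGrid:
    """Fine regular grid caching V and ∇V, expanded on demand."""

    def __init__(self, lows: np.ndarray, highs: np.ndarray, spacings: np.ndarray):
        self.spacings = np.asarray(spacings, dtype=float)
        self.axes = [
            np.arange(lo, hi + 0.5 * sp, sp)
            for lo, hi, sp in zip(lows, highs, self.spacings)
        ]
        shape = tuple(len(a) for a in self.axes)
        self.v = np.zeros(shape)
        self.dv = [np.zeros(shape) for _ in self.axes]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def contains(self, pt: np.ndarray, margin: np.ndarray) -> bool:
        return all(
            ax[0] <= p - m and p + m <= ax[-1]
            for ax, p, m in zip(self.axes, pt, margin)
        )

    def add_hill(self, center: np.ndarray, widths: np.ndarray, height: float) -> None:
        mesh = [ax - c for ax, c in zip(self.axes, center)]
        if self.ndim == 1:
            d = mesh[0]
            g = height * np.exp(-0.5 * (d / widths[0]) ** 2)
            self.v += g
            self.dv[0] += g * (-d / widths[0] ** 2)
        else:
            gx = np.exp(-0.5 * (mesh[0] / widths[0]) ** 2)
            gy = np.exp(-0.5 * (mesh[1] / widths[1]) ** 2)
            g = height * gx[:, None] * gy[None, :]
            self.v += g
            self.dv[0] += g * (-mesh[0][:, None] / widths[0] ** 2)
            self.dv[1] += g * (-mesh[1][None, :] / widths[1] ** 2)

    def _locate(self, pt: np.ndarray) -> tuple[list[int], list[float]]:
        idx = []
        frac = []
        for ax, p in zip(self.axes, pt):
            x = (float(p) - ax[0]) / (ax[1] - ax[0])
            i = int(x)
            hi = len(ax) - 2
            if i < 0:
                i = 0
            elif i > hi:
                i = hi
            idx.append(i)
            frac.append(x - i)
        return idx, frac

    def _interp(self, arr: np.ndarray, idx, frac) -> float:
        if self.ndim == 1:
            i, t = idx[0], frac[0]
            return float(arr[i] * (1 - t) + arr[i + 1] * t)
        i, j = idx
        tx, ty = frac
        return float(
            arr[i, j] * (1 - tx) * (1 - ty)
            + arr[i + 1, j] * tx * (1 - ty)
            + arr[i, j + 1] * (1 - tx) * ty
            + arr[i + 1, j + 1] * tx * ty
        )

    @staticmethod
    def _cr_weights(t: float) -> tuple[float, float, float, float]:
        # Catmull-Rom cubic convolution weights for the 4-point stencil
        t2 = t * t
        t3 = t2 * t
        return (
            0.5 * (-t3 + 2 * t2 - t),
            0.5 * (3 * t3 - 5 * t2 + 2),
            0.5 * (-3 * t3 + 4 * t2 + t),
            0.5 * (t3 - t2),
        )

    def value(self, pt: np.ndarray) -> float:
        """Cubic (Catmull-Rom) interpolation of V; C¹ and ~(Δ/σ)³ accurate."""
        idx, frac = self._locate(pt)
        if self.ndim == 1:
            i, t = idx[0], frac[0]
            n = len(self.axes[0])
            stencil = [min(max(i + k, 0), n - 1) for k in (-1, 0, 1, 2)]
            w = self._cr_weights(t)
            return float(sum(wk * self.v[s] for wk, s in zip(w, stencil)))
        i, j = idx
        tx, ty = frac
        nx, ny = (len(a) for a in self.axes)
        sx = [min(max(i + k, 0), nx - 1) for k in (-1, 0, 1, 2)]
        sy = [min(max(j + k, 0), ny - 1) for k in (-1, 0, 1, 2)]
        wx = self._cr_weights(tx)
        wy = self._cr_weights(ty)
        patch = self.v[np.ix_(sx, sy)]
        return float(np.array(wx) @ patch @ np.array(wy))

    def gradient(self, pt: np.ndarray) -> np.ndarray:
        idx, frac = self._locate(pt)
        return np.array([self._interp(d, idx, frac) for d in self.dv])


class BiasState:
    """Deposited hills plus the well-tempered configuration.

    Evaluable as V(cv) either by exact Gaussian summation
    (:meth:`evaluate`) or through the grid cache used during dynamics;
    the two agree within the grid interpolation tolerance.  Hills falling
    outside the grid extent trigger grid growth, never truncation.
    """

    #: grid spacing as a fraction of the hill width
    GRID_SPACING_FRACTION = 1.0 / 16.0

    def __init__(self, cfg: WellTemperedConfig, use_grid: bool = True):
        self.cfg = cfg
        self.times: list[float] = []
        self._centers: list[np.ndarray] = []
        self._heights: list[float] = []
        self._widths: list[np.ndarray] = []
        self.use_grid = use_grid
        self._grid: _BiasGrid | None = None
        self._centers_arr: np.ndarray | None = None  # cache for vectorised eval

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_hills(self) -> int:
        return len(self._heights)

    @property
    def hills(self) -> list[HillRecord]:
        return [
            HillRecord(t, tuple(c), tuple(w), h)
            for t, c, w, h in zip(self.times, self._centers, self._widths, self._heights)
        ]

    def centers(self) -> np.ndarray:
        if self._centers_arr is None or self._centers_arr.shape[0] != self.n_hills:
            self._centers_arr = (
                np.array(self._centers) if self._centers else np.empty((0, self.cfg.n_cv))
            )
        return self._centers_arr

    def heights(self) -> np.ndarray:
        return np.asarray(self._heights)

    def widths(self) -> np.ndarray:
        return np.array(self._widths) if self._widths else np.empty((0, self.cfg.n_cv))

    # -- evaluation --------------------------------------------------------
    def evaluate(self, cv: np.ndarray, n_hills: int | None = None) -> float | np.ndarray:
        """Exact bias at one point (shape (k,)) or many points (shape (m, k)).

        ``n_hills`` restricts the sum to the first so-many hills (bias at an
        earlier time)."""
        pts = np.atleast_2d(np.asarray(cv, dtype=float))
        k = min(n_hills, self.n_hills) if n_hills is not None else self.n_hills
        if k == 0:
            out = np.zeros(pts.shape[0])
        else:
            c = self.centers()[:k]
            w = self.widths()[:k]
            h = self.heights()[:k]
            out = np.zeros(pts.shape[0])
            # chunk over query points to keep the (points × hills) block small
            block = max(1, int(4e6) // max(k, 1))
            for i in range(0, pts.shape[0], block):
                p = pts[i : i + block]
                d2 = ((p[:, None, :] - c[None, :, :]) ** 2 / (2.0 * w[None, :, :] ** 2)).sum(axis=2)
                out[i : i + block] = (h[None, :] * np.exp(-d2)).sum(axis=1)
        return float(out[0]) if np.asarray(cv).ndim == 1 else out

    def evaluate_grid(self, cv: np.ndarray) -> float:
        if self._grid is None:
            return 0.0
        return self._grid.value(np.asarray(cv, dtype=float))

    def gradient(self, cv: np.ndarray, exact: bool = False) -> np.ndarray:
        """∂V/∂cv; grid-interpolated during dynamics, analytic when exact."""
        pt = np.asarray(cv, dtype=float)
        if not exact and self._grid is not None:
            return self._grid.gradient(pt)
        if self.n_hills == 0:
            return np.zeros(self.cfg.n_cv)
        c = self.centers()
        w = self.widths()
        h = self.heights()
        diff = pt[None, :] - c
        g = h * np.exp(-(diff**2 / (2.0 * w**2)).sum(axis=1))
        return (g[:, None] * (-diff / w**2)).sum(axis=0)

    # -- deposition --------------------------------------------------------
    def _ensure_grid(self, center: np.ndarray, widths: np.ndarray) -> None:
        margin = 6.0 * widths
        if self._grid is None:
            sp = widths * self.GRID_SPACING_FRACTION
            self._grid = _BiasGrid(center - margin, center + margin, sp)
            return
        if self._grid.contains(center, margin):
            return
        # grow: rebuild over the union extent and replay all hills
        lows = np.array([min(ax[0], c - m) for ax, c, m in
                         zip(self._grid.axes, center, margin)])
        highs = np.array([max(ax[-1], c + m) for ax, c, m in
                          zip(self._grid.axes, center, margin)])
        new = _BiasGrid(lows, highs, self._grid.spacings)
        for c0, w0, h0 in zip(self._centers, self._widths, self._heights):
            new.add_hill(c0, w0, h0)
        self._grid = new

    def deposit(self, cv: np.ndarray, time: float) -> HillRecord:
        center = np.asarray(cv, dtype=float)
        if not np.all(np.isfinite(center)):
            raise InputError("cannot deposit a hill at non-finite CV values")
        if center.shape != (self.cfg.n_cv,):
            raise InputError(f"CV vector must have length {self.cfg.n_cv}")
        widths = np.asarray(self.cfg.sigma, dtype=float)
        height = wt_hill_height(float(self.evaluate(center)), self.cfg)
        if self.use_grid:
            # grow/replay over existing hills before this one is appended
            self._ensure_grid(center, widths)
            self._grid.add_hill(center, widths, height)  # type: ignore[union-attr]
        self.times.append(float(time))
        self._centers.append(center.copy())
        self._widths.append(widths.copy())
        self._heights.append(float(height))
        self._centers_arr = None
        return HillRecord(float(time), tuple(center), tuple(widths), float(height))


def deposit_hill(state: BiasState, cv: Sequence[float], time: float) -> BiasState:
    """Append one well-tempered hill at ``cv``; returns the mutated state."""
    state.deposit(np.asarray(cv, dtype=float), time)
    return state


def evaluate_bias(state: BiasState, cv: Sequence[float]) -> float:
    """Exact total bias V(cv) in kcal/mol."""
    return float(state.evaluate(np.asarray(cv, dtype=float)))


def free_energy_estimate(
    state: BiasState,
    axes: Sequence[FESAxis] | None = None,
    n_hills: int | None = None,
) -> FreeEnergySurface:
    """Well-tempered free-energy estimate F = −(T+ΔT)/ΔT · V, min-shifted.

    ``axes`` default to a grid spanning the deposited hills ±4σ with 200
    bins per CV (1D) or 80 per CV (2D).
    """
    if state.n_hills == 0:
        raise InputError("no hills deposited; free energy undefined")
    cfg = state.cfg
    if axes is None:
        c = state.centers()
        w = np.asarray(cfg.sigma)
        nb = 200 if cfg.n_cv == 1 else 80
        axes = [
            FESAxis.from_range(name, c[:, i].min() - 4 * w[i], c[:, i].max() + 4 * w[i], nb)
            for i, name in enumerate(cfg.cv_names)
        ]
    prefactor = -(cfg.temperature + cfg.delta_t) / cfg.delta_t
    if len(axes) == 1:
        pts = axes[0].centers[:, None]
        v = state.evaluate(pts, n_hills=n_hills)
        values = prefactor * v
    else:
        xg, yg = np.meshgrid(axes[0].centers, axes[1].centers, indexing="ij")
        pts = np.column_stack([xg.ravel(), yg.ravel()])
        v = state.evaluate(pts, n_hills=n_hills)
        values = (prefactor * v).reshape(xg.shape)
    return FreeEnergySurface(axes=list(axes), values=values,
                             meta={"prefactor": prefactor, "n_hills": n_hills or state.n_hills})


# ---------------------------------------------------------------------------
# metadynamics driver


@dataclass
class MetadTrajectory:
    """Recorded frames of a metadynamics (or unbiased) run."""

    times: np.ndarray  # (F,) ps
    cvs: np.ndarray  # (F, k)
    bias: np.ndarray  # (F,) instantaneous V(cv, t) at each frame
    coords: np.ndarray | None = None  # (F, n_dof) when requested
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CVWall:
    """One-sided quartic restraining wall on a CV: E = k·(cv − bound)⁴ beyond it."""

    cv_index: int
    lower: float | None = None
    upper: float | None = None
    k: float = 500.0

    def energy_and_gradient(self, value: float) -> tuple[float, float]:
        if self.lower is not None and value < self.lower:
            d = value - self.lower
            return self.k * d**4, 4.0 * self.k * d**3
        if self.upper is not None and value > self.upper:
            d = value - self.upper
            return self.k * d**4, 4.0 * self.k * d**3
        return 0.0, 0.0


def run_metadynamics(
    system,
    cfg: WellTemperedConfig,
    steps: int,
    dt: float,
    seed: int,
    integrator: str = "overdamped",
    diffusion: float = 1.0,
    friction: float = 1.0,
    colvar_stride: int = 10,
    walls: Sequence[CVWall] = (),
    x0: np.ndarray | None = None,
    record_coords: bool = False,
) -> tuple[MetadTrajectory, BiasState]:
    """Langevin dynamics with well-tempered metadynamics bias on the CVs.

    ``system`` must expose ``n_dof``, ``initial_coords``, ``force(x)`` and
    ``cv_and_jacobian(x)`` (and ``masses`` for the inertial integrator).
    Hills are deposited every ``round(τ/dt)`` steps, so hill times are the
    exact multiples of the effective deposition interval.  With ``w = 0``
    the bias is identically zero and the trajectory is bit-identical to an
    unbiased run with the same seed.  Fully reproducible given ``seed``.
    """
    if steps < 0 or dt <= 0:
        raise InputError("steps must be ≥ 0 and dt > 0")
    rng = np.random.default_rng(seed)
    state = BiasState(cfg)
    x = np.array(x0 if x0 is not None else system.initial_coords, dtype=float)
    deposit_every = max(1, int(round(cfg.tau / dt)))

    def total_force(xx: np.ndarray) -> np.ndarray:
        cv, jac = system.cv_and_jacobian(xx)
        f = system.force(xx)
        if state.n_hills:
            f = f - state.gradient(cv) @ jac
        for wall in walls:
            _, g = wall.energy_and_gradient(float(cv[wall.cv_index]))
            if g != 0.0:
                f = f - g * jac[wall.cv_index]
        return f

    f = total_force(x)
    v = np.zeros_like(x)
    if integrator == "baoab":
        masses = np.asarray(getattr(system, "masses", np.ones(system.n_dof)), dtype=float)
        kbt = KB_KCAL * cfg.temperature
        v = rng.standard_normal(x.shape) * np.sqrt(kbt * KCAL_PER_MOL_TO_AMU_A2_PS2 / masses)

    rec_t: list[float] = []
    rec_cv: list[np.ndarray] = []
    rec_bias: list[float] = []
    rec_x: list[np.ndarray] = []

    def record(step: int) -> None:
        cv = system.cv(x)
        rec_t.append(step * dt)
        rec_cv.append(np.asarray(cv, dtype=float).copy())
        rec_bias.append(float(state.evaluate(cv)) if state.n_hills else 0.0)
        if record_coords:
            rec_x.append(x.copy())

    record(0)
    for step in range(1, steps + 1):
        if integrator == "overdamped":
            x, f = overdamped_step(x, total_force, dt, diffusion, cfg.temperature, rng, f=f)
        elif integrator == "baoab":
            x, v, f = baoab_step(x, v, f, total_force, dt, friction, cfg.temperature, masses, rng)
        else:
            raise ConfigError(f"unknown integrator {integrator!r}")
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite coordinates at step {step}")
        if cfg.w > 0 and step % deposit_every == 0:
            state.deposit(np.asarray(system.cv(x), dtype=float), step * dt)
            f = total_force(x)  # bias changed under our feet
        if step % colvar_stride == 0:
            record(step)

    traj = MetadTrajectory(
        times=np.array(rec_t),
        cvs=np.array(rec_cv),
        bias=np.array(rec_bias),
        coords=np.array(rec_x) if record_coords else None,
        seed=seed,
    )
    return traj, state


def convergence_monitor(
    state: BiasState,
    checkpoints: Sequence[float],
    region_a: Callable[[np.ndarray], np.ndarray],
    region_b: Callable[[np.ndarray], np.ndarray],
    axes: Sequence[FESAxis] | None = None,
) -> dict:
    """Free-energy difference between two CV regions at successive times.

    ``region_a``/``region_b`` map an (m, k) array of grid points to boolean
    membership masks.  For each checkpoint time the hills deposited up to
    that time define a free-energy estimate; the region free energies are
    Boltzmann-integrated at the simulation temperature and their
    difference ΔF = F_b − F_a reported, together with the trailing
    fluctuation amplitude (max − min of ΔF over the second half of the
    checkpoints).
    """
    if len(checkpoints) < 2:
        raise InputError("need at least two checkpoints")
    kbt = KB_KCAL * state.cfg.temperature
    times = np.asarray(state.times)
    deltas = []
    for t in checkpoints:
        n = int(np.searchsorted(times, t, side="right"))
        if n == 0:
            deltas.append(np.nan)
            continue
        surf = free_energy_estimate(state, axes=axes, n_hills=n)
        if surf.ndim == 1:
            pts = surf.axes[0].centers[:, None]
        else:
            xg, yg = np.meshgrid(surf.axes[0].centers, surf.axes[1].centers, indexing="ij")
            pts = np.column_stack([xg.ravel(), yg.ravel()])
        fvals = surf.values.ravel()
        in_a = np.asarray(region_a(pts), dtype=bool)
        in_b = np.asarray(region_b(pts), dtype=bool)
        if not in_a.any() or not in_b.any():
            raise InputError("a convergence region contains no grid points")
        fa = -kbt * np.log(np.exp(-fvals[in_a] / kbt).sum())
        fb = -kbt * np.log(np.exp(-fvals[in_b] / kbt).sum())
        deltas.append(fb - fa)
    deltas_arr = np.array(deltas)
    tail = deltas_arr[len(deltas_arr) // 2:]
    tail = tail[np.isfinite(tail)]
    fluct = float(tail.max() - tail.min()) if tail.size else np.nan
    return {
        "checkpoints": np.asarray(checkpoints, dtype=float),
        "delta_f": deltas_arr,
        "trailing_fluctuation": fluct,
    }
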