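"""Synthetic toy systems with known free energies.

This module generates every fixture the rest of the package is exercised
on:

* analytic 1D/2D potentials (tilted double wells, harmonic wells) whose
  minima, saddles and barrier heights are known in closed form;
* a seedable Langevin integrator (inertial BAOAB and an overdamped
  Euler–Maruyama variant) in the package unit system (Å, ps, amu,
  kcal/mol);
* a labelled "mini-receptor": a 28-bead seven-helix bundle with
  pseudo-residues carrying the Ballesteros–Weinstein tags (2.41, 3.50,
  6.30, 6.35, 6.48) and the PDB atom names the activation descriptors
  need, built in two end states whose descriptor values are construction
  targets (inactive: d_IL = 3 Å, χ_TS = 163°, Δd_TM6 = 0; active:
  d_IL = 12 Å, χ_TS = 55°, Δd_TM6 = 5.9 Å), plus a harmonic-network
  energy with a switchable double-well collective mode connecting them.

The mini-receptor emulates the geometry of GPCR activation (outward TM6
swing, ionic-lock breakage, toggle-switch rotamer flip) at bead
resolution; it carries no realistic protein energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import KB_KCAL, KCAL_PER_MOL_TO_AMU_A2_PS2
from .descriptors import ResidueMap
from .errors import InputError, IntegrationError
from .geometry import Conformation

__all__ = [
    "AnalyticPotential",
    "make_double_well",
    "make_double_well_2d",
    "make_harmonic",
    "baoab_step",
    "overdamped_step",
    "MiniReceptor",
    "MiniReceptorSystem",
    "TwoStateNetworkSystem",
    "make_two_state_chain",
    "make_mini_receptor",
    "interpolated_trajectory",
]


# ---------------------------------------------------------------------------
# analytic potentials


@dataclass
class AnalyticPotential:
    """A low-dimensional potential with closed-form stationary points.

    ``minima`` and ``saddles`` are lists of (location, energy) pairs; the
    locations are arrays of length ``dimension``.  The potential doubles as
    a "system" for the biasing engine: its collective variables are the
    coordinates themselves.
    """

    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    minima: list[tuple[np.ndarray, float]]
    saddles: list[tuple[np.ndarray, float]]
    label: str = ""
    cv_ranges: list[tuple[float, float]] = field(default_factory=list)

    # --- system protocol used by the biasing engine -----------------------
    @property
    def n_dof(self) -> int:
        return self.dimension

    @property
    def initial_coords(self) -> np.ndarray:
        return np.array(self.minima[0][0], dtype=float)

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.gradient(x)

    def cv(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def cv_and_jacobian(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(x, dtype=float), np.eye(self.dimension)

    @property
    def cv_names(self) -> list[str]:
        return [f"x{i+1}" for i in range(self.dimension)] if self.dimension > 1 else ["x"]

    @property
    def barrier(self) -> float:
        """Lowest saddle energy minus the global minimum energy."""
        if not self.saddles:
            raise InputError("potential has no saddle")
        fmin = min(e for _, e in self.minima)
        return min(e for _, e in self.saddles) - fmin

    @property
    def minima_energy_difference(self) -> float:
        """Energy of the higher minimum minus the lower one (≥ 0)."""
        es = sorted(e for _, e in self.minima)
        return es[-1] - es[0]


def make_double_well(barrier: float, asymmetry: float = 0.0, width: float = 1.0) -> AnalyticPotential:
    """Tilted quartic double well U(x) = b[(x/w)² − 1]² + a·x/(2w).

    ``barrier`` (b, kcal/mol) is the untilted barrier between the wells;
    ``asymmetry`` (a) tilts the two minima apart by ≈ a to first order;
    ``width`` (w, Å) puts the untilted minima at x = ±w.  The exact
    stationary points of the tilted polynomial are found by root-finding
    and stored, so the reported barrier accounts for the tilt.
    """
    if barrier <= 0:
        raise InputError("barrier must be positive")
    b, a, w = float(barrier), float(asymmetry), float(width)

    def energy(x):
        u = np.asarray(x, dtype=float) / w
        val = b * (u**2 - 1.0) ** 2 + a * u / 2.0
        return float(val) if np.ndim(x) == 0 or np.shape(x) == (1,) else val

    def gradient(x):
        u = np.atleast_1d(np.asarray(x, dtype=float))[0] / w
        return np.array([(4.0 * b * (u**2 - 1.0) * u + a / 2.0) / w])

    # dU/du = 4b(u³ − u) + a/2 = 0
    roots = np.roots([4.0 * b, 0.0, -4.0 * b, a / 2.0])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    minima: list[tuple[np.ndarray, float]] = []
    saddles: list[tuple[np.ndarray, float]] = []
    for u0 in real:
        x0 = np.array([u0 * w])
        e0 = b * (u0**2 - 1.0) ** 2 + a * u0 / 2.0
        curv = 12.0 * b * u0**2 - 4.0 * b
        (minima if curv > 0 else saddles).append((x0, float(e0)))
    return AnalyticPotential(
        dimension=1, energy=lambda x: float(energy(np.atleast_1d(x)[0])),
        gradient=gradient, minima=minima, saddles=saddles,
        label=f"double_well(b={b}, a={a}, w={w})",
        cv_ranges=[(-2.0 * w, 2.0 * w)],
    )


def make_double_well_2d(
    barrier: float, asymmetry: float = 0.0, width: float = 1.0, k_perp: float = 2.0
) -> AnalyticPotential:
    """Double well along x plus a harmonic channel in y."""
    dw = make_double_well(barrier, asymmetry, width)

    def energy(p):
        x, y = p
        return dw.energy(np.array([x])) + 0.5 * k_perp * y**2

    def gradient(p):
        x, y = p
        return np.array([dw.gradient(np.array([x]))[0], k_perp * y])

    minima = [(np.array([loc[0], 0.0]), e) for loc, e in dw.minima]
    saddles = [(np.array([loc[0], 0.0]), e) for loc, e in dw.saddles]
    return AnalyticPotential(
        dimension=2, energy=energy, gradient=gradient,
        minima=minima, saddles=saddles,
        label=f"double_well_2d(b={barrier}, a={asymmetry}, k_perp={k_perp})",
        cv_ranges=[(-2.0 * width, 2.0 * width), (-3.0, 3.0)],
    )


def make_harmonic(k_spring: float, center: float = 0.0) -> AnalyticPotential:
    """1D harmonic well, for equipartition checks."""
    c = float(center)

    def energy(x):
        return 0.5 * k_spring * (np.atleast_1d(x)[0] - c) ** 2

    def gradient(x):
        return np.array([k_spring * (np.atleast_1d(x)[0] - c)])

    return AnalyticPotential(
        dimension=1, energy=energy, gradient=gradient,
        minima=[(np.array([c]), 0.0)], saddles=[],
        label=f"harmonic(k={k_spring})", cv_ranges=[(c - 3.0, c + 3.0)],
    )


# ---------------------------------------------------------------------------
# Langevin integrators


def baoab_step(
    x: np.ndarray,
    v: np.ndarray,
    f: np.ndarray,
    force: Callable[[np.ndarray], np.ndarray],
    dt: float,
    friction: float,
    temperature: float,
    masses: np.ndarray | float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One inertial BAOAB Langevin update.

    ``f`` is the force at ``x`` (kcal/mol/Å); the new force at the updated
    position is returned so consecutive steps need one force evaluation
    each.  ``friction`` is in 1/ps; a stable regime needs dt·friction ≲ 0.1
    and dt well below the fastest oscillation period.
    """
    m = np.asarray(masses, dtype=float)
    conv = KCAL_PER_MOL_TO_AMU_A2_PS2
    v = v + 0.5 * dt * f * conv / m
    x = x + 0.5 * dt * v
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * KB_KCAL * temperature * conv / m)
    v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    f_new = force(x)
    if not np.all(np.isfinite(f_new)):
        raise IntegrationError("non-finite force; integration unstable")
    v = v + 0.5 * dt * f_new * conv / m
    return x, v, f_new


def overdamped_step(
    x: np.ndarray,
    force: Callable[[np.ndarray], np.ndarray],
    dt: float,
    diffusion: float,
    temperature: float,
    rng: np.random.Generator,
    f: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One overdamped (Brownian) Euler–Maruyama update.

    dx = (D/k_BT)·F dt + √(2 D dt)·ξ, with diffusion coefficient D in
    Å²/ps.  Returns the new position and the force there.
    """
    kbt = KB_KCAL * temperature
    if f is None:
        f = force(x)
    x = x + (diffusion / kbt) * f * dt + np.sqrt(2.0 * diffusion * dt) * rng.standard_normal(np.shape(x))
    f_new = force(x)
    if not np.all(np.isfinite(f_new)):
        raise IntegrationError("non-finite force; integration unstable")
    return x, f_new


# ---------------------------------------------------------------------------
# mini-receptor construction


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a fourth point at given bond/angle/dihedral from a–b–c (NeRF)."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


_ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


def _mass_for(atom_name: str) -> float:
    return _ELEMENT_MASS.get(atom_name.strip()[0], 12.011)


@dataclass
class MiniReceptor:
    """A labelled bead-model receptor with two end-state conformations.

    ``inactive`` and ``active`` share atom ordering; ``residue_map`` carries
    the BW tags; ``ca_mask`` is the default metric/ABMD mask (all beads);
    ``align_mask`` is the d_TM6 alignment selection (Cα of the static core
    helices 2, 3 and 7, which do not move upon activation).
    """

    inactive: Conformation
    active: Conformation
    residue_map: ResidueMap
    ca_mask: np.ndarray
    align_mask: np.ndarray
    seed: int

    def system(
        self,
        barrier: float = 2.0,
        asymmetry: float = 1.0,
        k_orth: float = 10.0,
    ) -> "TwoStateNetworkSystem":
        return TwoStateNetworkSystem(
            self.inactive, self.active, barrier=barrier, asymmetry=asymmetry, k_orth=k_orth
        )


class TwoStateNetworkSystem:
    """Harmonic-network energy with a double-well collective mode.

    Coordinates are projected onto the inactive→active displacement vector
    D: q = (X − X_inactive)·D/|D|² is 0 at the inactive and 1 at the active
    end state.  The energy is a tilted double well in q (barrier and
    asymmetry in kcal/mol, untilted minima at q = 0 and q = 1) plus a
    harmonic restraint k_orth·|X_⊥|²/2 on the component orthogonal to the
    path.  Both end states are local minima by construction, the restraint
    stiffness is the same everywhere, so the free energy along q equals
    the double well up to a constant — the ground truth the sampling
    modules are validated against.  The energy is defined in the lab frame
    (no global roto-translational invariance), which keeps the toy model
    simple; descriptors and path CVs still superpose internally.
    """

    def __init__(
        self,
        inactive: Conformation,
        active: Conformation,
        barrier: float,
        asymmetry: float = 0.0,
        k_orth: float = 2.0,
    ):
        if inactive.n_atoms != active.n_atoms:
            raise InputError("end states must share atom count and ordering")
        self.inactive_state = inactive
        self.active_state = active
        self.k_orth = float(k_orth)
        # double well over u = 2q - 1 with untilted minima at u = ±1
        self.mode = make_double_well(barrier, asymmetry, width=1.0)
        self.x_in = inactive.coords.ravel()
        self.x_ac = active.coords.ravel()
        self.disp = self.x_ac - self.x_in
        self.disp_sq = float(self.disp @ self.disp)
        self.n_atoms = inactive.n_atoms
        self.masses = np.repeat(inactive.masses, 3)

    @property
    def n_dof(self) -> int:
        return self.x_in.size

    @property
    def initial_coords(self) -> np.ndarray:
        return self.x_in.copy()

    def projection(self, x: np.ndarray) -> float:
        """Collective mode coordinate q (0 = inactive, 1 = active)."""
        return float((x - self.x_in) @ self.disp / self.disp_sq)

    @property
    def minima_q(self) -> list[tuple[float, float]]:
        """Exact (q, energy) of the tilted collective-mode minima."""
        return [((u[0] + 1.0) / 2.0, e) for u, e in self.mode.minima]

    @property
    def saddle_q(self) -> tuple[float, float]:
        u, e = self.mode.saddles[0]
        return (u[0] + 1.0) / 2.0, e

    def energy(self, x: np.ndarray) -> float:
        dx = x - self.x_in
        q = float(dx @ self.disp / self.disp_sq)
        perp = dx - q * self.disp
        return self.mode.energy(np.array([2.0 * q - 1.0])) + 0.5 * self.k_orth * float(perp @ perp)

    def force(self, x: np.ndarray) -> np.ndarray:
        dx = x - self.x_in
        q = float(dx @ self.disp / self.disp_sq)
        perp = dx - q * self.disp
        dmode_du = self.mode.gradient(np.array([2.0 * q - 1.0]))[0]
        # dq/dx = D/|D|²; u = 2q − 1; the perp restraint gradient is k·perp
        # (the projector is idempotent and perp ⊥ D)
        grad = dmode_du * 2.0 * self.disp / self.disp_sq + self.k_orth * perp
        return -grad

    def conformation(self, x: np.ndarray) -> Conformation:
        return self.inactive_state.with_coords(x.reshape(-1, 3))


#: backward-looking alias: the mini-receptor system is a two-state network
MiniReceptorSystem = TwoStateNetworkSystem


def make_two_state_chain(
    n_beads: int = 6,
    displacement: float = 5.0,
    seed: int = 0,
) -> tuple[Conformation, Conformation]:
    """A stiff two-state bead chain for ratchet (ABMD) exercises.

    Returns two conformations of an ``n_beads`` chain whose end states
    differ by approximately ``displacement`` Å RMSD: every bead receives a
    deterministic pseudo-random displacement of that magnitude.  Pair with
    :class:`TwoStateNetworkSystem` (typically with a stiff orthogonal
    restraint and a low, target-tilted collective barrier) to get runs
    that reliably reach the target state.
    """
    if n_beads < 4:
        raise InputError("need at least 4 beads")
    rng = np.random.default_rng(seed)
    coords_in = np.column_stack([
        np.arange(n_beads) * 3.8,
        1.5 * np.sin(np.arange(n_beads)),
        np.zeros(n_beads),
    ])
    step = rng.normal(size=(n_beads, 3))
    step *= displacement / np.sqrt((step**2).sum(axis=1).mean())
    coords_ac = coords_in + step
    labels = dict(
        atom_names=["CA"] * n_beads,
        residue_ids=np.arange(1, n_beads + 1),
        residue_names=["GLY"] * n_beads,
        chain_ids=["A"] * n_beads,
        masses=np.full(n_beads, 12.011),
    )
    return Conformation(coords_in, **labels), Conformation(coords_ac, **labels)


def make_mini_receptor(seed: int = 0) -> MiniReceptor:
    """Deterministically build the two-state labelled mini-receptor.

    Seven 4-bead "helices" on a 9-Å circle; the activation transition
    rigidly swings helix 6 (TM6) outward so that the centroid of residue
    6.35 moves 5.9 Å away from the intracellular midpoint, tilts helices
    1, 4 and 5 (the TM5 tilt that accompanies agonist binding, plus minor
    rearrangements elsewhere), repositions the R3.50/E6.30 side-chain
    atoms so d_IL goes from exactly 3 Å to exactly 12 Å, and rebuilds the
    W6.48 side chain with χ1 = 163° (inactive) or 55° (active).  Helices
    2, 3 and 7 form a static core: they are identical in both end states,
    and the d_TM6 alignment mask is their Cα set, which makes the
    constructed Δd_TM6 exact.  ``seed`` only perturbs the helix axial
    phases by a tiny deterministic amount so distinct seeds give distinct
    but equivalent receptors.
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-0.1, 0.1, size=7)

    n_helices, beads_per = 7, 4
    radius, rise = 9.0, 3.0
    names: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    chains: list[str] = []
    coords: list[np.ndarray] = []

    special = {  # (helix index 1-based, bead index from intracellular end)
        (2, 0): ("2.41", "TYR"),
        (3, 0): ("3.50", "ARG"),
        (6, 0): ("6.30", "GLU"),
        (6, 1): ("6.35", "LYS"),
        (6, 2): ("6.48", "TRP"),
    }
    bw_entries: dict[str, tuple] = {}

    resid = 0
    bead_xyz: dict[tuple[int, int], np.ndarray] = {}
    for h in range(1, n_helices + 1):
        ang = 2.0 * np.pi * (h - 1) / n_helices
        axis_xy = radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        for b in range(beads_per):
            resid += 1
            pos = axis_xy + np.array([0.0, 0.0, rise * b + phase[h - 1]])
            label = special.get((h, b))
            res_name = label[1] if label else "GLY"
            if label:
                bw_entries[label[0]] = ("A", resid, res_name)
            bead_xyz[(h, b)] = pos
            coords.append(pos)
            names.append("CA")
            res_ids.append(resid)
            res_names.append(res_name)
            chains.append("A")

    def add_atom(name: str, resid_: int, res_name: str, pos: np.ndarray) -> None:
        coords.append(np.asarray(pos, dtype=float))
        names.append(name)
        res_ids.append(resid_)
        res_names.append(res_name)
        chains.append("A")

    def resid_of(hb: tuple[int, int]) -> int:
        return (hb[0] - 1) * beads_per + hb[1] + 1

    # --- side chains, inactive geometry -----------------------------------
    ca_r350 = bead_xyz[(3, 0)]
    ca_e630 = bead_xyz[(6, 0)]
    gap = ca_e630 - ca_r350
    e_hat = gap / np.linalg.norm(gap)
    n_hat = np.array([0.0, 0.0, 1.0])
    p_arg = ca_r350 + 2.0 * e_hat  # guanidinium tip toward TM6
    p_glu_in = p_arg + 3.0 * e_hat  # ionic lock closed: d_IL = 3 Å

    arg_id = resid_of((3, 0))
    glu_id = resid_of((6, 0))
    trp_id = resid_of((6, 2))
    add_atom("NH1", arg_id, "ARG", p_arg + 1.0 * n_hat)
    add_atom("NH2", arg_id, "ARG", p_arg - 1.0 * n_hat)
    add_atom("OE1", glu_id, "GLU", p_glu_in + 1.0 * n_hat)
    add_atom("OE2", glu_id, "GLU", p_glu_in - 1.0 * n_hat)

    # Trp 6.48 backbone N + side chain CB/CG with χ1 = N–CA–CB–CG
    ca_trp = bead_xyz[(6, 2)]
    helix_dir = np.array([0.0, 0.0, 1.0])
    inward = -bead_xyz[(6, 0)] / np.linalg.norm(bead_xyz[(6, 0)])
    n_pos = ca_trp - 1.46 * helix_dir
    cb_pos = ca_trp + 1.53 * (0.8 * inward + 0.6 * helix_dir)
    cg_in = _place_atom(n_pos, ca_trp, cb_pos, 1.52, 114.0, 163.0)
    add_atom("N", trp_id, "TRP", n_pos)
    add_atom("CB", trp_id, "TRP", cb_pos)
    add_atom("CG", trp_id, "TRP", cg_in)

    coords_in = np.array(coords)
    atom_names = np.array(names, dtype=object)
    res_ids_arr = np.array(res_ids)
    res_names_arr = np.array(res_names, dtype=object)
    chains_arr = np.array(chains, dtype=object)
    masses = np.array([_mass_for(nm) for nm in names])

    inactive = Conformation(coords_in, atom_names, res_ids_arr, res_names_arr,
                            chains_arr, masses)

    # --- active state: rigid outward swing of helix 6 ---------------------
    m241 = bead_xyz[(2, 0)]
    m635 = bead_xyz[(6, 1)]
    midpoint = 0.5 * (m241 + m635)
    out_hat = (m635 - midpoint) / np.linalg.norm(m635 - midpoint)
    tm6_shift = 5.9 * out_hat

    coords_ac = coords_in.copy()
    helix6_resids = {resid_of((6, b)) for b in range(beads_per)}
    moving = np.isin(res_ids_arr, list(helix6_resids))
    coords_ac[moving] += tm6_shift

    # accompanying rearrangements of the non-core helices (2, 3, 7 stay
    # fixed so descriptor constructions and the d_TM6 alignment are exact)
    for h, base, grad in ((1, 1.2, 0.3), (4, 1.2, 0.3), (5, 0.8, 0.8)):
        ang = 2.0 * np.pi * (h - 1) / n_helices
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
        for b in range(beads_per):
            i = resid_of((h, b)) - 1  # CA beads come first, one per residue
            coords_ac[i] += (base + grad * b) * radial + 0.4 * tangent

    # re-place the glutamate oxygens so the broken lock sits at exactly 12 Å
    p_glu_dir = (p_glu_in + tm6_shift) - p_arg
    p_glu_dir = p_glu_dir / np.linalg.norm(p_glu_dir)
    p_glu_ac = p_arg + 12.0 * p_glu_dir
    idx_oe1 = int(np.flatnonzero(atom_names == "OE1")[0])
    idx_oe2 = int(np.flatnonzero(atom_names == "OE2")[0])
    coords_ac[idx_oe1] = p_glu_ac + 1.0 * n_hat
    coords_ac[idx_oe2] = p_glu_ac - 1.0 * n_hat

    # rebuild the toggle-switch side chain at the active rotamer (χ1 = 55°)
    idx_n = int(np.flatnonzero(atom_names == "N")[0])
    idx_cb = int(np.flatnonzero(atom_names == "CB")[0])
    idx_cg = int(np.flatnonzero(atom_names == "CG")[0])
    ca_trp_idx = int(np.flatnonzero((res_ids_arr == trp_id) & (atom_names == "CA"))[0])
    coords_ac[idx_cg] = _place_atom(coords_ac[idx_n], coords_ac[ca_trp_idx],
                                    coords_ac[idx_cb], 1.52, 114.0, 55.0)

    active = Conformation(coords_ac, atom_names, res_ids_arr, res_names_arr,
                          chains_arr, masses)

    ca_mask = inactive.ca_indices()
    core_resids = [resid_of((h, b)) for h in (2, 3, 7) for b in range(beads_per)]
    align_mask = inactive.select(atom_names=["CA"], residue_ids=core_resids)
    return MiniReceptor(
        inactive=inactive,
        active=active,
        residue_map=ResidueMap(bw_entries),
        ca_mask=ca_mask,
        align_mask=align_mask,
        seed=seed,
    )


def interpolated_trajectory(
    mr: MiniReceptor,
    n_frames: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[Conformation]:
    """Frames linearly interpolating inactive → active with optional noise.

    Frame 0 is the noise-free inactive state, frame n−1 the noise-free
    active state; interior frames get i.i.d. Gaussian coordinate noise of
    standard deviation ``noise_sigma`` Å.
    """
    if n_frames < 2:
        raise InputError("need at least two frames")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        lam = i / (n_frames - 1)
        xyz = (1.0 - lam) * mr.inactive.coords + lam * mr.active.coords
        if noise_sigma > 0 and 0 < i < n_frames - 1:
            xyz = xyz + rng.normal(0.0, noise_sigma, size=xyz.shape)
        frames.append(mr.inactive.with_coords(xyz))
    return frames
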