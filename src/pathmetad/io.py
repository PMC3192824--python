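"""File formats and run configuration.

Formats handled:

* **PDB** (single- and multi-model) for conformations and reference paths,
  through biotite's PDB reader/writer.  When altloc records are present
  the first altloc is kept and a warning is logged.
* **XYZ** for toy-system trajectories (element/name, x, y, z; coordinates
  in Å), a trivial two-header-line text format written directly.
* **HILLS / COLVAR** whitespace-separated text dialects with a
  ``#! FIELDS ...`` header line, the lingua franca of metadynamics
  plug-ins.  Numeric round trips are bit-exact at ``%.9g``.
* **Run configuration**: a flat key-value YAML file validated against
  :class:`RunConfig`; unknown keys are rejected and every run can write
  the resolved configuration next to its outputs.

Every output file carries header comments recording the tool version, a
hash of the resolved configuration, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biasing import BiasState, WellTemperedConfig
from .errors import ConfigError, ParseError
from .geometry import Conformation

logger = logging.getLogger("pathmetad")

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "RunConfig",
    "header_lines",
]

_ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def header_lines(seed: int | None = None, config: dict | None = None) -> list[str]:
    """Standard provenance header: version, config hash, seed."""
    lines = [f"pathmetad v{__version__}"]
    if config is not None:
        digest = hashlib.sha1(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest()[:12]
        lines.append(f"config_hash={digest}")
    if seed is not None:
        lines.append(f"seed={seed}")
    return lines


# ---------------------------------------------------------------------------
# PDB


def _to_atom_array(c: Conformation):
    import biotite.structure as struc

    arr = struc.AtomArray(c.n_atoms)
    arr.coord = np.asarray(c.coords, dtype=np.float32)
    arr.atom_name = c.atom_names.astype(str)
    arr.res_id = c.residue_ids
    arr.res_name = c.residue_names.astype(str)
    arr.chain_id = c.chain_ids.astype(str)
    arr.element = np.array([_guess_element(n) for n in c.atom_names], dtype="U2")
    return arr


def _from_atom_array(arr) -> Conformation:
    masses = np.array([
        _ELEMENT_MASS.get(str(e).upper(), 12.011) for e in arr.element
    ])
    return Conformation(
        coords=np.asarray(arr.coord, dtype=float),
        atom_names=np.asarray(arr.atom_name, dtype=object),
        residue_ids=np.asarray(arr.res_id, dtype=int),
        residue_names=np.asarray(arr.res_name, dtype=object),
        chain_ids=np.asarray(arr.chain_id, dtype=object),
        masses=masses,
    )


def read_pdb(path: str | Path, model: int | None = None):
    """Read a PDB file into one Conformation (single model, or ``model``
    1-based) or a list of Conformations (multi-model file, ``model=None``).

    Only the first altloc of alternate-location records is kept.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if model is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                arr = pdb_file.get_structure(model=model, altloc="first")
            return _from_atom_array(arr)
        if n_models == 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                arr = pdb_file.get_structure(model=1, altloc="first")
            return _from_atom_array(arr)
        out = []
        for m in range(1, n_models + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                arr = pdb_file.get_structure(model=m, altloc="first")
            out.append(_from_atom_array(arr))
        return out
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various exceptions on bad input
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc


def write_pdb(conformations, path: str | Path) -> None:
    """Write one Conformation, or a list as a MODEL/ENDMDL multi-model file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(conformations, Conformation):
        obj = _to_atom_array(conformations)
    else:
        arrays = [_to_atom_array(c) for c in conformations]
        obj = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(obj)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# XYZ


def write_xyz(frames, path: str | Path, comments: Sequence[str] | None = None) -> None:
    """Write conformations (or raw (N,3) arrays) as a multi-frame XYZ file."""
    if isinstance(frames, Conformation):
        frames = [frames]
    with open(path, "w") as fh:
        for i, fr in enumerate(frames):
            if isinstance(fr, Conformation):
                coords = fr.coords
                names = [_guess_element(n) for n in fr.atom_names]
            else:
                coords = np.asarray(fr, dtype=float)
                names = ["C"] * coords.shape[0]
            comment = comments[i] if comments is not None else f"frame {i}"
            fh.write(f"{coords.shape[0]}\n{comment}\n")
            for nm, (x, y, z) in zip(names, coords):
                fh.write(f"{nm} {x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path: str | Path, template: Conformation | None = None):
    """Read a multi-frame XYZ file.

    Returns a list of (N, 3) arrays, or a list of Conformations when a
    ``template`` with matching atom count supplies the labels.
    """
    frames: list = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", line=i + 1)
        if i + 1 + n >= len(lines) + 1:
            raise ParseError("truncated XYZ frame", line=i + 1)
        block = lines[i + 2 : i + 2 + n]
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError("XYZ atom line needs 4 fields", line=i + 3 + j)
            coords[j] = [float(p) for p in parts[1:4]]
        if template is not None:
            frames.append(template.with_coords(coords))
        else:
            frames.append(coords)
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# HILLS / COLVAR dialects


def _read_fields_table(path: str | Path) -> tuple[list[str], pd.DataFrame, dict]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ParseError('missing "#! FIELDS" header line', line=1)
        fields = first.split()[2:]
        meta: dict[str, str] = {}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#! SET"):
                parts = line.split(maxsplit=3)
                if len(parts) >= 4:
                    meta[parts[2]] = parts[3]
                continue
            if line.startswith("#"):
                continue
            vals = line.split()
            if len(vals) != len(fields):
                raise ParseError(
                    f"{len(vals)} columns but header declares {len(fields)}",
                    line=lineno,
                )
            rows.append([float(v) for v in vals])
    data = pd.DataFrame(rows, columns=fields)
    return fields, data, meta


def _write_fields_table(
    path: str | Path,
    data: pd.DataFrame,
    meta: dict | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(str(c) for c in data.columns) + "\n")
        for key, value in (meta or {}).items():
            fh.write(f"#! SET {key} {value}\n")
        for line in extra_header:
            fh.write(f"# {line}\n")
        for row in data.itertuples(index=False):
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def write_hills(state: BiasState, path: str | Path, seed: int | None = None) -> None:
    """Write a BiasState's hills in the HILLS text dialect."""
    cfg = state.cfg
    names = list(cfg.cv_names)
    cols = (
        ["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"]
    )
    c = state.centers()
    w = state.widths()
    data = pd.DataFrame(
        np.column_stack([
            np.asarray(state.times),
            c,
            w,
            state.heights(),
            np.full(state.n_hills, cfg.bias_factor),
        ]) if state.n_hills else np.empty((0, len(cols))),
        columns=cols,
    )
    meta = {"temperature": f"{cfg.temperature:.9g}", "tau": f"{cfg.tau:.9g}",
            "w": f"{cfg.w:.9g}"}
    _write_fields_table(path, data, meta=meta, extra_header=header_lines(seed=seed))


def read_hills(path: str | Path, temperature: float | None = None) -> BiasState:
    """Reconstruct a BiasState from a HILLS file.

    The bias factor column fixes ΔT given the temperature (taken from the
    file's ``#! SET temperature`` line unless overridden).
    """
    fields, data, meta = _read_fields_table(path)
    if "time" not in fields or "height" not in fields:
        raise ParseError("HILLS file must have time and height columns")
    sigma_cols = [f for f in fields if f.startswith("sigma_")]
    cv_cols = [f for f in fields if f not in ("time", "height", "biasf") and not f.startswith("sigma_")]
    temp = temperature if temperature is not None else float(meta.get("temperature", 300.0))
    if len(data) and "biasf" in fields:
        bf = float(data["biasf"].iloc[0])
        delta_t = (bf - 1.0) * temp
    else:
        delta_t = 10.0 * temp
    if len(data) and sigma_cols:
        sigma = tuple(float(data[c].iloc[0]) for c in sigma_cols)
    else:
        sigma = tuple(1.0 for _ in cv_cols)
    w = float(meta.get("w", data["height"].max() if len(data) else 0.4))
    cfg = WellTemperedConfig(
        w=max(w, 1e-12), tau=float(meta.get("tau", 8.0)), temperature=temp,
        delta_t=delta_t, sigma=sigma, cv_names=tuple(cv_cols),
    )
    state = BiasState(cfg, use_grid=False)
    for row in data.itertuples(index=False):
        state.times.append(float(getattr(row, "time")))
        state._centers.append(np.array([getattr(row, c) for c in cv_cols]))
        state._widths.append(np.array([getattr(row, c) for c in sigma_cols]))
        state._heights.append(float(getattr(row, "height")))
    return state


def write_colvar(
    data: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a COLVAR table (time, CVs, bias, optional descriptor columns)."""
    _write_fields_table(path, data, extra_header=header_lines(seed=seed, config=config))


def read_colvar(path: str | Path) -> pd.DataFrame:
    _, data, _ = _read_fields_table(path)
    return data


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Biasing: w (kcal/mol), tau (ps), delta_T_over_T, temperature (K),
    sigma_s, sigma_z (Å²); path: gamma (Å⁻²); ABMD: k_ratchet
    (kcal/(mol·nm²)), n_abmd; clustering: k_cut, n_refs; dynamics: dt (ps),
    friction (1/ps), diffusion (Å²/ps), steps; seed.
    """

    w: float = 0.4
    tau: float = 8.0
    delta_T_over_T: float = 10.0
    temperature: float = 300.0
    sigma_s: float = 0.1
    sigma_z: float = 1.0
    gamma: float = 4.0
    k_ratchet: float = 10.0
    n_abmd: int = 10
    k_cut: int = 30
    n_refs: int = 10
    steps: int = 100000
    dt: float = 0.01
    friction: float = 1.0
    diffusion: float = 1.0
    integrator: str = "overdamped"
    colvar_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ["tau", "delta_T_over_T", "temperature", "sigma_s", "sigma_z",
                    "gamma", "dt", "friction", "diffusion"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.w < 0 or self.k_ratchet < 0:
            raise ConfigError("w and k_ratchet must be non-negative")
        if not self.k_cut >= self.n_refs >= 2:
            raise ConfigError("need k_cut >= n_refs >= 2")
        if self.integrator not in ("overdamped", "baoab"):
            raise ConfigError(f"unknown integrator {self.integrator!r}")

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def well_tempered(self) -> WellTemperedConfig:
        return WellTemperedConfig(
            w=self.w,
            tau=self.tau,
            temperature=self.temperature,
            delta_t=self.delta_T_over_T * self.temperature,
            sigma=(self.sigma_s, self.sigma_z),
            cv_names=("s", "z"),
        )
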