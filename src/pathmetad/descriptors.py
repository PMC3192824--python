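"""GPCR activation order parameters.

Three descriptors are computed from labelled conformations through a
Ballesteros–Weinstein (BW) residue map:

* ``d_IL`` — the ionic-lock distance: Euclidean distance between the centre
  of mass of the guanidinium η-nitrogens of R3.50 and the carboxylate
  oxygens of E6.30.  (The glutamate carboxylate oxygens carry PDB names
  OE1/OE2, formally ε-oxygens; the common "δ-oxygens" phrasing refers to the
  same terminal carboxylate pair, and the selection here is by name
  {OE1, OE2}.)
* ``chi_TS`` — the rotamer toggle switch: the first side-chain dihedral χ1
  (N–CA–CB–CG) of W6.48, in degrees.
* ``d_TM6`` / ``delta_d_TM6`` — the outward displacement of the intracellular
  end of TM6: after rigid alignment onto an inactive reference structure,
  the distance from the fixed midpoint M = ½[⟨R_2.41⟩ + ⟨R_6.35⟩] of the
  inactive structure to the centroid of residue 6.35, and its change
  relative to the inactive reference itself.

M is computed once from the inactive reference and never recomputed per
frame.  Which atoms define the alignment for d_TM6 is a package choice
(default: all Cα except a configurable excluded label set, here the moving
TM6 labels); it is exposed through ``align_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import geometry
from .errors import InputError, ParseError, SelectionError
from .geometry import Conformation

__all__ = [
    "ResidueMap",
    "DescriptorValues",
    "ionic_lock_distance",
    "toggle_switch_angle",
    "tm6_displacement",
    "compute_descriptors",
]


@dataclass(frozen=True)
class ResidueEntry:
    chain_id: str
    residue_id: int
    residue_name: str


class ResidueMap:
    """Maps Ballesteros–Weinstein labels like ``"3.50"`` to residues.

    BW notation identifies each transmembrane residue as ``H.NN`` where H is
    the helix number and NN the position relative to the helix's most
    conserved residue (NN = 50).
    """

    def __init__(self, entries: Mapping[str, ResidueEntry | tuple]):
        self._entries: dict[str, ResidueEntry] = {}
        for label, entry in entries.items():
            if not isinstance(entry, ResidueEntry):
                entry = ResidueEntry(str(entry[0]), int(entry[1]), str(entry[2]))
            if label in self._entries:
                raise InputError(f"duplicate BW label {label!r}")
            self._entries[str(label)] = entry

    def __getitem__(self, label: str) -> ResidueEntry:
        try:
            return self._entries[label]
        except KeyError:
            raise SelectionError(f"BW label {label!r} not present in residue map") from None

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def labels(self) -> list[str]:
        return list(self._entries)

    def atoms(
        self,
        c: Conformation,
        label: str,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms of the residue mapped to ``label``.

        Raises :class:`SelectionError` naming the label and the atom names
        sought when nothing matches.
        """
        entry = self[label]
        idx = c.select(
            atom_names=atom_names,
            residue_ids=[entry.residue_id],
            chain_ids=[entry.chain_id],
        )
        if idx.size == 0:
            wanted = "any atom" if atom_names is None else f"atoms {sorted(atom_names)}"
            raise SelectionError(
                f"BW label {label!r} (chain {entry.chain_id}, residue "
                f"{entry.residue_id} {entry.residue_name}): {wanted} not found"
            )
        return idx

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMap":
        """Read a 4-column TSV: bw_label, chain, resid, resname.

        Lines starting with ``#`` are comments; a header line whose first
        field is ``bw_label`` is skipped.
        """
        entries: dict[str, tuple] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if fields[0] == "bw_label":
                    continue
                if len(fields) != 4:
                    raise ParseError(
                        f"expected 4 columns (bw_label chain resid resname), got {len(fields)}",
                        line=lineno,
                    )
                label, chain, resid, resname = fields
                try:
                    entries[label] = (chain, int(resid), resname)
                except ValueError:
                    raise ParseError(f"residue id {resid!r} is not an integer", line=lineno)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bw_label\tchain\tresid\tresname\n")
            for label, e in self._entries.items():
                fh.write(f"{label}\t{e.chain_id}\t{e.residue_id}\t{e.residue_name}\n")


@dataclass(frozen=True)
class DescriptorValues:
    """The three activation descriptors for one frame."""

    d_il: float  # Å
    chi_ts: float  # degrees, (-180, 180]
    d_tm6: float  # Å
    delta_d_tm6: float  # Å

    def as_dict(self) -> dict[str, float]:
        return {
            "d_IL": self.d_il,
            "chi_TS": self.chi_ts,
            "d_TM6": self.d_tm6,
            "delta_d_TM6": self.delta_d_tm6,
        }


def ionic_lock_distance(c: Conformation, rmap: ResidueMap) -> float:
    """Ionic-lock distance d_IL in Å.

    Distance between the centre of mass of {NH1, NH2} of R3.50 and of
    {OE1, OE2} of E6.30.
    """
    arg_idx = rmap.atoms(c, "3.50", atom_names=["NH1", "NH2"])
    glu_idx = rmap.atoms(c, "6.30", atom_names=["OE1", "OE2"])
    p_arg = geometry.centroid(c, arg_idx, weighting="mass")
    p_glu = geometry.centroid(c, glu_idx, weighting="mass")
    return float(np.linalg.norm(p_arg - p_glu))


def toggle_switch_angle(c: Conformation, rmap: ResidueMap) -> float:
    """Toggle-switch dihedral χ_TS (the χ1 of W6.48) in degrees."""
    pts = []
    for name in ("N", "CA", "CB", "CG"):
        idx = rmap.atoms(c, "6.48", atom_names=[name])
        pts.append(c.coords[idx[0]])
    return geometry.dihedral(*pts)


def tm6_displacement(
    c: Conformation,
    inactive_ref: Conformation,
    rmap: ResidueMap,
    align_mask: Sequence[int] | np.ndarray | None = None,
) -> tuple[float, float]:
    """TM6 outward displacement (d_TM6, Δd_TM6) in Å.

    ``align_mask`` selects the atoms (by index, identical ordering in both
    structures) used for the rigid fit of ``c`` onto ``inactive_ref``;
    ``None`` uses all Cα atoms.  The midpoint M and the reference value
    d_TM6(inactive) are computed from ``inactive_ref`` only.
    """
    if align_mask is None:
        align_mask = inactive_ref.ca_indices()
    m241 = geometry.centroid(inactive_ref, rmap.atoms(inactive_ref, "2.41"))
    m635_ref = geometry.centroid(inactive_ref, rmap.atoms(inactive_ref, "6.35"))
    midpoint = 0.5 * (m241 + m635_ref)
    d_ref = float(np.linalg.norm(midpoint - m635_ref))

    fit = geometry.superpose(c, inactive_ref, align_mask)
    aligned = c.with_coords(c.coords @ fit.rotation.T + fit.translation)
    m635 = geometry.centroid(aligned, rmap.atoms(aligned, "6.35"))
    d_tm6 = float(np.linalg.norm(midpoint - m635))
    return d_tm6, d_tm6 - d_ref


def compute_descriptors(
    c: Conformation,
    inactive_ref: Conformation,
    rmap: ResidueMap,
    align_mask: Sequence[int] | np.ndarray | None = None,
) -> DescriptorValues:
    """All three descriptors for one frame."""
    d_tm6, delta = tm6_displacement(c, inactive_ref, rmap, align_mask)
    return DescriptorValues(
        d_il=ionic_lock_distance(c, rmap),
        chi_ts=toggle_switch_angle(c, rmap),
        d_tm6=d_tm6,
        delta_d_tm6=delta,
    )
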