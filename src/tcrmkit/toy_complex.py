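"""Synthetic antibody--pMHC complexes with known contact geometry.

Builds a parametric toy complex — an MHC-like platform with two helix rails
flanking a presented peptide, a beta-2-microglobulin-sized chain, and a
two-domain antibody — in which every interface contact is *planted* at a
chosen distance, so the ground-truth footprint (contact counts, P/M/PM
classes, contacted positions) is known by construction.  This is the
structural counterpart of the single-molecule simulator: it lets the whole
contact/footprint/geometry/design pipeline be tested without deposited
coordinates.

Geometry conventions of the toy (used by the geometry tests): the peptide
runs N->C along +x, the groove normal is +z, the antibody sits above the
groove at z > 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import AA3TO1, ATOM_COLUMNS, AnnotatedComplex, ChainRole, RawStructure

__all__ = ["PlantedContact", "ToyComplexSpec", "make_toy_complex",
           "transform_complex", "transform_chains"]

ONE_TO_THREE = {v: k for k, v in AA3TO1.items()}

HELIX_WINDOWS = ((50, 86), (138, 176))
TOY_CDRS = {
    "H": {"H1": (26, 35), "H2": (50, 65), "H3": (95, 102)},
    "L": {"L1": (24, 34), "L2": (50, 56), "L3": (89, 97)},
}


@dataclass(frozen=True)
class PlantedContact:
    """One planted antibody atom touching one target atom.

    ``target`` is ``("P", i)`` for peptide position Pi (1-based) or
    ``("M", resnum)`` for an MHC-helix residue.
    """

    ab_chain: str
    ab_residue: int
    target: tuple[str, int]
    distance: float = 3.6


@dataclass
class ToyComplexSpec:
    peptide_sequence: str = "SIINFEKL"
    contacts: list[PlantedContact] = field(default_factory=list)
    mhc_residue_names: dict[int, str] = field(default_factory=dict)
    ab_residue_names: dict[tuple[str, int], str] = field(default_factory=dict)
    name: str = "toy"


def _grid(n: int, center: np.ndarray, spacing: float = 3.8) -> np.ndarray:
    """n points on a compact cubic lattice, centered on `center` exactly."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = np.array([(i, j, k) for i in range(side)
                    for j in range(side) for k in range(side)][:n], float)
    pts *= spacing
    return pts - pts.mean(axis=0) + center


def make_toy_complex(spec: ToyComplexSpec | None = None
                     ) -> tuple[AnnotatedComplex, pd.DataFrame]:
    """Build the toy complex; returns (complex, planted-contact truth table)."""
    spec = spec or ToyComplexSpec()
    rows: list[tuple] = []

    def add(chain, resnum, resname, atom, element, pos):
        rows.append((chain, resnum, "", resname, atom, element,
                     float(pos[0]), float(pos[1]), float(pos[2]),
                     1.0, "", True, False))

    # --- MHC heavy chain "A": platform residues 1..180 + alpha3 blob 181..275
    helix_ca: dict[int, np.ndarray] = {}
    floor_res = [i for i in range(1, 181)
                 if not any(lo <= i <= hi for lo, hi in HELIX_WINDOWS)]
    floor_grid = _grid(len(floor_res), np.array([0.0, 0.0, -5.0]), spacing=3.0)
    # flatten the floor toward a slab under the groove
    floor_grid[:, 2] = -5.0 + 0.15 * (floor_grid[:, 2] + 5.0)
    for resnum, pos in zip(floor_res, floor_grid):
        name = spec.mhc_residue_names.get(resnum, "ALA")
        add("A", resnum, name, "CA", "C", pos)
    for (lo, hi), y in zip(HELIX_WINDOWS, (-6.5, 6.5)):
        mid = (lo + hi) / 2.0
        for resnum in range(lo, hi + 1):
            name = spec.mhc_residue_names.get(resnum, "ALA")
            pos = np.array([(resnum - mid) * 1.5, y, 0.0])
            helix_ca[resnum] = pos
            add("A", resnum, name, "CA", "C", pos)
    alpha3 = _grid(95, np.array([0.0, 0.0, -20.0]))
    for resnum, pos in zip(range(181, 276), alpha3):
        add("A", resnum, spec.mhc_residue_names.get(resnum, "ALA"), "CA", "C", pos)

    # --- beta-2 microglobulin "B": 99-residue blob well below the platform
    for resnum, pos in zip(range(1, 100), _grid(99, np.array([14.0, 0.0, -22.0]))):
        add("B", resnum, "ALA", "CA", "C", pos)

    # --- peptide "C": N->C along +x at z ~ 2, side-chain tips pointing up
    n_pep = len(spec.peptide_sequence)
    pep_tip: dict[int, np.ndarray] = {}
    for i, aa in enumerate(spec.peptide_sequence, start=1):
        resname = ONE_TO_THREE[aa]
        x = (i - (n_pep + 1) / 2.0) * 3.5
        add("C", i, resname, "N", "N", (x - 0.8, 0.3, 1.8))
        add("C", i, resname, "CA", "C", (x, 0.0, 2.0))
        add("C", i, resname, "C", "C", (x + 0.8, -0.3, 2.1))
        add("C", i, resname, "O", "O", (x + 1.0, -1.0, 1.6))
        if aa != "G":
            add("C", i, resname, "CB", "C", (x, 0.0, 3.3))
            tip = np.array([x, 0.0, 4.5])
            add("C", i, resname, "CG", "C", tip)
        else:
            tip = np.array([x, 0.0, 2.0])
        pep_tip[i] = tip

    # --- MHC side-chain atoms for planted M targets
    mhc_tip: dict[int, np.ndarray] = {}
    for pc in spec.contacts:
        kind, num = pc.target
        if kind == "M" and num not in mhc_tip:
            if num not in helix_ca:
                raise ValueError(f"M target {num} is not a helix residue")
            ca = helix_ca[num]
            tip = np.array([ca[0], ca[1] - np.sign(ca[1]) * 2.2, 2.8])
            mhc_tip[num] = tip
            name = spec.mhc_residue_names.get(num, "ALA")
            add("A", num, name, "CG", "C", tip)

    # --- antibody chains: 115-residue V-domain blobs above the groove,
    #     VL -> VH direction in the groove plane
    frameworks = {"H": np.array([7.0, -3.0, 19.0]), "L": np.array([-7.0, 3.0, 19.0])}
    motif = {"H": ("TRP", "GLY", "GLN", "GLY"), "L": ("PHE", "GLY", "GLY", "GLY")}
    for chain, center in frameworks.items():
        grid = _grid(115, center)
        for resnum, pos in zip(range(1, 116), grid):
            if 103 <= resnum <= 106:
                resname = motif[chain][resnum - 103]
            else:
                resname = spec.ab_residue_names.get((chain, resnum), "ALA")
            add(chain, resnum, resname, "CA", "C", pos)

    # --- planted interface atoms
    truth_rows = []
    per_residue_counter: dict[tuple[str, int], int] = {}
    for pc in spec.contacts:
        kind, num = pc.target
        if kind == "P":
            target_pos = pep_tip[num]
            target_atom = "CG" if spec.peptide_sequence[num - 1] != "G" else "CA"
        elif kind == "M":
            target_pos = mhc_tip[num]
            target_atom = "CG"
        else:
            raise ValueError(f"unknown target kind {kind!r}")
        k = per_residue_counter.get((pc.ab_chain, pc.ab_residue), 0)
        per_residue_counter[(pc.ab_chain, pc.ab_residue)] = k + 1
        alpha = np.radians(8.0 * ((k % 3) - 1))
        beta = np.radians(8.0 * ((k // 3) - 0.5))
        direction = np.array([np.sin(alpha), np.sin(beta),
                              np.sqrt(max(0.0, 1 - np.sin(alpha) ** 2
                                          - np.sin(beta) ** 2))])
        pos = target_pos + pc.distance * direction
        resname = spec.ab_residue_names.get((pc.ab_chain, pc.ab_residue), "ALA")
        add(pc.ab_chain, pc.ab_residue, resname, f"X{k + 1}", "C", pos)
        truth_rows.append((pc.ab_chain, pc.ab_residue, kind, num,
                           target_atom, pc.distance))

    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    roles = {"A": ChainRole.MHC_HEAVY, "B": ChainRole.B2M, "C": ChainRole.PEPTIDE,
             "H": ChainRole.AB_HEAVY, "L": ChainRole.AB_LIGHT}
    positions = [(f"P{i}", i, "", ONE_TO_THREE[aa])
                 for i, aa in enumerate(spec.peptide_sequence, start=1)]
    cx = AnnotatedComplex(atoms=atoms, role_map=roles, cdr_map=dict(TOY_CDRS),
                          peptide_positions=positions, name=spec.name,
                          provenance={"generator": "toy_complex"})
    truth = pd.DataFrame(truth_rows, columns=[
        "ab_chain", "ab_residue", "target_kind", "target_number",
        "target_atom", "distance"])
    return cx, truth


def _as_raw(cx: AnnotatedComplex | RawStructure) -> pd.DataFrame:
    return cx.atoms


def transform_complex(cx: AnnotatedComplex, rotation: Rotation,
                      translation=(0.0, 0.0, 0.0)) -> AnnotatedComplex:
    """Apply one rigid motion to every atom (for invariance tests)."""
    return transform_chains(cx, list(cx.role_map), rotation, translation)


def transform_chains(cx: AnnotatedComplex, chain_ids, rotation: Rotation,
                     translation=(0.0, 0.0, 0.0),
                     pivot=(0.0, 0.0, 0.0)) -> AnnotatedComplex:
    """Rigid motion of selected chains about ``pivot`` (e.g. rotate the antibody)."""
    atoms = cx.atoms.copy()
    mask = atoms["chain_id"].isin(chain_ids).to_numpy()
    xyz = atoms.loc[mask, ["x", "y", "z"]].to_numpy(float)
    pivot = np.asarray(pivot, float)
    xyz = rotation.apply(xyz - pivot) + pivot + np.asarray(translation, float)
    atoms.loc[mask, ["x", "y", "z"]] = xyz
    return AnnotatedComplex(
        atoms=atoms, role_map=dict(cx.role_map), cdr_map=dict(cx.cdr_map),
        peptide_positions=list(cx.peptide_positions), name=cx.name,
        provenance=dict(cx.provenance))
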