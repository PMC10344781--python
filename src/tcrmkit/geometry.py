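"""Docking geometry of an antibody over the MHC peptide groove.

A groove-fixed orthonormal frame is built from the class I alpha1/alpha2
helices (default author-numbering windows 50-86 and 138-176): the groove axis
is the first principal component of the helix C-alpha cloud, oriented from
the peptide N- to C-terminus; the normal is the smallest principal component,
oriented toward the antibody.  The antibody axis runs from the VL to the VH
C-alpha centroid.  The docking angle is measured between the groove axis and
the antibody axis projected into the groove plane.

The rotation between two complexes sharing an MHC scaffold is obtained by
Kabsch-superposing the query's groove C-alphas (residues 1-180) onto the
reference's and measuring the signed in-plane angle between the two antibody
axes.  Sign convention: positive = clockwise as seen by an observer on the
antibody side looking down the groove normal with the groove axis pointing
peptide N->C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import AnnotatedComplex, ChainRole

__all__ = [
    "GrooveFrame",
    "DockingResult",
    "groove_frame",
    "ab_axis",
    "docking_angle",
    "docking_rotation",
    "superpose",
]

HELIX_WINDOWS = ((50, 86), (138, 176))
PLATFORM_RANGE = (1, 180)
V_DOMAIN_LENGTH = 115


@dataclass
class GrooveFrame:
    origin: np.ndarray
    groove_axis: np.ndarray
    normal_axis: np.ndarray

    def __post_init__(self) -> None:
        g, n = self.groove_axis, self.normal_axis
        if abs(np.linalg.norm(g) - 1) > 1e-8 or abs(np.linalg.norm(n) - 1) > 1e-8:
            raise ValueError("frame axes must be unit vectors")
        if abs(np.dot(g, n)) > 1e-8:
            raise ValueError("frame axes must be orthogonal")

    @property
    def third_axis(self) -> np.ndarray:
        return np.cross(self.groove_axis, self.normal_axis)

    def project(self, v: np.ndarray) -> np.ndarray:
        """Project a vector into the groove plane (components along g, t)."""
        v = np.asarray(v, float)
        in_plane = v - np.dot(v, self.normal_axis) * self.normal_axis
        return in_plane


@dataclass
class DockingResult:
    docking_angle: float
    footprint_centroid: np.ndarray
    rotation_vs_reference: float | None = None


def _ca_table(cx: AnnotatedComplex, chain_id: str) -> pd.DataFrame:
    atoms = cx.atoms
    sel = atoms[(atoms["chain_id"] == chain_id) & (atoms["atom_name"] == "CA")
                & atoms["is_polymer"] & ~atoms["element"].isin(["H", "D"])]
    return sel.drop_duplicates(subset=["residue_number", "insertion_code"])


def _window_ca(cx: AnnotatedComplex, windows) -> pd.DataFrame:
    mhc = cx.chain(ChainRole.MHC_HEAVY)
    ca = _ca_table(cx, mhc)
    mask = np.zeros(len(ca), dtype=bool)
    for lo, hi in windows:
        mask |= ca["residue_number"].between(lo, hi).to_numpy()
    return ca[mask]


def _ab_centroid(cx: AnnotatedComplex) -> np.ndarray:
    chains = [cx.chain(ChainRole.AB_HEAVY), cx.chain(ChainRole.AB_LIGHT)]
    sel = cx.atoms[cx.atoms["chain_id"].isin(chains) & cx.atoms["is_polymer"]]
    return sel[["x", "y", "z"]].to_numpy(float).mean(axis=0)


def groove_frame(cx: AnnotatedComplex,
                 helix_windows=HELIX_WINDOWS) -> GrooveFrame:
    """Groove-fixed frame from the alpha1/alpha2 helix C-alphas."""
    helix = _window_ca(cx, helix_windows)
    n_expected = sum(hi - lo + 1 for lo, hi in helix_windows)
    if len(helix) < 0.8 * n_expected:
        raise ValueError(
            f"only {len(helix)}/{n_expected} helix C-alphas present (>20% missing)")
    xyz = helix[["x", "y", "z"]].to_numpy(float)
    center = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - center)
    groove = vt[0] / np.linalg.norm(vt[0])
    normal = vt[2] / np.linalg.norm(vt[2])

    # orient groove axis from peptide N- to C-terminus
    pep = _ca_table(cx, cx.chain(ChainRole.PEPTIDE))
    pep_xyz = pep[["x", "y", "z"]].to_numpy(float)
    if len(pep_xyz) >= 2 and np.dot(groove, pep_xyz[-1] - pep_xyz[0]) < 0:
        groove = -groove
    # orient normal toward the antibody
    if np.dot(normal, _ab_centroid(cx) - center) < 0:
        normal = -normal
    normal = normal - np.dot(normal, groove) * groove
    normal /= np.linalg.norm(normal)

    # origin: centroid of the groove-floor C-alphas (platform minus helices)
    mhc = cx.chain(ChainRole.MHC_HEAVY)
    ca = _ca_table(cx, mhc)
    lo, hi = PLATFORM_RANGE
    floor = ca[ca["residue_number"].between(lo, hi)]
    in_helix = np.zeros(len(floor), dtype=bool)
    for wlo, whi in helix_windows:
        in_helix |= floor["residue_number"].between(wlo, whi).to_numpy()
    floor = floor[~in_helix]
    origin = (floor if len(floor) else helix)[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    return GrooveFrame(origin=origin, groove_axis=groove, normal_axis=normal)


def ab_axis(cx: AnnotatedComplex,
            v_domain_length: int = V_DOMAIN_LENGTH) -> tuple[np.ndarray, np.ndarray]:
    """Axis through the VL and VH C-alpha centroids (direction VL -> VH)."""
    cents = {}
    for role in (ChainRole.AB_HEAVY, ChainRole.AB_LIGHT):
        chains = cx.chains_with_role(role)
        if not chains:
            raise ValueError(f"{role.value} chain missing")
        ca = _ca_table(cx, chains[0]).head(v_domain_length)
        if len(ca) < 0.5 * v_domain_length:
            raise ValueError(f"{role.value} V domain incomplete ({len(ca)} C-alphas)")
        cents[role] = ca[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    vl, vh = cents[ChainRole.AB_LIGHT], cents[ChainRole.AB_HEAVY]
    direction = vh - vl
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("VH and VL centroids coincide")
    return (vl + vh) / 2.0, direction / norm


def docking_angle(cx: AnnotatedComplex, frame: GrooveFrame | None = None) -> float:
    """Angle (deg, [0, 180)) between groove axis and in-plane antibody axis."""
    frame = frame or groove_frame(cx)
    _, direction = ab_axis(cx)
    in_plane = frame.project(direction)
    norm = np.linalg.norm(in_plane)
    if norm < 1e-8:
        raise ValueError("antibody axis is parallel to the groove normal; "
                         "in-plane projection is degenerate")
    in_plane /= norm
    ang = np.degrees(np.arctan2(np.dot(in_plane, frame.third_axis),
                                np.dot(in_plane, frame.groove_axis)))
    return float(ang % 180.0)


def superpose(ref_xyz: np.ndarray, query_xyz: np.ndarray
              ) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid fit (Kabsch) of query onto reference.

    Returns (rotation, translation, rmsd) such that
    ``rotation.apply(query) + translation ~= reference``.
    """
    ref_xyz = np.asarray(ref_xyz, float)
    query_xyz = np.asarray(query_xyz, float)
    if ref_xyz.shape != query_xyz.shape or len(ref_xyz) < 3:
        raise ValueError("superposition needs matched point sets of >= 3 points")
    ref_c = ref_xyz.mean(axis=0)
    q_c = query_xyz.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_xyz - ref_c, query_xyz - q_c)
    rmsd = float(rssd / np.sqrt(len(ref_xyz)))
    translation = ref_c - rot.apply(q_c)
    return rot, translation, rmsd


def _matched_platform_ca(ref: AnnotatedComplex, query: AnnotatedComplex
                         ) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = PLATFORM_RANGE
    out = []
    for cx in (ref, query):
        ca = _ca_table(cx, cx.chain(ChainRole.MHC_HEAVY))
        ca = ca[ca["residue_number"].between(lo, hi)]
        out.append({int(r.residue_number): np.array([r.x, r.y, r.z])
                    for r in ca.itertuples(index=False)})
    common = sorted(set(out[0]) & set(out[1]))
    if len(common) < 20:
        raise ValueError(f"only {len(common)} matched platform residues")
    return (np.array([out[0][i] for i in common]),
            np.array([out[1][i] for i in common]))


def docking_rotation(reference: AnnotatedComplex, query: AnnotatedComplex,
                     max_rmsd: float = 3.0) -> float:
    """Signed in-plane rotation (deg) of the query antibody vs the reference.

    Positive = clockwise, viewed from the antibody side down the groove
    normal with the groove axis pointing peptide N->C.
    """
    ref_xyz, query_xyz = _matched_platform_ca(reference, query)
    rot, _, rmsd = superpose(ref_xyz, query_xyz)
    if rmsd > max_rmsd:
        raise ValueError(f"groove superposition RMSD {rmsd:.2f} A > {max_rmsd} A; "
                         "frames not comparable")
    frame = groove_frame(reference)
    _, u_ref = ab_axis(reference)
    _, u_query_local = ab_axis(query)
    u_query = rot.apply(u_query_local)

    p_ref = frame.project(u_ref)
    p_query = frame.project(u_query)
    for v in (p_ref, p_query):
        if np.linalg.norm(v) < 1e-8:
            raise ValueError("antibody axis parallel to groove normal")
    p_ref /= np.linalg.norm(p_ref)
    p_query /= np.linalg.norm(p_query)
    ccw = np.degrees(np.arctan2(np.dot(np.cross(p_ref, p_query), frame.normal_axis),
                                np.dot(p_ref, p_query)))
    return float(-ccw)
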