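"""Antibody--pMHC interface footprints.

A "contact" is an antibody-atom / target-atom pair within a Euclidean cutoff
(inclusive, default 4.0 A, hydrogens excluded).  Residue-level statements
("contacts seven MHC amino acids") are distinct-residue projections of the
atom-pair set.  Antibody residues are classified P (peptide only), M (MHC
only) or PM (both) from their atom-pair counts — the classification used in
TCR-mimic library design, where P/PM positions are randomized and M positions
preserved.

Buried surface area is decomposed into the peptide- and MHC-derived portions
with a deterministic Shrake–Rupley sphere-sampling SASA (fixed Fibonacci
point set, probe 1.4 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import AnnotatedComplex, ChainRole

__all__ = [
    "ContactPair",
    "FootprintTable",
    "InterfaceSummary",
    "find_contacts",
    "classify_ab_residues",
    "mhc_residue_share",
    "polar_contacts",
    "shrake_rupley_sasa",
    "buried_surface",
    "footprint_report",
    "VDW_RADII",
]

#: Peptide backbone atoms excluded under the side-chain-only criterion
#: (glycine CA counts as side chain).
BACKBONE_ATOMS = {"N", "CA", "C", "O"}

AB_ROLES = (ChainRole.AB_HEAVY, ChainRole.AB_LIGHT)
TARGET_ROLES = (ChainRole.PEPTIDE, ChainRole.MHC_HEAVY)

CONTACT_COLUMNS = [
    "ab_chain", "ab_residue_number", "ab_insertion_code", "ab_residue_name",
    "ab_atom", "ab_role", "target_role", "target_chain", "target_residue_number",
    "target_insertion_code", "target_residue_name", "target_atom",
    "distance", "polar_class", "complex_name",
]


@dataclass(frozen=True)
class ContactPair:
    ab_atom: tuple[str, int, str]
    target_atom: tuple[str, int, str]
    target_role: ChainRole
    distance: float
    polar_class: str = "vdw"


@dataclass
class FootprintTable:
    """Per-antibody-residue contact record (one row per contacting residue)."""

    table: pd.DataFrame
    cutoff: float
    complex_name: str = ""

    def residues_with_peptide_contacts(self) -> pd.DataFrame:
        return self.table[self.table["n_contacts_peptide"] > 0]

    def residues_with_mhc_contacts(self) -> pd.DataFrame:
        return self.table[self.table["n_contacts_mhc"] > 0]


@dataclass
class InterfaceSummary:
    bsa_peptide: float
    bsa_mhc: float
    per_cdr: pd.DataFrame
    contacted_mhc_residues: pd.DataFrame
    cutoff: float
    extras: dict = field(default_factory=dict)


def _role_of(cx: AnnotatedComplex, chain_id: str) -> ChainRole:
    return cx.role_map[chain_id]


def _atom_subset(cx: AnnotatedComplex, roles, include_hydrogens: bool) -> pd.DataFrame:
    chains = [c for c, r in cx.role_map.items() if r in roles]
    sel = cx.atoms[cx.atoms["chain_id"].isin(chains) & cx.atoms["is_polymer"]]
    if not include_hydrogens:
        sel = sel[~sel["element"].isin(["H", "D"])]
    return sel


def find_contacts(cx: AnnotatedComplex, cutoff: float = 4.0,
                  side_chain_only: bool = False, restrict_to_cdrs: bool = False,
                  include_hydrogens: bool = False) -> pd.DataFrame:
    """All antibody-atom / target-atom pairs within ``cutoff`` (inclusive).

    ``side_chain_only`` drops backbone atoms (N, CA, C, O; glycine CA kept)
    on the *target peptide* only — the criterion used for the human library
    design ("within 4 A of the peptide side chains"); antibody and MHC atoms
    are always all-atom.  ``restrict_to_cdrs`` keeps only antibody atoms
    inside annotated CDR intervals.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    for role in AB_ROLES + TARGET_ROLES:
        if role not in cx.role_map.values():
            raise ValueError(f"complex is missing a {role.value} chain")

    ab = _atom_subset(cx, AB_ROLES, include_hydrogens)
    if restrict_to_cdrs:
        if not cx.cdr_map:
            raise ValueError("restrict_to_cdrs requires CDR annotation")
        keep = np.zeros(len(ab), dtype=bool)
        for i, row in enumerate(ab.itertuples(index=False)):
            keep[i] = cx.cdr_of(row.chain_id, int(row.residue_number)) is not None
        ab = ab[keep]

    target = _atom_subset(cx, TARGET_ROLES, include_hydrogens)
    if side_chain_only:
        pep_chain = cx.chain(ChainRole.PEPTIDE)
        is_pep = target["chain_id"] == pep_chain
        backbone = target["atom_name"].isin(BACKBONE_ATOMS) & ~(
            (target["residue_name"] == "GLY") & (target["atom_name"] == "CA"))
        target = target[~(is_pep & backbone)]

    ab_xyz = ab[["x", "y", "z"]].to_numpy(float)
    t_xyz = target[["x", "y", "z"]].to_numpy(float)
    rows: list[tuple] = []
    if len(ab_xyz) and len(t_xyz):
        tree = cKDTree(t_xyz)
        ab_rows = list(ab.itertuples(index=False))
        t_rows = list(target.itertuples(index=False))
        for i, hits in enumerate(tree.query_ball_point(ab_xyz, r=cutoff)):
            a = ab_rows[i]
            for j in sorted(hits):
                t = t_rows[j]
                d = float(np.linalg.norm(ab_xyz[i] - t_xyz[j]))
                rows.append((
                    a.chain_id, int(a.residue_number), a.insertion_code,
                    a.residue_name, a.atom_name, _role_of(cx, a.chain_id).value,
                    _role_of(cx, t.chain_id).value, t.chain_id,
                    int(t.residue_number), t.insertion_code, t.residue_name,
                    t.atom_name, d, "vdw", cx.name,
                ))
    contacts = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return contacts.sort_values(
        ["ab_chain", "ab_residue_number", "ab_insertion_code", "ab_atom",
         "target_chain", "target_residue_number", "target_atom"],
        kind="mergesort").reset_index(drop=True)


def contact_pairs(contacts: pd.DataFrame) -> list[ContactPair]:
    return [
        ContactPair(
            (r.ab_chain, r.ab_residue_number, r.ab_atom),
            (r.target_chain, r.target_residue_number, r.target_atom),
            ChainRole(r.target_role), r.distance, r.polar_class)
        for r in contacts.itertuples(index=False)
    ]


def classify_ab_residues(contacts: pd.DataFrame,
                         cx: AnnotatedComplex | None = None,
                         cutoff: float = 4.0) -> FootprintTable:
    """Partition contacting antibody residues into P / M / PM classes."""
    names = set(contacts["complex_name"]) if len(contacts) else set()
    if len(names) > 1:
        raise ValueError(f"contacts mix complexes: {sorted(names)}")
    rows = []
    key = ["ab_chain", "ab_residue_number", "ab_insertion_code", "ab_residue_name"]
    for (chain, resnum, icode, resname), grp in contacts.groupby(key, sort=False):
        n_pep = int((grp["target_role"] == ChainRole.PEPTIDE.value).sum())
        n_mhc = int((grp["target_role"] == ChainRole.MHC_HEAVY.value).sum())
        if n_pep and n_mhc:
            cls = "PM"
        elif n_pep:
            cls = "P"
        else:
            cls = "M"
        pep_positions: list[str] = []
        if cx is not None and n_pep:
            pep = grp[grp["target_role"] == ChainRole.PEPTIDE.value]
            seen = pep.drop_duplicates(
                subset=["target_residue_number", "target_insertion_code"])
            pep_positions = sorted(
                {cx.peptide_position_label(int(r.target_residue_number),
                                           r.target_insertion_code)
                 for r in seen.itertuples(index=False)},
                key=lambda s: int(s[1:]))
        cdr = cx.cdr_of(chain, int(resnum)) if cx is not None else None
        rows.append((chain, int(resnum), icode, resname, cdr or "FR",
                     n_pep, n_mhc, ",".join(pep_positions), cls))
    table = pd.DataFrame(rows, columns=[
        "chain", "residue_number", "insertion_code", "residue_name", "cdr",
        "n_contacts_peptide", "n_contacts_mhc", "peptide_positions", "class"])
    table = table.sort_values(["chain", "residue_number", "insertion_code"],
                              kind="mergesort").reset_index(drop=True)
    return FootprintTable(table=table, cutoff=cutoff,
                          complex_name=next(iter(names), ""))


def mhc_residue_share(contacts: pd.DataFrame, residue_subset) -> float:
    """Fraction of antibody--MHC atom contacts contributed by a residue subset.

    ``residue_subset`` items are either author residue numbers (ints) or
    strings like ``"R65"`` (one-letter residue type + author number, the
    type is verified against the structure).
    """
    mhc = contacts[contacts["target_role"] == ChainRole.MHC_HEAVY.value]
    total = len(mhc)
    if total == 0:
        raise ValueError("no antibody-MHC contacts present (cannot form a share)")
    from .structure import AA3TO1
    one_to_three = {v: k for k, v in AA3TO1.items()}
    numbers: set[int] = set()
    for item in residue_subset:
        if isinstance(item, str):
            aa, num = item[0].upper(), int(item[1:])
            expected = one_to_three[aa]
            found = mhc[mhc["target_residue_number"] == num]["target_residue_name"]
            if len(found) and not (found == expected).all():
                raise ValueError(
                    f"residue {num} is {found.iloc[0]}, not {expected} ({item})")
            numbers.add(num)
        else:
            numbers.add(int(item))
    present = set(mhc["target_residue_number"].astype(int))
    missing = numbers - present
    # subset residues must exist in the MHC chain's contacted set or at least
    # in the chain; absent-from-contacts is fine (contributes 0)
    in_subset = mhc["target_residue_number"].astype(int).isin(numbers)
    del missing
    return float(in_subset.sum()) / float(total)


# ---------------------------------------------------------------------------
# polar contacts
# ---------------------------------------------------------------------------

_SALT_BASIC = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
               ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_SALT_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def polar_contacts(contacts: pd.DataFrame, donor_acceptor_cutoff: float = 3.5,
                   saltbridge_cutoff: float = 4.0) -> pd.DataFrame:
    """Relabel contact pairs as hydrogen bonds or salt bridges.

    hbond: both atoms N or O within ``donor_acceptor_cutoff``.  saltbridge:
    opposite-charge side-chain N/O groups (Arg/Lys/His vs Asp/Glu) within
    ``saltbridge_cutoff``; the salt-bridge label overrides hbond, both
    override vdw.
    """
    out = contacts.copy()
    ab_el = out["ab_atom"].str[:1]
    t_el = out["target_atom"].str[:1]
    both_polar = ab_el.isin(["N", "O"]) & t_el.isin(["N", "O"])
    hbond = both_polar & (out["distance"] <= donor_acceptor_cutoff)

    ab_key = list(zip(out["ab_residue_name"], out["ab_atom"]))
    t_key = list(zip(out["target_residue_name"], out["target_atom"]))
    ab_basic = np.array([k in _SALT_BASIC for k in ab_key])
    ab_acidic = np.array([k in _SALT_ACIDIC for k in ab_key])
    t_basic = np.array([k in _SALT_BASIC for k in t_key])
    t_acidic = np.array([k in _SALT_ACIDIC for k in t_key])
    salt = ((ab_basic & t_acidic) | (ab_acidic & t_basic)) & \
        (out["distance"].to_numpy() <= saltbridge_cutoff)

    out.loc[hbond, "polar_class"] = "hbond"
    out.loc[salt, "polar_class"] = "saltbridge"
    return out


# ---------------------------------------------------------------------------
# SASA / buried surface
# ---------------------------------------------------------------------------

#: van der Waals radii (A), versioned with the package.  Bondi-style values.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "D": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(atoms: pd.DataFrame, n_points: int = 960,
                       probe_radius: float = PROBE_RADIUS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), sphere sampling.

    The sample point set is fixed (Fibonacci lattice), so results are
    run-to-run identical.
    """
    xyz = atoms[["x", "y", "z"]].to_numpy(float)
    radii = np.array([VDW_RADII.get(e, _DEFAULT_RADIUS) for e in atoms["element"]])
    radii = radii + probe_radius
    n_atoms = len(xyz)
    sphere = _fibonacci_sphere(n_points)
    areas = np.zeros(n_atoms)
    if n_atoms == 0:
        return areas
    tree = cKDTree(xyz)
    max_r = radii.max()
    for i in range(n_atoms):
        pts = xyz[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(xyz[i], r=radii[i] + max_r)
                 if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    return areas


def buried_surface(cx: AnnotatedComplex, n_points: int = 960) -> dict[str, float]:
    """pMHC surface buried by the antibody, split into peptide and MHC parts.

    BSA(x) = SASA(pMHC alone) - SASA(pMHC in complex), summed over the atoms
    of x in {peptide, MHC heavy chain}.  beta-2 microglobulin atoms occlude
    in both states but are not reported.
    """
    pmhc_roles = (ChainRole.PEPTIDE, ChainRole.MHC_HEAVY, ChainRole.B2M)
    pmhc = _atom_subset(cx, pmhc_roles, include_hydrogens=False).reset_index(drop=True)
    both = _atom_subset(cx, pmhc_roles + AB_ROLES,
                        include_hydrogens=False).reset_index(drop=True)
    sasa_alone = shrake_rupley_sasa(pmhc, n_points=n_points)
    sasa_complex_all = shrake_rupley_sasa(both, n_points=n_points)
    # pMHC atoms come first in `both` only if chain order cooperates; match on keys
    key_cols = ["chain_id", "residue_number", "insertion_code", "atom_name"]
    both_keys = {tuple(t): i for i, t in
                 enumerate(both[key_cols].itertuples(index=False, name=None))}
    idx = np.array([both_keys[tuple(t)] for t in
                    pmhc[key_cols].itertuples(index=False, name=None)])
    delta = sasa_alone - sasa_complex_all[idx]
    pep_chain = cx.chain(ChainRole.PEPTIDE)
    mhc_chain = cx.chain(ChainRole.MHC_HEAVY)
    bsa_peptide = float(delta[(pmhc["chain_id"] == pep_chain).to_numpy()].sum())
    bsa_mhc = float(delta[(pmhc["chain_id"] == mhc_chain).to_numpy()].sum())
    return {"bsa_peptide": max(bsa_peptide, 0.0) if bsa_peptide > -1e-6 else bsa_peptide,
            "bsa_mhc": max(bsa_mhc, 0.0) if bsa_mhc > -1e-6 else bsa_mhc}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _per_cdr_counts(cx: AnnotatedComplex, contacts: pd.DataFrame,
                    target_role: ChainRole) -> pd.DataFrame:
    sub = contacts[contacts["target_role"] == target_role.value]
    cdr_names = ["H1", "H2", "H3", "L1", "L2", "L3", "FR"]
    counts = dict.fromkeys(cdr_names, 0)
    for r in sub.itertuples(index=False):
        cdr = cx.cdr_of(r.ab_chain, int(r.ab_residue_number)) or "FR"
        counts[cdr] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "cdr": cdr_names,
        "n_contacts": [counts[c] for c in cdr_names],
        "fraction": [counts[c] / total if total else 0.0 for c in cdr_names],
    })


def footprint_report(cx: AnnotatedComplex, cutoff: float = 4.0,
                     side_chain_only: bool = False, restrict_to_cdrs: bool = False,
                     include_bsa: bool = False) -> dict:
    """Full footprint analysis: per-residue table, per-CDR shares, summary.

    Returns a machine-readable record; ``render_footprint_report`` formats it.
    """
    contacts = find_contacts(cx, cutoff=cutoff, side_chain_only=side_chain_only,
                             restrict_to_cdrs=restrict_to_cdrs)
    contacts = polar_contacts(contacts)
    fp = classify_ab_residues(contacts, cx, cutoff=cutoff)
    mhc = contacts[contacts["target_role"] == ChainRole.MHC_HEAVY.value]
    pep = contacts[contacts["target_role"] == ChainRole.PEPTIDE.value]
    mhc_res = (mhc.groupby(["target_residue_number", "target_residue_name"])
               .size().reset_index(name="n_contacts")
               .sort_values("target_residue_number").reset_index(drop=True))
    report = {
        "complex": cx.name,
        "cutoff": cutoff,
        "side_chain_only": side_chain_only,
        "restrict_to_cdrs": restrict_to_cdrs,
        "footprint": fp,
        "contacts": contacts,
        "n_peptide_atom_contacts": int(len(pep)),
        "n_mhc_atom_contacts": int(len(mhc)),
        "n_distinct_mhc_residues": int(len(mhc_res)),
        "contacted_mhc_residues": mhc_res,
        "per_cdr_peptide": _per_cdr_counts(cx, contacts, ChainRole.PEPTIDE),
        "per_cdr_mhc": _per_cdr_counts(cx, contacts, ChainRole.MHC_HEAVY),
    }
    if include_bsa:
        report.update(buried_surface(cx))
    return report


def render_footprint_report(report: dict) -> str:
    """Deterministic plain-text rendering of a footprint report."""
    lines = [
        f"Footprint report: {report['complex']}",
        f"cutoff = {report['cutoff']:.2f} A, side_chain_only = "
        f"{report['side_chain_only']}, restrict_to_cdrs = {report['restrict_to_cdrs']}",
        "",
        "residue  cdr  class  n_pep  n_mhc  peptide_positions",
    ]
    for _, r in report["footprint"].table.iterrows():
        lines.append(
            f"{r['chain']}{r['residue_number']}{r['insertion_code']:<2s} "
            f"{r['cdr']:<4s} {r['class']:<5s} {r['n_contacts_peptide']:5d} "
            f"{r['n_contacts_mhc']:5d}  {r['peptide_positions']}")
    lines += [
        "",
        f"peptide-directed atom contacts: {report['n_peptide_atom_contacts']}",
        f"MHC-directed atom contacts:     {report['n_mhc_atom_contacts']}",
        f"distinct contacted MHC residues: {report['n_distinct_mhc_residues']}",
        "",
        "per-CDR shares (MHC-directed):",
    ]
    for r in report["per_cdr_mhc"].itertuples(index=False):
        lines.append(f"  {r.cdr:<3s} {r.n_contacts:4d}  {r.fraction:6.3f}")
    if "bsa_peptide" in report:
        lines += ["", f"BSA peptide: {report['bsa_peptide']:.1f} A^2",
                  f"BSA MHC:     {report['bsa_mhc']:.1f} A^2"]
    return "\n".join(lines) + "\n"
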