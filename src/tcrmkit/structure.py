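"""Parsing and annotation of antibody--pMHC complex structures.

This module turns a deposited PDB/mmCIF file (or a synthetic complex) into an
:class:`AnnotatedComplex`: a flat atom table plus a map of biological chain
roles (MHC heavy chain, beta-2 microglobulin, presented peptide, antibody
heavy/light chain) and CDR loop intervals, so that downstream stages can speak
in coordinates such as "light-chain CDR1 residue 32" or "peptide position P5".

All residue numbering is author numbering as deposited; nothing is renumbered.
Alternate locations are resolved on load to the highest-occupancy conformer
(ties broken alphabetically by alt-loc id).  Hydrogens are retained in the
atom table but excluded from distance work downstream.
"""

from __future__ import annotations

import enum
import re
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ChainRole",
    "RawStructure",
    "AnnotatedComplex",
    "load_structure",
    "write_pdb",
    "assign_roles",
    "annotate_cdrs",
    "fetch_structure",
    "chain_sequences",
    "CDR_SCHEMES",
]

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Atom-table column order shared by the whole package.
ATOM_COLUMNS = [
    "chain_id", "residue_number", "insertion_code", "residue_name",
    "atom_name", "element", "x", "y", "z", "occupancy", "alt_loc",
    "is_polymer", "is_water",
]


class ChainRole(enum.Enum):
    MHC_HEAVY = "MHC_HEAVY"
    B2M = "B2M"
    PEPTIDE = "PEPTIDE"
    AB_HEAVY = "AB_HEAVY"
    AB_LIGHT = "AB_LIGHT"
    OTHER = "OTHER"


@dataclass(frozen=True)
class AtomRecord:
    """A single atom in author numbering."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite or malformed position for atom {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class RawStructure:
    """A parsed coordinate file: atom table plus provenance, before role assignment."""

    atoms: pd.DataFrame
    name: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain_id"]))

    def atom_records(self) -> Iterable[AtomRecord]:
        for row in self.atoms.itertuples(index=False):
            yield AtomRecord(
                row.chain_id, int(row.residue_number), row.insertion_code,
                row.residue_name, row.atom_name, row.element,
                np.array([row.x, row.y, row.z]), float(row.occupancy), row.alt_loc,
            )


@dataclass
class AnnotatedComplex:
    """Atom table + chain roles + CDR intervals + peptide position labels."""

    atoms: pd.DataFrame
    role_map: dict[str, ChainRole]
    cdr_map: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    peptide_positions: list[tuple[str, int, str, str]] = field(default_factory=list)
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = list(self.role_map.values())
        if roles.count(ChainRole.PEPTIDE) != 1:
            raise ValueError("an AnnotatedComplex requires exactly one PEPTIDE chain")
        if roles.count(ChainRole.MHC_HEAVY) != 1:
            raise ValueError("an AnnotatedComplex requires exactly one MHC_HEAVY chain")
        unknown = set(self.atoms["chain_id"]) - set(self.role_map)
        if unknown:
            raise ValueError(f"atoms belong to chains without a role: {sorted(unknown)}")
        for chain, ranges in self.cdr_map.items():
            ivals = sorted(ranges.values())
            for (a_lo, a_hi), (b_lo, b_hi) in zip(ivals, ivals[1:]):
                if b_lo <= a_hi:
                    raise ValueError(f"overlapping CDR ranges on chain {chain}")

    def chains_with_role(self, role: ChainRole) -> list[str]:
        return [c for c, r in self.role_map.items() if r is role]

    def chain(self, role: ChainRole) -> str:
        chains = self.chains_with_role(role)
        if len(chains) != 1:
            raise ValueError(f"expected exactly one {role.value} chain, found {chains}")
        return chains[0]

    @property
    def peptide_sequence(self) -> str:
        return "".join(AA3TO1.get(name, "X") for _, _, _, name in self.peptide_positions)

    def peptide_position_label(self, residue_number: int, insertion_code: str = "") -> str:
        for label, num, icode, _ in self.peptide_positions:
            if num == residue_number and icode == insertion_code:
                return label
        raise KeyError(f"peptide residue {residue_number}{insertion_code} not found")

    def cdr_of(self, chain_id: str, residue_number: int) -> str | None:
        """CDR name ('H1'..'L3') containing this residue, or None for framework."""
        for name, (lo, hi) in self.cdr_map.get(chain_id, {}).items():
            if lo <= residue_number <= hi:
                return name
        return None


# ---------------------------------------------------------------------------
# loading / serialization
# ---------------------------------------------------------------------------

_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
            "auto": gemmi.CoorFormat.Detect}


def load_structure(path: str | Path, format: str = "auto") -> RawStructure:
    """Read a PDB or mmCIF file into a flat atom table.

    All ATOM/HETATM records are retained with author numbering and insertion
    codes.  Alternate locations are resolved to the highest-occupancy
    conformer (alphabetical alt-loc id on ties).  Waters and other
    non-polymer heteroatoms are kept and flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use pdb/mmcif/auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise ValueError(f"{path}: structure contains no model/atoms")
    model = st[0]

    rows: list[tuple] = []
    for chain in model:
        for res in chain:
            is_water = res.is_water()
            is_polymer = res.name in AA3TO1
            for atom in res:
                rows.append((
                    chain.name, res.seqid.num, res.seqid.icode.replace("\x00", "").strip(),
                    res.name, atom.name, atom.element.name.upper(),
                    atom.pos.x, atom.pos.y, atom.pos.z,
                    float(atom.occ), atom.altloc.replace("\x00", "").strip(),
                    is_polymer, is_water,
                ))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    if atoms.empty:
        raise ValueError(f"{path}: empty model")
    atoms = _resolve_alt_locs(atoms)
    return RawStructure(atoms=atoms, name=path.stem,
                        provenance={"path": str(path), "format": format})


def _resolve_alt_locs(atoms: pd.DataFrame) -> pd.DataFrame:
    """Keep one conformer per atom: highest occupancy, alphabetical alt-loc on ties."""
    if (atoms["alt_loc"] == "").all():
        return atoms.reset_index(drop=True)
    key = ["chain_id", "residue_number", "insertion_code", "residue_name", "atom_name"]
    atoms = atoms.sort_values(key + ["occupancy", "alt_loc"],
                              ascending=[True] * len(key) + [False, True],
                              kind="mergesort")
    atoms = atoms.drop_duplicates(subset=key, keep="first")
    return atoms.sort_index(kind="mergesort").reset_index(drop=True)


def write_pdb(obj: RawStructure | AnnotatedComplex | pd.DataFrame, path: str | Path) -> None:
    """Serialize an atom table back to minimal PDB (author numbering preserved)."""
    atoms = obj if isinstance(obj, pd.DataFrame) else obj.atoms
    with open(path, "w") as fh:
        for i, row in enumerate(atoms.itertuples(index=False), start=1):
            record = "HETATM" if (row.is_water or not row.is_polymer) else "ATOM  "
            name = row.atom_name if len(row.atom_name) == 4 else f" {row.atom_name:<3s}"
            fh.write(
                f"{record}{i % 100000:5d} {name:<4s}{row.alt_loc or ' ':1s}"
                f"{row.residue_name:>3s} {row.chain_id[:1]:1s}"
                f"{row.residue_number:4d}{row.insertion_code or ' ':1s}   "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{row.occupancy:6.2f}"
                f"{0.0:6.2f}          {row.element:>2s}\n"
            )
        fh.write("END\n")


def fetch_structure(accession: str, cache_dir: str | Path = "data/structures",
                    format: str = "mmcif") -> Path:
    """Download a deposited entry by accession into a local cache (network helper).

    All network use in the package is isolated to this function; every other
    code path works from local files.
    """
    accession = accession.lower()
    if not re.fullmatch(r"[0-9][a-z0-9]{3}", accession):
        raise ValueError(f"malformed accession {accession!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    ext = "cif" if format == "mmcif" else "pdb"
    dest = cache_dir / f"{accession}.{ext}"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{accession.upper()}.{ext}"
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# role assignment
# ---------------------------------------------------------------------------

def chain_sequences(atoms: pd.DataFrame) -> dict[str, str]:
    """One-letter sequence of standard amino acids per chain, in file order."""
    seqs: dict[str, str] = {}
    poly = atoms[atoms["is_polymer"]]
    for chain_id, group in poly.groupby("chain_id", sort=False):
        residues = group.drop_duplicates(
            subset=["residue_number", "insertion_code"])["residue_name"]
        seqs[chain_id] = "".join(AA3TO1[name] for name in residues)
    return seqs


# FR4 J-segment motifs: heavy chains carry W-G-x-G, light chains F-G-x-G.
_HEAVY_MOTIF = re.compile(r"WG.G")
_LIGHT_MOTIF = re.compile(r"FG.G")


def assign_roles(structure: RawStructure | AnnotatedComplex,
                 hints: Mapping[str, ChainRole] | None = None) -> AnnotatedComplex:
    """Assign biological roles to chains by length/content heuristics.

    PEPTIDE = the polymer chain of length 8--12; B2M ~ 95--105 residues;
    MHC heavy-chain ectodomain ~ 270--290 residues; the remaining two
    V-domain-bearing chains are split into heavy/light by their FR4
    J-segment motif (``WGxG`` heavy vs ``FGxG`` light).  ``hints`` override
    the heuristics verbatim and are required whenever they are ambiguous.
    """
    atoms = structure.atoms
    hints = dict(hints or {})
    seqs = chain_sequences(atoms)
    if len(seqs) < 4 and not hints:
        raise ValueError(
            f"only {len(seqs)} polymer chains present; supply role hints")

    roles: dict[str, ChainRole] = {}
    for chain_id, role in hints.items():
        roles[chain_id] = role

    unassigned = [c for c in seqs if c not in roles]
    lengths = {c: len(seqs[c]) for c in unassigned}

    def _take(pred, role: ChainRole, unique: bool, what: str):
        cands = [c for c in unassigned if pred(lengths[c]) and c not in roles]
        if unique and len(cands) > 1:
            raise ValueError(f"ambiguous {what} assignment, candidates {cands}; "
                             "supply hints")
        for c in cands[: 1 if unique else None]:
            roles[c] = role

    _take(lambda n: 8 <= n <= 12, ChainRole.PEPTIDE, unique=True, what="PEPTIDE")
    _take(lambda n: 95 <= n <= 105, ChainRole.B2M, unique=True, what="B2M")
    _take(lambda n: 270 <= n <= 290, ChainRole.MHC_HEAVY, unique=True, what="MHC_HEAVY")

    ab_cands = [c for c in unassigned if c not in roles and lengths[c] >= 90]
    if ab_cands:
        if len(ab_cands) != 2:
            raise ValueError(
                f"cannot split antibody chains among candidates {ab_cands}; supply hints")
        calls: dict[str, ChainRole] = {}
        for c in ab_cands:
            heavy = bool(_HEAVY_MOTIF.search(seqs[c]))
            light = bool(_LIGHT_MOTIF.search(seqs[c]))
            if heavy == light:
                raise ValueError(
                    f"chain {c}: antibody heavy/light motif ambiguous; supply hints")
            calls[c] = ChainRole.AB_HEAVY if heavy else ChainRole.AB_LIGHT
        if set(calls.values()) != {ChainRole.AB_HEAVY, ChainRole.AB_LIGHT}:
            raise ValueError(
                f"both candidate antibody chains matched the same motif: {calls}; "
                "supply hints")
        roles.update(calls)

    for c in atoms["chain_id"].unique():
        roles.setdefault(c, ChainRole.OTHER)

    peptide_chains = [c for c, r in roles.items() if r is ChainRole.PEPTIDE]
    if len(peptide_chains) != 1:
        raise ValueError(f"expected exactly one PEPTIDE chain, got {peptide_chains}")

    pep = atoms[(atoms["chain_id"] == peptide_chains[0]) & atoms["is_polymer"]]
    residues = pep.drop_duplicates(subset=["residue_number", "insertion_code"])
    n = len(residues)
    if not 8 <= n <= 11:
        warnings.warn(f"peptide length {n} outside the class I range 8-11")
    positions = [(f"P{i + 1}", int(r.residue_number), r.insertion_code, r.residue_name)
                 for i, r in enumerate(residues.itertuples(index=False))]

    prov = dict(getattr(structure, "provenance", {}))
    prov["role_hints"] = {c: r.value for c, r in hints.items()}
    return AnnotatedComplex(
        atoms=atoms.reset_index(drop=True), role_map=roles,
        peptide_positions=positions, name=getattr(structure, "name", ""),
        provenance=prov)


# ---------------------------------------------------------------------------
# CDR annotation
# ---------------------------------------------------------------------------

#: Standard CDR intervals applied to author numbering.  Useful only when the
#: deposited antibody chains are author-numbered in the corresponding scheme,
#: which must be confirmed per structure; otherwise pass manual ranges.
CDR_SCHEMES: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
    "kabat": {
        "heavy": {"H1": (31, 35), "H2": (50, 65), "H3": (95, 102)},
        "light": {"L1": (24, 34), "L2": (50, 56), "L3": (89, 97)},
    },
    "chothia": {
        "heavy": {"H1": (26, 32), "H2": (52, 56), "H3": (95, 102)},
        "light": {"L1": (24, 34), "L2": (50, 56), "L3": (89, 97)},
    },
}


def annotate_cdrs(complex_: AnnotatedComplex, scheme: str = "chothia",
                  manual_ranges: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
                  ) -> AnnotatedComplex:
    """Record the six CDR intervals on the antibody chains.

    ``scheme`` applies the standard Kabat/Chothia interval tables to the
    author numbering; ``manual_ranges`` (chain_id -> {name: (lo, hi)}) are
    accepted verbatim and take precedence.  The scheme used is recorded in
    the provenance metadata.
    """
    heavy = complex_.chain(ChainRole.AB_HEAVY)
    light = complex_.chain(ChainRole.AB_LIGHT)
    seqs = chain_sequences(complex_.atoms)
    for c in (heavy, light):
        if len(seqs.get(c, "")) < 90:
            raise ValueError(f"antibody chain {c} shorter than a V domain")

    cdr_map: dict[str, dict[str, tuple[int, int]]] = {}
    if manual_ranges is not None:
        for chain_id, ranges in manual_ranges.items():
            if not ranges:
                raise ValueError(f"empty manual CDR range set for chain {chain_id}")
            clean = {}
            for name, (lo, hi) in ranges.items():
                if hi < lo:
                    raise ValueError(f"empty CDR range {name}: ({lo}, {hi})")
                clean[name] = (int(lo), int(hi))
            cdr_map[chain_id] = clean
        scheme_used = "manual"
    else:
        if scheme not in CDR_SCHEMES:
            raise ValueError(f"unknown CDR scheme {scheme!r}")
        cdr_map[heavy] = dict(CDR_SCHEMES[scheme]["heavy"])
        cdr_map[light] = dict(CDR_SCHEMES[scheme]["light"])
        scheme_used = scheme

    prov = dict(complex_.provenance)
    prov["cdr_scheme"] = scheme_used
    return AnnotatedComplex(
        atoms=complex_.atoms, role_map=dict(complex_.role_map), cdr_map=cdr_map,
        peptide_positions=list(complex_.peptide_positions),
        name=complex_.name, provenance=prov)
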