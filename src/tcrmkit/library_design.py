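"""Focused randomization-library design from an interface footprint.

The design rule: randomize the antibody positions that contact the presented
peptide, preserve the positions that contact the MHC.  Positions contacting
both (PM) are randomized by default (``include_PM=True``) but the flag is
exposed because a stricter policy may preserve them.  Theoretical diversity
is the exact integer ``alphabet ** n_randomized`` — distinct from realized
transformant counts, which depend on transformation efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .footprint import FootprintTable

__all__ = ["DesignPolicy", "LibraryDesign", "select_positions",
           "theoretical_diversity", "design_report"]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DesignPolicy:
    contact_cutoff: float = 4.0
    side_chain_only: bool = False
    include_PM: bool = True
    restrict_to_cdrs: bool = True
    alphabet: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be > 0")


@dataclass
class LibraryDesign:
    randomized_positions: pd.DataFrame
    preserved_positions: pd.DataFrame
    theoretical_diversity: int
    policy: DesignPolicy
    complex_name: str = ""
    notes: list[str] = field(default_factory=list)


def theoretical_diversity(n_positions: int, alphabet_size: int = 20) -> int:
    """Exact ``alphabet_size ** n_positions`` (Python big integers)."""
    if n_positions < 1 or alphabet_size < 1:
        raise ValueError("n_positions and alphabet_size must be >= 1")
    return alphabet_size ** n_positions


def select_positions(footprint: FootprintTable, policy: DesignPolicy) -> LibraryDesign:
    """Apply the randomize-peptide-contacts / preserve-MHC-contacts rule."""
    table = footprint.table
    if policy.restrict_to_cdrs:
        table = table[table["cdr"] != "FR"]
    randomized_classes = {"P", "PM"} if policy.include_PM else {"P"}
    randomized = table[table["class"].isin(randomized_classes)]
    preserved = table[~table["class"].isin(randomized_classes)]
    if randomized.empty:
        raise ValueError("no peptide-contacting residues found under this policy")
    cols = ["chain", "residue_number", "insertion_code", "residue_name",
            "cdr", "class", "n_contacts_peptide", "n_contacts_mhc",
            "peptide_positions"]
    randomized = randomized[cols].reset_index(drop=True)
    preserved = preserved[cols].reset_index(drop=True)
    return LibraryDesign(
        randomized_positions=randomized,
        preserved_positions=preserved,
        theoretical_diversity=theoretical_diversity(len(randomized),
                                                    len(policy.alphabet)),
        policy=policy,
        complex_name=footprint.complex_name,
        notes=["theoretical diversity = alphabet^positions; realized library "
               "sizes are transformant counts and will be smaller"],
    )


def design_report(design: LibraryDesign) -> str:
    """Deterministic human-readable rendering of a library design."""
    lines = [
        f"Library design: {design.complex_name}",
        f"policy: cutoff={design.policy.contact_cutoff:.2f} A, "
        f"side_chain_only={design.policy.side_chain_only}, "
        f"include_PM={design.policy.include_PM}, "
        f"restrict_to_cdrs={design.policy.restrict_to_cdrs}, "
        f"alphabet={len(design.policy.alphabet)} aa",
        "",
        f"randomized positions ({len(design.randomized_positions)}):",
    ]
    for _, r in design.randomized_positions.iterrows():
        lines.append(f"  {r['chain']}{r['residue_number']}{r['insertion_code']:<2s}"
                     f"{r['residue_name']} {r['cdr']:<3s} class={r['class']}"
                     f" pep_positions={r['peptide_positions'] or '-'}")
    lines += ["", f"preserved positions ({len(design.preserved_positions)}):"]
    if design.preserved_positions.empty:
        lines.append("  none")
    else:
        for _, r in design.preserved_positions.iterrows():
            lines.append(f"  {r['chain']}{r['residue_number']}{r['insertion_code']:<2s}"
                         f"{r['residue_name']} {r['cdr']:<3s} class={r['class']}")
    div = design.theoretical_diversity
    lines += ["", f"theoretical diversity: {div:,} ({div:.2e})"]
    for note in design.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
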