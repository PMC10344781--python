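"""Peptide-enrichment profiling and a simple proteome scan.

Selection outputs are summarized as a position frequency matrix (PFM) over
*unique* peptides — the per-position amino-acid abundance underlying heatmap
and sequence-logo displays.  The proteome scan scores every length-L window
of a protein database by the summed log frequency of its residues, a
deliberately simple motif-match scorer for ranking candidate source proteins
of an enriched peptide motif.  The cytotoxicity helper implements the
standard reporter-assay formula (1 - treated/control) x 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PositionFrequencyMatrix", "frequency_matrix", "proteome_scan",
           "read_fasta", "cytotoxicity_percent", "AMINO_ACIDS"]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies from unique peptides.

    ``matrix`` is a (20, L) DataFrame indexed by amino acid with columns
    1..L; every column sums to 1.
    """

    matrix: pd.DataFrame
    n_unique_peptides: int
    pseudocount: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(self.matrix[c].idxmax() for c in self.matrix.columns)


def frequency_matrix(peptides: Sequence[str],
                     pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    """Column-normalized amino-acid counts over the unique peptides.

    Duplicates are counted once.  The pseudocount is added to every cell
    before normalization.  Mixed lengths or non-standard letters raise an
    error naming the offending row.
    """
    if not peptides:
        raise ValueError("no peptides given")
    unique = list(dict.fromkeys(p.upper() for p in peptides))
    L = len(unique[0])
    for i, pep in enumerate(unique):
        if len(pep) != L:
            raise ValueError(f"peptide {i} ({pep!r}) has length {len(pep)}, "
                             f"expected {L}")
        bad = set(pep) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"peptide {i} ({pep!r}) contains non-standard "
                             f"letters {sorted(bad)}")
    counts = np.zeros((20, L))
    for pep in unique:
        for j, aa in enumerate(pep):
            counts[_AA_INDEX[aa], j] += 1
    counts += pseudocount
    freqs = counts / counts.sum(axis=0, keepdims=True)
    matrix = pd.DataFrame(freqs, index=list(AMINO_ACIDS),
                          columns=range(1, L + 1))
    return PositionFrequencyMatrix(matrix=matrix,
                                   n_unique_peptides=len(unique),
                                   pseudocount=pseudocount)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def proteome_scan(pfm: PositionFrequencyMatrix,
                  proteome: Mapping[str, str] | str | Path,
                  anchor_mask: Sequence[int] | None = None,
                  epsilon: float = 1e-6,
                  top_n: int | None = 100) -> pd.DataFrame:
    """Score every length-L proteome window against the frequency matrix.

    score(window) = sum over positions of log(freq[aa, pos] + epsilon);
    positions listed in ``anchor_mask`` (1-based) are excluded from the sum
    (use for fixed MHC anchor positions).  Returns hits sorted by descending
    score, ties broken by protein id then offset (0-based, half-open).
    """
    if isinstance(proteome, (str, Path)):
        proteome = read_fasta(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    L = pfm.length
    mask = np.ones(L, dtype=bool)
    for pos in anchor_mask or ():
        if not 1 <= pos <= L:
            raise ValueError(f"anchor position {pos} outside 1..{L}")
        mask[pos - 1] = False
    logf = np.log(pfm.matrix.to_numpy() + epsilon)

    rows = []
    any_window = False
    for pid in sorted(proteome):
        seq = proteome[pid].upper()
        idx = np.array([_AA_INDEX.get(aa, -1) for aa in seq])
        for start in range(0, len(seq) - L + 1):
            window = idx[start:start + L]
            if np.any(window < 0):
                continue
            any_window = True
            score = float(logf[window[mask], np.nonzero(mask)[0]].sum())
            rows.append((pid, start, seq[start:start + L], score))
    if not any_window:
        import warnings
        warnings.warn("no scorable window: every sequence shorter than the motif")
        return pd.DataFrame(columns=["protein_id", "start", "window", "score"])
    hits = pd.DataFrame(rows, columns=["protein_id", "start", "window", "score"])
    hits = hits.sort_values(["score", "protein_id", "start"],
                            ascending=[False, True, True],
                            kind="mergesort").reset_index(drop=True)
    return hits.head(top_n) if top_n else hits


def cytotoxicity_percent(treated_units: float, control_units: float) -> float:
    """Reporter-assay cytotoxicity: (1 - treated/control) x 100.

    May be negative (treated signal above control); the value is reported
    as computed.
    """
    if control_units <= 0:
        raise ValueError("control_units must be > 0")
    return (1.0 - treated_units / control_units) * 100.0
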