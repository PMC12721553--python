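"""Multiple sequence alignments over the DNA alphabet, with ambiguity codes.

IUPAC ambiguity codes (and gaps) are mapped to the set of compatible bases:
full-uncertainty leaf partials in likelihood computations and full state-sets
in parsimony.  Reading goes through Bio.AlignIO (FASTA / NEXUS / PHYLIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treespace import TaxaOrder

__all__ = ["Alignment", "read_alignment", "write_fasta", "BASES"]

BASES = "ACGT"

# IUPAC nucleotide codes -> bitmask over (A, C, G, T)
_CODE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT", ".": "ACGT",
}
_MASK = {c: sum(1 << BASES.index(b) for b in s) for c, s in _CODE_SETS.items()}


@dataclass
class Alignment:
    """An N x M character matrix with taxon labels in a fixed order."""

    taxa: TaxaOrder
    matrix: np.ndarray  # (N, M) of single characters

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        bad = set(np.unique(self.matrix)) - set(_MASK)
        if bad:
            raise ValueError(f"unknown characters {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def state_masks(self) -> np.ndarray:
        """(N, M) uint8 bitmasks over ACGT, for parsimony."""
        lut = np.vectorize(_MASK.__getitem__, otypes=[np.uint8])
        return lut(self.matrix)

    def partials(self) -> np.ndarray:
        """(N, M, 4) leaf conditional likelihoods (1 for compatible bases)."""
        masks = self.state_masks()
        return ((masks[..., None] >> np.arange(4)) & 1).astype(float)


def read_alignment(path: str, fmt: str | None = None) -> Alignment:
    """Read FASTA / NEXUS / PHYLIP; taxa are ordered lexicographically."""
    from Bio import AlignIO

    if fmt is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        fmt = {"fa": "fasta", "fasta": "fasta", "fna": "fasta",
               "nex": "nexus", "nexus": "nexus",
               "phy": "phylip-relaxed", "phylip": "phylip-relaxed"}.get(suffix, "fasta")
    aln = AlignIO.read(path, fmt)
    records = {rec.id: str(rec.seq).upper() for rec in aln}
    taxa = TaxaOrder(list(records))
    matrix = np.array([list(records[name]) for name in taxa.names])
    return Alignment(taxa, matrix)


def write_fasta(path: str, alignment: Alignment) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(alignment.taxa.names):
            fh.write(f">{name}\n{''.join(alignment.matrix[i])}\n")
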