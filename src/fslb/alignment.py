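"""Amino-acid alignments with original-site-index bookkeeping.

Every filtering operation preserves each surviving column's original 1-based
index, so "remove the 1000 fastest sites" composes with taxon removal without
losing track of which supermatrix column a rate was estimated for.
"""

from __future__ import annotations

import io
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["AMINO_ACIDS", "Alignment"]

# PAML residue order; matches the bundled LG data file.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
MISSING = -1

_ENCODE = np.full(128, MISSING, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i
_DECODE = np.array(list(AMINO_ACIDS + "-"))


class Alignment:
    """Taxa x sites character matrix over the 20 amino acids.

    Gaps ('-') and ambiguity codes ('X', '?', '.', 'B', 'Z', 'J', 'U', 'O')
    are all treated as missing data.  Rows must be equal length and taxon
    labels unique.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        data: np.ndarray,
        site_indices: Optional[Sequence[int]] = None,
    ):
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise ValueError("alignment data must be a 2-D matrix")
        if len(taxa) != data.shape[0]:
            raise ValueError(f"{len(taxa)} labels for {data.shape[0]} rows")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if site_indices is None:
            site_indices = np.arange(1, data.shape[1] + 1)
        site_indices = np.asarray(site_indices, dtype=np.int64)
        if site_indices.shape != (data.shape[1],):
            raise ValueError("site_indices must have one entry per column")
        self.taxa = list(taxa)
        self.data = data
        self.site_indices = site_indices

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], sequences: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        rows = [_ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8) & 0x7F] for s in sequences]
        data = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.int8)
        return cls(taxa, data)

    # -- basic properties --------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sequence(self, taxon: str) -> str:
        row = self.data[self.taxa.index(taxon)]
        return "".join(_DECODE[row])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.site_indices, other.site_indices)
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"

    # -- filtering ---------------------------------------------------------

    def subset_taxa(self, keep: Iterable[str]) -> "Alignment":
        """Keep the given taxa, preserving the current row order."""
        keep = set(keep)
        unknown = keep - set(self.taxa)
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        rows = [i for i, t in enumerate(self.taxa) if t in keep]
        return Alignment([self.taxa[i] for i in rows], self.data[rows], self.site_indices)

    def select_site_positions(self, positions: Sequence[int]) -> "Alignment":
        """Keep columns by current 0-based position (original indices follow)."""
        positions = np.asarray(positions, dtype=np.int64)
        return Alignment(self.taxa, self.data[:, positions], self.site_indices[positions])

    # -- I/O ---------------------------------------------------------------

    def _records(self):
        return [
            SeqRecord(Seq("".join(_DECODE[self.data[i]])), id=t, description="")
            for i, t in enumerate(self.taxa)
        ]

    def to_fasta(self) -> str:
        buf = io.StringIO()
        SeqIO.write(self._records(), buf, "fasta")
        return buf.getvalue()

    def to_phylip(self) -> str:
        buf = io.StringIO()
        AlignIO.write(MultipleSeqAlignment(self._records()), buf, "phylip-relaxed")
        return buf.getvalue()

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_phylip())

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        records = list(SeqIO.parse(source, "fasta"))
        return cls.from_sequences([r.id for r in records], [str(r.seq) for r in records])

    @classmethod
    def from_phylip(cls, source) -> "Alignment":
        aln = AlignIO.read(source, "phylip-relaxed")
        return cls.from_sequences([r.id for r in aln], [str(r.seq) for r in aln])

    @classmethod
    def read(cls, path) -> "Alignment":
        """Read FASTA or relaxed PHYLIP, sniffing the format."""
        with open(path) as fh:
            head = fh.read(1)
        if head == ">":
            return cls.from_fasta(str(path))
        with open(path) as fh:
            return cls.from_phylip(fh)
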