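"""Promoter amplicon reference: sequence, CpG map, and the A/G variant.

The bisulfite amplicon covers the rDNA upstream control element / core
promoter and carries 25 contiguous CpG sites plus a single A/G SNV (major
allele G) used to restrict methylation calling to reads from the major
sequence variant.  The true promoter sequence is not redistributed here; a
synthetic stand-in with the same combinatorial structure (25 CpGs, one
variant site, plenty of non-CpG cytosines for conversion QC) is built
deterministically by :func:`default_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import encode_seq

N_CPGS = 25


@dataclass(frozen=True)
class AmpliconReference:
    """A bisulfite amplicon reference with annotated CpGs and one SNV.

    Parameters
    ----------
    sequence
        Upper-case DNA of the (unconverted, top-strand) amplicon.
    cpg_positions
        Zero-based offsets of the C of each of the 25 CpG dinucleotides,
        strictly increasing.
    variant_offset
        Zero-based offset of the A/G variant site.
    major_allele
        Base of the major allele at ``variant_offset`` (``"G"`` here).
    """

    sequence: str
    cpg_positions: tuple[int, ...]
    variant_offset: int
    major_allele: str = "G"
    name: str = "rDNA_promoter_amplicon"

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "cpg_positions", tuple(int(p) for p in self.cpg_positions))
        if len(self.cpg_positions) != N_CPGS:
            raise ValueError(f"expected {N_CPGS} CpG positions, got {len(self.cpg_positions)}")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError("CpG positions must be strictly increasing")
        for p in self.cpg_positions:
            if seq[p : p + 2] != "CG":
                raise ValueError(f"position {p} does not point at a CG dinucleotide")
        cpg_cols = {p for p in self.cpg_positions} | {p + 1 for p in self.cpg_positions}
        if self.variant_offset in cpg_cols:
            raise ValueError("variant offset lies inside a CpG dinucleotide")
        if seq[self.variant_offset] != self.major_allele:
            raise ValueError("reference base at variant offset must be the major allele")
        if len(self.non_cpg_c_positions) < 20:
            raise ValueError("reference needs >= 20 non-CpG cytosines for conversion QC")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def encoded(self) -> np.ndarray:
        return encode_seq(self.sequence)

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Offsets of reference cytosines outside CpG context (conversion QC)."""
        cpg = set(self.cpg_positions)
        return tuple(i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg)

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, fasta_path, annotation_path=None) -> None:
        """Write the sequence as FASTA plus a TSV sidecar with the annotation."""
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([rec], str(fasta_path), "fasta")
        if annotation_path is None:
            annotation_path = Path(str(fasta_path)).with_suffix(".annot.tsv")
        with open(annotation_path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write("cpg_positions\t" + ",".join(map(str, self.cpg_positions)) + "\n")
            fh.write(f"variant_offset\t{self.variant_offset}\n")
            fh.write(f"major_allele\t{self.major_allele}\n")

    @classmethod
    def from_fasta(cls, fasta_path, annotation_path=None) -> "AmpliconReference":
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        if annotation_path is None:
            annotation_path = Path(str(fasta_path)).with_suffix(".annot.tsv")
        ann: dict[str, str] = {}
        with open(annotation_path) as fh:
            header = fh.readline()
            if not header.startswith("key"):
                raise ValueError("annotation TSV must have a key/value header")
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                ann[k] = v
        return cls(
            sequence=str(rec.seq),
            cpg_positions=tuple(int(x) for x in ann["cpg_positions"].split(",")),
            variant_offset=int(ann["variant_offset"]),
            major_allele=ann.get("major_allele", "G"),
            name=rec.id,
        )


def default_reference(length: int = 280, seed: int = 20210892) -> AmpliconReference:
    """Build the default synthetic promoter amplicon.

    The sequence is generated deterministically: 25 CpGs evenly spread over
    the amplicon interior, one G variant site between two CpGs, and a GC-rich
    background (promoter-like) guaranteeing >= 20 non-CpG cytosines.  No CG
    dinucleotide occurs outside the 25 annotated sites, so CpG context is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    # background without any C directly before G and without CG pairs
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=[0.22, 0.30, 0.26, 0.22]))
    for i in range(length - 1):
        while seq[i] == "C" and seq[i + 1] == "G":
            seq[i] = str(rng.choice(["A", "T", "C"])) if rng.random() < 0.5 else "T"
            # replacing with C again impossible: re-check loop guard
            if seq[i] == "C":
                seq[i] = "T"
    # plant 25 CpGs in the interior, >= 4 nt apart
    start, stop = 20, length - 20
    cpg_pos = np.linspace(start, stop, N_CPGS).astype(int)
    for p in cpg_pos:
        seq[p], seq[p + 1] = "C", "G"
        if p >= 1 and seq[p - 1] == "C":
            seq[p - 1] = "T"  # avoid creating an unannotated CpG-like CC G run
        if p + 2 < length and seq[p + 2] == "G":
            pass  # CGG is fine; the annotated C is still the only CpG C
    # clean any accidental CG outside the annotated set
    annotated = set(int(p) for p in cpg_pos)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in annotated:
            seq[i] = "T"
    # variant site halfway between CpGs 12 and 13, forced to G
    mid = (int(cpg_pos[12]) + 2 + int(cpg_pos[13])) // 2
    cpg_cols = annotated | {p + 1 for p in annotated}
    while mid in cpg_cols or (mid >= 1 and seq[mid - 1] == "C"):
        mid += 1  # keep out of CpGs and avoid creating a new CG
    seq[mid] = "G"
    return AmpliconReference(
        sequence="".join(seq),
        cpg_positions=tuple(int(p) for p in cpg_pos),
        variant_offset=mid,
        major_allele="G",
    )
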