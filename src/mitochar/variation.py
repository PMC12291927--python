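"""Alignment-based polymorphism census, amino-acid substitution mapping and
SNP-based haplotype classification.

Gap (``-``) and ``N`` characters are missing data, never alleles: a column
containing only ``A`` and ``-`` is not polymorphic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import MITO_TABLE, STOP_CODONS

__all__ = [
    "AlignmentMatrix",
    "HaplotypeScheme",
    "AASubstitution",
    "polymorphic_sites",
    "variable_fraction",
    "aa_substitutions",
    "classify_haplotype",
    "site_diff",
    "base_at",
    "DEFAULT_CYTB_SCHEME",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AlignmentMatrix:
    """Equal-length aligned sequences over {A,C,G,T,N,-} with unique names."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sample names")
        if not self.seqs:
            raise ValueError("empty alignment")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        allowed = set("ACGTN-")
        for name, s in zip(self.names, self.seqs):
            bad = set(s) - allowed
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def row(self, name: str) -> str:
        try:
            return self.seqs[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sample named {name!r}") from None

    def encoded(self) -> np.ndarray:
        """int8 matrix: A=0 C=1 G=2 T=3, missing (N/-) = -1."""
        mapping = np.full(256, -1, dtype=np.int8)
        for base, code in _CODE.items():
            mapping[ord(base)] = code
        raw = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_samples, self.n_columns)
        return mapping[raw]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(names=names, seqs=seqs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.seqs):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def subset_columns(self, indices: Sequence[int]) -> "AlignmentMatrix":
        """New alignment from 0-based column indices (used by bootstrap)."""
        cols = list(indices)
        return AlignmentMatrix(
            names=list(self.names),
            seqs=["".join(s[i] for i in cols) for s in self.seqs],
        )


def polymorphic_sites(aln: AlignmentMatrix) -> list[int]:
    """1-based columns with >=2 distinct states among {A,C,G,T}."""
    if aln.n_samples < 2:
        raise ValueError("need at least two sequences")
    enc = aln.encoded()
    out = []
    for j in range(aln.n_columns):
        col = enc[:, j]
        states = np.unique(col[col >= 0])
        if states.size >= 2:
            out.append(j + 1)
    return out


def variable_fraction(aln: AlignmentMatrix) -> float:
    """Percentage of alignment columns that are polymorphic."""
    return 100.0 * len(polymorphic_sites(aln)) / aln.n_columns


def site_diff(row_a: str, row_b: str) -> int:
    """Hamming count over columns where both states are unambiguous bases."""
    if len(row_a) != len(row_b):
        raise ValueError("sequences differ in length")
    bases = set("ACGT")
    return sum(
        1
        for x, y in zip(row_a.upper(), row_b.upper())
        if x in bases and y in bases and x != y
    )


def base_at(row: str, position: int) -> str:
    """Base at a 1-based alignment position (single-site marker lookup)."""
    if not (1 <= position <= len(row)):
        raise ValueError(f"position {position} outside alignment of {len(row)}")
    return row[position - 1].upper()


@dataclass(frozen=True)
class AASubstitution:
    position: int  # 1-based codon/protein position
    ref: str
    alts: tuple[str, ...]  # distinct non-reference residues observed


def _codon_residue(codon: str) -> str | None:
    if any(ch not in "ACGT" for ch in codon):
        return None
    if codon in STOP_CODONS:
        return "*"
    return MITO_TABLE.forward_table[codon]


def aa_substitutions(
    aln: AlignmentMatrix, reference_row: str
) -> list[AASubstitution]:
    """Residue differences of every sample versus a named reference row.

    The alignment is read as in-frame concatenated coding sequence under the
    vertebrate mitochondrial code; codons containing gaps or N are skipped.
    A trailing partial codon is ignored with a warning.
    """
    ref = aln.row(reference_row)
    n_codons, rem = divmod(aln.n_columns, 3)
    if rem:
        warnings.warn(
            f"alignment length {aln.n_columns} not divisible by 3; "
            f"ignoring trailing {rem} column(s)",
            stacklevel=2,
        )
    subs: dict[int, tuple[str, set[str]]] = {}
    others = [s for name, s in zip(aln.names, aln.seqs) if name != reference_row]
    for i in range(n_codons):
        ref_res = _codon_residue(ref[3 * i : 3 * i + 3])
        if ref_res is None:
            continue
        for s in others:
            res = _codon_residue(s[3 * i : 3 * i + 3])
            if res is not None and res != ref_res:
                subs.setdefault(i + 1, (ref_res, set()))[1].add(res)
    return [
        AASubstitution(position=pos, ref=ref_res, alts=tuple(sorted(alts)))
        for pos, (ref_res, alts) in sorted(subs.items())
    ]


@dataclass(frozen=True)
class HaplotypeScheme:
    """Diagnostic-site haplotype rule: read bases at fixed alignment
    positions, join, look the word up in a label map.

    Positions are alignment coordinates anchored to whatever reference the
    caller aligned against, so the scheme is fully parameterizable.
    """

    positions: tuple[int, ...]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("duplicate haplotype labels")
        for word in self.labels:
            if len(word) != len(self.positions):
                raise ValueError(
                    f"label key {word!r} does not match {len(self.positions)} positions"
                )


#: cytochrome-b lineage scheme: four diagnostic positions on the reference
#: coordinate system, E* = European and A* = Asian lineages.
DEFAULT_CYTB_SCHEME = HaplotypeScheme(
    positions=(15036, 15038, 15041, 15045),
    labels={"TGCG": "E1", "TGTG": "E2", "CATA": "A1", "CATG": "A2", "TATG": "A3"},
)


def classify_haplotype(row: str, scheme: HaplotypeScheme = DEFAULT_CYTB_SCHEME) -> str:
    """Label a sequence from its bases at the scheme's diagnostic positions."""
    if scheme.positions[-1] > len(row):
        raise ValueError(
            f"scheme position {scheme.positions[-1]} outside sequence of {len(row)}"
        )
    word = "".join(row[p - 1].upper() for p in scheme.positions)
    if any(ch not in "ACGT" for ch in word):
        return "incomplete"
    return scheme.labels.get(word, f"unclassified({word})")
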