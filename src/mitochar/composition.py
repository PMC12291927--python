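"""Base/amino-acid composition, strand-asymmetry skews, translation and RSCU.

Skews follow the usual strand-asymmetry definitions,
``AT skew = (A - T) / (A + T)`` and ``GC skew = (G - C) / (G + C)``; a zero
denominator yields an explicit *undefined* state (``None``), never 0.
Translation uses the vertebrate mitochondrial genetic code (NCBI table 2):
AGA/AGG are stops, ATA codes Met and TGA codes Trp.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genome import CircularGenome, GeneFeature

__all__ = [
    "CompositionSummary",
    "MitoTranslation",
    "CodonProfile",
    "extract_region",
    "reverse_complement",
    "composition_summary",
    "translate_mito",
    "codon_counts",
    "rscu",
    "amino_acid_distribution",
    "codon_profile",
    "MITO_TABLE",
    "SYNONYMOUS_FAMILIES",
]

logger = logging.getLogger(__name__)

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
STOP_CODONS = frozenset(MITO_TABLE.stop_codons)  # TAA, TAG, AGA, AGG

#: codons grouped by encoded amino acid under the vertebrate mito code;
#: stop codons are excluded from every family.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(MITO_TABLE.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(genome: CircularGenome, feature: GeneFeature) -> str:
    """Wrap-aware slice of the feature, returned 5'->3' on the coding sense.

    Light-strand features are reverse-complemented so downstream translation
    and codon counting read the mRNA-sense sequence.
    """
    feature.validate_against(genome.length)
    if feature.wraps:
        raw = genome.seq[feature.start - 1 :] + genome.seq[: feature.stop]
    else:
        raw = genome.seq[feature.start - 1 : feature.stop]
    return reverse_complement(raw) if feature.strand == "-" else raw


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts/percentages and skews for one region (N excluded)."""

    region_label: str
    length: int
    counts: Mapping[str, int]
    percent: Mapping[str, float]
    at_percent: float
    at_skew: float | None
    gc_skew: float | None


def _skew(x: int | float, y: int | float) -> float | None:
    total = x + y
    if total == 0:
        return None
    return (x - y) / total


def composition_summary(seq: str, region_label: str = "region") -> CompositionSummary:
    """Counts, percentages (over A/C/G/T) and AT/GC skews of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    c = Counter(seq.upper())
    counts = {b: c.get(b, 0) for b in "ACGT"}
    n_count = c.get("N", 0)
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    if n_count > 0.10 * len(seq):
        logger.warning(
            "region %s: %.1f%% ambiguous bases", region_label, 100 * n_count / len(seq)
        )
    percent = {b: 100.0 * counts[b] / denom for b in "ACGT"}
    return CompositionSummary(
        region_label=region_label,
        length=len(seq),
        counts=counts,
        percent=percent,
        at_percent=percent["A"] + percent["T"],
        at_skew=_skew(counts["A"], counts["T"]),
        gc_skew=_skew(counts["G"], counts["C"]),
    )


@dataclass(frozen=True)
class MitoTranslation:
    protein: str
    start_codon: str
    stop_status: str  # complete | incomplete_T | incomplete_TA | none
    internal_stops: tuple[int, ...] = ()  # 1-based codon positions


def translate_mito(cds: str) -> MitoTranslation:
    """Translate a coding sequence under the vertebrate mitochondrial code.

    The final full codon, when it is a stop, terminates the protein and marks
    the gene *complete*.  Genes truncated at the annotation boundary are
    recognized by length mod 3: a trailing ``T`` (mod 1) or ``TA`` (mod 2) is
    an incomplete stop completed by mRNA polyadenylation.  Premature stop
    codons are kept as ``*`` in the protein and flagged, not fatal.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6:
        raise ValueError("coding sequence shorter than two codons")
    n_full = len(cds) // 3
    remainder = len(cds) % 3
    tail = cds[3 * n_full :]

    codons = [cds[3 * i : 3 * i + 3] for i in range(n_full)]
    stop_status = "none"
    if remainder == 1 and tail == "T":
        stop_status = "incomplete_T"
    elif remainder == 2 and tail == "TA":
        stop_status = "incomplete_TA"
    elif remainder == 0 and codons[-1] in STOP_CODONS:
        stop_status = "complete"
        codons = codons[:-1]

    protein_chars: list[str] = []
    internal: list[int] = []
    for i, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            protein_chars.append("*")
            internal.append(i)
        elif "N" in codon:
            protein_chars.append("X")
        else:
            protein_chars.append(MITO_TABLE.forward_table[codon])
    return MitoTranslation(
        protein="".join(protein_chars),
        start_codon=cds[:3],
        stop_status=stop_status,
        internal_stops=tuple(internal),
    )


def codon_counts(cds_list: Iterable[str]) -> Counter[str]:
    """Pooled counts of complete codons; terminal stop codons and trailing
    partial codons are excluded."""
    counts: Counter[str] = Counter()
    for cds in cds_list:
        cds = cds.upper().replace("U", "T")
        n_full = len(cds) // 3
        codons = [cds[3 * i : 3 * i + 3] for i in range(n_full)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        counts.update(c for c in codons if "N" not in c)
    return counts


def rscu(counts: Mapping[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage for every sense codon.

    RSCU(c) = count(c) * k / sum of counts over c's synonymous family, where
    k is the family size.  A family with zero total usage gets all zeros;
    stop codons never enter a family.
    """
    out: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = (counts.get(c, 0) * k / total) if total > 0 else 0.0
    return out


def amino_acid_distribution(proteins: Sequence[str]) -> dict[str, float]:
    """Pooled residue percentages over translated proteins.

    Stop (``*``) and ambiguous (``X``) symbols are excluded.
    """
    if not proteins:
        raise ValueError("no proteins supplied")
    pooled: Counter[str] = Counter()
    for p in proteins:
        pooled.update(ch for ch in p if ch not in "*X")
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no countable residues")
    return {aa: 100.0 * n / total for aa, n in sorted(pooled.items())}


@dataclass
class CodonProfile:
    """Codon usage of a gene set: counts, RSCU, residue distribution and the
    per-gene start/stop classification."""

    counts: Counter[str] = field(default_factory=Counter)
    rscu: dict[str, float] = field(default_factory=dict)
    aa_percent: dict[str, float] = field(default_factory=dict)
    gene_start: dict[str, str] = field(default_factory=dict)
    gene_stop_status: dict[str, str] = field(default_factory=dict)


def codon_profile(genome: CircularGenome) -> CodonProfile:
    """Codon usage, RSCU and amino-acid distribution over all PCGs."""
    from .genome import GeneClass

    pcgs = genome.features_of_class(GeneClass.PCG)
    if not pcgs:
        raise ValueError("genome has no protein-coding features")
    cds = {f.name: extract_region(genome, f) for f in pcgs}
    translations = {name: translate_mito(s) for name, s in cds.items()}
    counts = codon_counts(cds.values())
    return CodonProfile(
        counts=counts,
        rscu=rscu(counts),
        aa_percent=amino_acid_distribution([t.protein for t in translations.values()]),
        gene_start={n: t.start_codon for n, t in translations.items()},
        gene_stop_status={n: t.stop_status for n, t in translations.items()},
    )
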