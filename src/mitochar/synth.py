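"""Synthetic pig-like mitogenomes and alignments with known ground truth.

The packaged 37-gene coordinate skeleton (plus origin-spanning control
region) gives every generated genome the real gene-organization layout;
sequence content is synthetic, drawn from a tunable base composition, with
protein-coding regions written as valid vertebrate-mito ORFs, a control
region carrying a tunable tandem repeat, and optional per-sample variant
injection.  All randomness flows from one seed through fixed subkeys, so
sub-generators are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import expm

from .composition import MITO_TABLE, STOP_CODONS, reverse_complement
from .genome import (
    AnnotationError,
    CircularGenome,
    GeneClass,
    GeneFeature,
    feature_length,
    read_annotation_table,
)
from .phylo.tree import Node, PhyloTree
from .variation import AlignmentMatrix, HaplotypeScheme

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "TN93Params",
    "load_skeleton",
    "generate_genome",
    "inject_variants",
    "make_haplotype_panel",
    "simulate_alignment",
]

_SKELETON_LENGTH = 16581

# rng subkeys: background sequence, per-gene ORFs, control region, simulation
_BG, _ORF, _CTRL = 0, 1, 2

_SENSE_CODONS = tuple(sorted(MITO_TABLE.forward_table))
_BASES = "ACGT"


def load_skeleton(genome_length: int = _SKELETON_LENGTH) -> list[GeneFeature]:
    """The packaged annotation skeleton: 37 genes + wrapping control region."""
    ref = resources.files("mitochar.data") / "pig_mito_annotation.tsv"
    with resources.as_file(ref) as path:
        return read_annotation_table(path, genome_length)


@dataclass
class SynthSpec:
    """Parameters of one synthetic mitogenome."""

    seed: int = 0
    genome_length: int = _SKELETON_LENGTH
    #: target strand composition in percent, order A/T/C/G
    composition: dict[str, float] = field(
        default_factory=lambda: {"A": 34.0, "T": 26.3, "C": 27.8, "G": 11.9}
    )
    repeat_motif: str = "CGTACACGTG"
    repeat_copies: int = 9
    repeat_local_start: int = 705
    #: per-gene start-codon overrides (defaults: ATG everywhere, GTG for nad4l)
    start_codons: dict[str, str] = field(default_factory=lambda: {"nad4l": "GTG"})
    #: per-sample variant injections: sample -> [(1-based position, base)]
    variants: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    features: list[GeneFeature] | None = None  # defaults to the packaged skeleton


@dataclass
class SynthTruth:
    """Ground truth recorded while generating, for oracle-style tests."""

    coding_seqs: dict[str, str]  # intended 5'->3' coding sequence per PCG
    proteins: dict[str, str]  # intended translation (no terminal stop)
    intact_pcgs: list[str]  # PCGs whose region no later write disturbed
    variant_ledger: dict[str, list[tuple[int, str, str]]]  # (pos, ref, alt)
    samples: dict[str, str]  # variant sample sequences


def _composition_probs(composition: dict[str, float]) -> np.ndarray:
    p = np.array([composition[b] for b in _BASES], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid composition")
    return p / p.sum()


_CODON_BASE_COUNTS = np.array(
    [[codon.count(b) for b in _BASES] for codon in _SENSE_CODONS], dtype=float
)


def _codon_probs(base_probs: np.ndarray) -> np.ndarray:
    """Sense-codon sampling distribution whose per-base marginal matches the
    target composition.

    Excluding stop codons from independent per-base sampling biases the
    marginal (stops are A/T-rich), so the base weights are calibrated by
    iterative proportional fitting before forming codon products.
    """
    q = base_probs.copy()
    for _ in range(200):
        w = np.exp(_CODON_BASE_COUNTS @ np.log(np.maximum(q, 1e-12)))
        p = w / w.sum()
        marginal = (p @ _CODON_BASE_COUNTS) / 3.0
        if np.abs(marginal - base_probs).max() < 1e-10:
            break
        q *= base_probs / np.maximum(marginal, 1e-12)
        q /= q.sum()
    return p


def _positions(feature: GeneFeature, genome_length: int) -> list[int]:
    """0-based genome indices covered by the feature, in 5'->3' H-strand order."""
    if feature.wraps:
        return list(range(feature.start - 1, genome_length)) + list(
            range(0, feature.stop)
        )
    return list(range(feature.start - 1, feature.stop))


def _write_coding(
    seq: list[str], feature: GeneFeature, coding: str, genome_length: int
) -> None:
    placed = reverse_complement(coding) if feature.strand == "-" else coding
    for pos, base in zip(_positions(feature, genome_length), placed):
        seq[pos] = base


def _read_region(seq: list[str], feature: GeneFeature, genome_length: int) -> str:
    raw = "".join(seq[p] for p in _positions(feature, genome_length))
    return reverse_complement(raw) if feature.strand == "-" else raw


def _build_orf(
    n: int, start_codon: str, rng: np.random.Generator, codon_probs: np.ndarray
) -> str:
    """Coding sequence of exactly n bases: start codon, stop-free interior,
    then a complete TAA stop (n % 3 == 0), trailing T (1) or TA (2)."""
    if n < 6:
        raise ValueError("ORF shorter than two codons")
    n_full, rem = divmod(n, 3)
    n_middle = n_full - 1 - (1 if rem == 0 else 0)
    idx = rng.choice(len(_SENSE_CODONS), size=max(n_middle, 0), p=codon_probs)
    middle = "".join(_SENSE_CODONS[i] for i in idx)
    tail = {0: "TAA", 1: "T", 2: "TA"}[rem]
    return start_codon + middle + tail


def _translate_codons(coding: str) -> str:
    n_full = len(coding) // 3
    codons = [coding[3 * i : 3 * i + 3] for i in range(n_full)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return "".join(MITO_TABLE.forward_table[c] for c in codons)


def generate_genome(spec: SynthSpec) -> tuple[CircularGenome, SynthTruth]:
    """Deterministic synthetic mitogenome + ground truth for the given spec.

    PCGs are written in start order; where annotated genes overlap, the later
    gene's sequence wins in the shared region, so an earlier gene whose tail
    is overwritten may lose its terminal stop (as recorded in
    ``truth.intact_pcgs``).  Gene starts are never overwritten on the
    packaged skeleton.
    """
    L = spec.genome_length
    features = spec.features if spec.features is not None else load_skeleton(L)
    for f in features:
        if f.start > L or f.stop > L:
            raise AnnotationError(f"skeleton overflow: {f.name} exceeds {L} bp")

    base_probs = _composition_probs(spec.composition)
    rng_bg = np.random.default_rng(np.random.SeedSequence([spec.seed, _BG]))
    seq = [ _BASES[i] for i in rng_bg.choice(4, size=L, p=base_probs) ]

    codon_probs = _codon_probs(base_probs)
    coding_seqs: dict[str, str] = {}
    pcgs = sorted(
        (f for f in features if f.gene_class == GeneClass.PCG), key=lambda f: f.start
    )
    for gi, f in enumerate(pcgs):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _ORF, gi]))
        start_codon = spec.start_codons.get(f.name, "ATG")
        coding = _build_orf(feature_length(f, L), start_codon, rng, codon_probs)
        coding_seqs[f.name] = coding
        _write_coding(seq, f, coding, L)

    controls = [f for f in features if f.gene_class == GeneClass.CONTROL]
    if controls and spec.repeat_copies > 0:
        ctrl = controls[0]
        region_len = feature_length(ctrl, L)
        run = spec.repeat_motif * spec.repeat_copies
        if spec.repeat_local_start < 1 or spec.repeat_local_start - 1 + len(run) > region_len:
            raise ValueError("repeat run does not fit in the control region")
        region = list(_read_region(seq, ctrl, L))
        lo = spec.repeat_local_start - 1
        region[lo : lo + len(run)] = list(run)
        # guard against accidental flanking copies that would extend the run
        motif_len = len(spec.repeat_motif)
        if lo >= motif_len and "".join(region[lo - motif_len : lo]) == spec.repeat_motif:
            region[lo - 1] = "A" if region[lo - 1] != "A" else "C"
        hi = lo + len(run)
        if hi + motif_len <= region_len and "".join(region[hi : hi + motif_len]) == spec.repeat_motif:
            region[hi] = "A" if region[hi] != "A" else "C"
        _write_coding(seq, ctrl, "".join(region), L)

    intact = [
        f.name for f in pcgs if _read_region(seq, f, L) == coding_seqs[f.name]
    ]
    genome = CircularGenome(seq="".join(seq), features=list(features))

    ledger: dict[str, list[tuple[int, str, str]]] = {}
    samples: dict[str, str] = {}
    for sample, muts in spec.variants.items():
        positions = [p for p, _ in muts]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{sample}: injected positions must be distinct")
        samples[sample] = inject_variants(genome.seq, muts)
        ledger[sample] = [(p, genome.seq[p - 1], b.upper()) for p, b in muts]

    truth = SynthTruth(
        coding_seqs=coding_seqs,
        proteins={name: _translate_codons(c) for name, c in coding_seqs.items()},
        intact_pcgs=intact,
        variant_ledger=ledger,
        samples=samples,
    )
    return genome, truth


def inject_variants(seq: str, variants: list[tuple[int, str]]) -> str:
    """Copy of ``seq`` with the given (1-based position, base) substitutions."""
    out = list(seq)
    for pos, base in variants:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"variant position {pos} outside sequence")
        out[pos - 1] = base.upper()
    return "".join(out)


def make_haplotype_panel(
    base: CircularGenome, scheme: HaplotypeScheme
) -> AlignmentMatrix:
    """Base genome plus one sample per scheme word, as an ungapped alignment.

    Each non-base sample has the scheme's diagnostic positions overwritten
    with one label's defining bases, so classification recovers every label.
    """
    if scheme.positions[-1] > base.length:
        raise ValueError("scheme positions exceed genome length")
    names = ["base"]
    seqs = [base.seq]
    for word, label in sorted(scheme.labels.items(), key=lambda kv: kv[1]):
        names.append(label)
        seqs.append(
            inject_variants(base.seq, list(zip(scheme.positions, word)))
        )
    return AlignmentMatrix(names=names, seqs=seqs)


# ---------------------------------------------------------------------------
# alignment simulation under TN93


@dataclass(frozen=True)
class TN93Params:
    """Substitution-model parameters: equilibrium frequencies (A,C,G,T) and
    the two transition/transversion rate ratios."""

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa_purine: float = 2.0  # A<->G rate relative to transversions
    kappa_pyrimidine: float = 2.0  # C<->T rate relative to transversions

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix scaled to one expected substitution per
        site per unit branch length."""
        pi = np.asarray(self.freqs, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9 or (pi <= 0).any():
            raise ValueError("freqs must be positive and sum to 1")
        a, c, g, t = 0, 1, 2, 3
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                if {i, j} == {a, g}:
                    rate = self.kappa_purine
                elif {i, j} == {c, t}:
                    rate = self.kappa_pyrimidine
                else:
                    rate = 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu


def simulate_alignment(
    tree: PhyloTree,
    length: int,
    params: TN93Params | None = None,
    seed: int = 0,
) -> AlignmentMatrix:
    """Evolve sequences site-independently under TN93 down ``tree``.

    Branch lengths are expected substitutions/site.  Each node's mutation
    draws come from an rng keyed by (seed, node preorder index), so the
    output is a pure function of (tree, length, params, seed).
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    params = params or TN93Params()
    q = params.rate_matrix()
    pi = np.asarray(params.freqs)

    states: dict[int, np.ndarray] = {}
    names: list[str] = []
    seqs: list[str] = []
    preorder = list(tree.root.walk())
    parent_of: dict[int, Node] = {}
    for node in preorder:
        for child in node.children:
            parent_of[id(child)] = node
    for idx, node in enumerate(preorder):
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        if node is tree.root:
            states[id(node)] = rng.choice(4, size=length, p=pi)
        else:
            parent = parent_of[id(node)]
            t = node.length
            if t is None:
                raise ValueError("simulate_alignment requires branch lengths")
            trans = expm(q * t)
            trans = np.clip(trans, 0.0, None)
            trans /= trans.sum(axis=1, keepdims=True)
            parent_state = states[id(parent)]
            child = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = parent_state == s
                n = int(mask.sum())
                if n:
                    child[mask] = rng.choice(4, size=n, p=trans[s])
            states[id(node)] = child
        if node.is_leaf():
            if node.name is None:
                raise ValueError("all leaves must be named")
            names.append(node.name)
            seqs.append("".join(_BASES[i] for i in states[id(node)]))
    return AlignmentMatrix(names=names, seqs=seqs)
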