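"""Tandem-repeat counting and motif occurrence detection in control regions."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "RepeatReport",
    "count_tandem_copies",
    "find_motif_occurrences",
    "most_frequent_kmer",
    "local_to_genome",
]


@dataclass(frozen=True)
class RepeatReport:
    motif: str
    copy_number: int
    run_start: int | None  # 1-based position within the region; None if no copy
    mismatches_per_copy: tuple[int, ...] = ()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def count_tandem_copies(
    region: str, motif: str, max_mismatch_per_copy: int = 0
) -> RepeatReport:
    """Longest run of consecutive, non-overlapping near-copies of ``motif``.

    A run is a series of motif-length windows stepping by ``len(motif)``,
    each within ``max_mismatch_per_copy`` Hamming distance of the motif.
    Trailing partial copies are not counted.  Ties on run length resolve to
    the earliest start.
    """
    if not motif:
        raise ValueError("empty motif")
    region, motif = region.upper(), motif.upper()
    m = len(motif)
    n = len(region)
    if m > n:
        raise ValueError("motif longer than region")

    mism = [_hamming(region[i : i + m], motif) for i in range(n - m + 1)]
    ok = [d <= max_mismatch_per_copy for d in mism]
    # run_len[i]: copies in the run starting at window i (windows step by m)
    run_len = [0] * (n - m + 1)
    for i in range(n - m, -1, -1):
        if ok[i]:
            nxt = i + m
            run_len[i] = 1 + (run_len[nxt] if nxt <= n - m else 0)
    best = max(run_len, default=0)
    if best == 0:
        return RepeatReport(motif=motif, copy_number=0, run_start=None)
    start = run_len.index(best)
    per_copy = tuple(mism[start + k * m] for k in range(best))
    return RepeatReport(
        motif=motif, copy_number=best, run_start=start + 1, mismatches_per_copy=per_copy
    )


def find_motif_occurrences(region: str, motif: str) -> list[int]:
    """All (possibly overlapping) exact occurrences, 1-based positions."""
    if not motif:
        raise ValueError("empty motif")
    region, motif = region.upper(), motif.upper()
    out: list[int] = []
    i = region.find(motif)
    while i != -1:
        out.append(i + 1)
        i = region.find(motif, i + 1)
    return out


def most_frequent_kmer(region: str, k: int) -> tuple[str, int]:
    """Most frequent k-mer and its count (ties -> lexicographically first).

    A deliberately simple helper for synthetic tests, not a repeat-discovery
    algorithm.
    """
    if k < 1 or k > len(region):
        raise ValueError("k out of range")
    counts = Counter(region[i : i + k] for i in range(len(region) - k + 1))
    best = max(counts.values())
    kmer = min(km for km, n in counts.items() if n == best)
    return kmer, best


def local_to_genome(local_pos: int, region_start: int, genome_length: int) -> int:
    """Map a 1-based position inside a (possibly wrapping) region to a
    1-based genome coordinate."""
    if local_pos < 1:
        raise ValueError("local position must be >= 1")
    return (region_start - 1 + local_pos - 1) % genome_length + 1
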