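"""Tamura-Nei (TN93) pairwise distances on aligned nucleotide sequences.

The closed-form maximum-likelihood distance separates the two transition
classes (purine A<->G and pyrimidine C<->T) from transversions and uses
empirical base frequencies pooled over the pair's shared usable columns.
Columns where either sequence has a gap, N or other ambiguity are excluded
pairwise.  When any logarithm argument is non-positive (saturation) the
distance is *inapplicable* — reported as an explicit marker, never silently
NaN from the math library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..variation import AlignmentMatrix

__all__ = ["DistanceMatrix", "tn93_distance", "tn93_matrix"]

_A, _C, _G, _T = 0, 1, 2, 3
_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip("ACGT", (_A, _C, _G, _T)):
    _ENCODE[ord(_b)] = _c


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; NaN entries mark inapplicable
    (saturated) pairs, exposed through :meth:`inapplicable_pairs`."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(np.diag(self.matrix), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.matrix) < -1e-12:
                raise ValueError("negative distances")
        asym = np.nan_to_num(self.matrix) - np.nan_to_num(self.matrix.T)
        if np.abs(asym).max() > 1e-9:
            raise ValueError("matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.names)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])

    def inapplicable_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if math.isnan(self.matrix[i, j]):
                    out.append((self.names[i], self.names[j]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.matrix):
                cells = ["inapplicable" if math.isnan(v) else f"{v:.8f}" for v in row]
                fh.write(name + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln]
        names = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")[1:]
            rows.append(
                [math.nan if c == "inapplicable" else float(c) for c in cells]
            )
        return cls(names=names, matrix=np.array(rows))


def _tn93_from_encoded(a: np.ndarray, b: np.ndarray) -> float | None:
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        return None
    aa, bb = a[mask], b[mask]

    pooled = np.concatenate([aa, bb])
    freq = np.bincount(pooled, minlength=4) / (2.0 * n)
    g_a, g_c, g_g, g_t = (float(x) for x in freq)
    g_r, g_y = g_a + g_g, g_c + g_t

    diff = aa != bb
    pur_a, pur_b = (aa == _A) | (aa == _G), (bb == _A) | (bb == _G)
    q = float((pur_a != pur_b).mean())
    p1 = float((diff & pur_a & pur_b).mean())
    p2 = float((diff & ~pur_a & ~pur_b).mean())

    if p1 == 0.0 and p2 == 0.0 and q == 0.0:
        return 0.0
    if g_r == 0.0 or g_y == 0.0:
        return None

    terms = 0.0
    # purine-transition term
    if g_a * g_g == 0.0:
        if p1 > 0.0:
            return None
    else:
        w1 = 1.0 - g_r * p1 / (2.0 * g_a * g_g) - q / (2.0 * g_r)
        if w1 <= 0.0:
            return None
        terms -= (2.0 * g_a * g_g / g_r) * math.log(w1)
    # pyrimidine-transition term
    if g_t * g_c == 0.0:
        if p2 > 0.0:
            return None
    else:
        w2 = 1.0 - g_y * p2 / (2.0 * g_t * g_c) - q / (2.0 * g_y)
        if w2 <= 0.0:
            return None
        terms -= (2.0 * g_t * g_c / g_y) * math.log(w2)
    # transversion term
    w3 = 1.0 - q / (2.0 * g_r * g_y)
    if w3 <= 0.0:
        return None
    c3 = 2.0 * (g_r * g_y - g_a * g_g * g_y / g_r - g_t * g_c * g_r / g_y)
    terms -= c3 * math.log(w3)
    return max(terms, 0.0)


def tn93_distance(seq_a: str, seq_b: str) -> float | None:
    """TN93 distance in substitutions/site, or ``None`` when inapplicable."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    return _tn93_from_encoded(_encode(seq_a), _encode(seq_b))


def tn93_matrix(aln: AlignmentMatrix) -> DistanceMatrix:
    """All-pairs TN93 distances; inapplicable pairs become NaN entries."""
    enc = aln.encoded()
    n = aln.n_samples
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _tn93_from_encoded(enc[i], enc[j])
            mat[i, j] = mat[j, i] = math.nan if d is None else d
    return DistanceMatrix(names=list(aln.names), matrix=mat)
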