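"""Nonparametric bootstrap supports for TN93 + neighbor-joining trees.

Alignment columns are resampled with replacement; replicate r's resample is a
pure function of (seed, r), so a single seed reproduces the whole replicate
stream bit-for-bit regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..variation import AlignmentMatrix
from .distance import DistanceMatrix, _tn93_from_encoded
from .nj import nj_tree
from .tree import PhyloTree

__all__ = ["BootstrapError", "BootstrapResult", "bootstrap_support"]


class BootstrapError(RuntimeError):
    """Raised when too many replicates are unusable."""


@dataclass
class BootstrapResult:
    tree: PhyloTree  # reference tree with supports attached
    replicates: int
    dropped: int  # replicates discarded for inapplicable distances

    @property
    def retained(self) -> int:
        return self.replicates - self.dropped


def _matrix_from_columns(
    enc: np.ndarray, names: list[str], cols: np.ndarray
) -> DistanceMatrix | None:
    sub = enc[:, cols]
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _tn93_from_encoded(sub[i], sub[j])
            if d is None:
                return None
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(names=names, matrix=mat)


def bootstrap_support(
    aln: AlignmentMatrix,
    replicates: int = 1000,
    seed: int = 0,
    max_dropped_fraction: float = 0.10,
) -> BootstrapResult:
    """Reference TN93+NJ tree with bipartition supports in [0, 100].

    support(edge) = 100 x fraction of retained replicate trees containing the
    edge's leaf bipartition.  Replicates whose resampled matrix has an
    inapplicable distance are dropped and counted; more than
    ``max_dropped_fraction`` dropped is an error.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = aln.encoded()
    names = list(aln.names)
    n_cols = aln.n_columns

    ref_matrix = _matrix_from_columns(enc, names, np.arange(n_cols))
    if ref_matrix is None:
        raise BootstrapError("reference alignment has an inapplicable distance")
    ref_tree = nj_tree(ref_matrix)
    ref_splits = ref_tree.splits()

    counts: dict[frozenset, int] = {s: 0 for s in ref_splits}
    dropped = 0
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        cols = rng.integers(0, n_cols, size=n_cols)
        mat = _matrix_from_columns(enc, names, cols)
        if mat is None:
            dropped += 1
            continue
        rep_splits = nj_tree(mat).split_set()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if dropped > max_dropped_fraction * replicates:
        raise BootstrapError(
            f"{dropped}/{replicates} bootstrap replicates dropped "
            "(inapplicable distances)"
        )
    retained = replicates - dropped
    for split, node in ref_splits.items():
        node.support = 100.0 * counts[split] / retained if retained else 0.0
    return BootstrapResult(tree=ref_tree, replicates=replicates, dropped=dropped)
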