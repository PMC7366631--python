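"""Kennard-Stone sample selection and the stratified 70/15/15 split.

The Kennard-Stone algorithm picks calibration samples that cover the data
space uniformly: it starts from the two mutually most-distant samples and
then repeatedly adds the sample whose minimum Euclidean distance to the
already-selected set is largest.  Splitting is stratified — the ranking is
run inside each class separately — so a 70/15/15 split of 126 + 126
samples yields 88/19/19 per class (176/38/38 overall) and the test-set
class balance is exact.  The procedure is fully deterministic (ties break
toward the lower row index); no RNG is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataset import SpectrumSet
from .exceptions import StratificationError


@dataclass
class SplitResult:
    """Disjoint train/validation/test row-index arrays plus the requested fractions."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        parts = [self.train_idx, self.val_idx, self.test_idx]
        flat = np.concatenate(parts)
        if len(np.unique(flat)) != flat.size:
            raise ValueError("split sets overlap")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def sizes(self) -> tuple:
        return (self.train_idx.size, self.val_idx.size, self.test_idx.size)


def kennard_stone_rank(X: np.ndarray) -> np.ndarray:
    """Deterministic Kennard-Stone ordering of the rows of X.

    The first two entries are the maximally distant pair (lexicographically
    lowest pair on ties); each subsequent entry maximises the minimum
    distance to all already-ranked rows (lowest index on ties).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("Kennard-Stone requires finite entries")
    D = squareform(pdist(X))
    iu, ju = np.triu_indices(n, k=1)
    best = int(np.argmax(D[iu, ju]))  # first max in row-major order = lowest (i, j)
    order = [int(iu[best]), int(ju[best])]
    remaining = np.ones(n, dtype=bool)
    remaining[order] = False
    min_dist = np.minimum(D[order[0]], D[order[1]])
    while remaining.any():
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # argmax returns the lowest index on ties
        order.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(order, dtype=int)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(spectra: SpectrumSet, fractions=(0.70, 0.15, 0.15)) -> SplitResult:
    """Per-class Kennard-Stone split into train/validation/test.

    Within each class: the Kennard-Stone ranking's first
    round(train_frac * n_class) rows go to training; the remainder is
    re-ranked and its first round(val_frac * n_class) rows go to
    validation; what is left goes to test.  This reproduces 176/38/38 for
    252 balanced samples at (0.70, 0.15, 0.15).
    """
    f_train, f_val, f_test = fractions
    if min(f_train, f_val, f_test) <= 0:
        raise ValueError("all three fractions must be positive")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = spectra.label
    if any(l == "" for l in labels):
        raise ValueError("stratified_split requires labelled rows")

    train, val, test = [], [], []
    for cls in np.unique(labels):
        rows = np.nonzero(labels == cls)[0]
        if rows.size < 3:
            raise StratificationError(f"class {cls!r} has {rows.size} samples; need >= 3")
        rank = kennard_stone_rank(spectra.absorbance[rows])
        n_train = _round_half_up(f_train * rows.size)
        train.extend(rows[rank[:n_train]])
        rest = rows[rank[n_train:]]
        n_val = _round_half_up(f_val * rows.size)
        if rest.size >= 2 and 0 < n_val < rest.size:
            rank2 = kennard_stone_rank(spectra.absorbance[rest])
            val.extend(rest[rank2[:n_val]])
            test.extend(rest[rank2[n_val:]])
        else:
            val.extend(rest[:n_val])
            test.extend(rest[n_val:])

    return SplitResult(
        train_idx=np.sort(train),
        val_idx=np.sort(val),
        test_idx=np.sort(test),
        fractions=tuple(fractions),
    )
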