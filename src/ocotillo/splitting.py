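"""Stratified partitioning of labelled samples.

Rows are allocated to parts per class with largest-remainder rounding, so the
class proportions of every part match the whole table as closely as integer
counts allow.  The partition is disjoint, exhaustive and deterministic per
seed.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .errors import InvalidParameterError


def largest_remainder_allocation(total: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer allocation of ``total`` items proportional to ``fractions``.

    Floors the exact quotas, then hands the remaining items to the parts with
    the largest fractional remainders (ties broken toward the lower part
    index).
    """
    fractions = np.asarray(fractions, dtype=float)
    quotas = total * fractions
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        # stable sort descending by remainder; ties -> lower index first
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def stratified_split(labels: np.ndarray, fractions: Sequence[float], seed: int = 0) -> List[np.ndarray]:
    """Partition row indices into ``len(fractions)`` stratified parts.

    Parameters
    ----------
    labels : array of class identifiers, one per row.
    fractions : part sizes summing to 1 (within 1e-9).
    seed : seed of the per-class shuffle.

    Returns
    -------
    list of index arrays, one per part, disjoint and jointly exhaustive.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("fractions must sum to 1")
    if np.any(fractions < 0):
        raise InvalidParameterError("fractions must be non-negative")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: List[List[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_pos = int(np.sum(fractions > 0))
        if len(idx) < n_pos:
            raise InvalidParameterError(
                f"class {cls!r} has {len(idx)} samples, fewer than the {n_pos} non-empty parts"
            )
        idx = rng.permutation(idx)
        counts = largest_remainder_allocation(len(idx), fractions)
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start : start + c].tolist())
            start += c
    return [np.sort(np.array(p, dtype=int)) for p in parts]
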