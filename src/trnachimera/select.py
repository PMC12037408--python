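"""Sequence-space diversity: edit distances, clustering, max-min subsets.

The final stage of a design run reduces hundreds of surviving chimeras to
a handful worth synthesizing.  All notions of similarity here are
Levenshtein (unit-cost edit) distances on the assembled sequences:

1. an optional prefilter trims the candidate pool toward a cap by
   iteratively removing the sequences most distant from the parent tRNA
   (or applying a hard user threshold),
2. affinity propagation on the negated distance matrix picks cluster
   exemplars that represent the remaining sequence space, and
3. the output group of size *k* maximizes the minimum pairwise distance
   between its members (exhaustive when the subset count is small enough
   to enumerate, otherwise farthest-point greedy plus local swaps).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

log = logging.getLogger(__name__)

EXHAUSTIVE_SUBSET_LIMIT = 10**6


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Symmetric pairwise Levenshtein matrix with zero diagonal."""
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein(seqs[i], seqs[j])
    _check_matrix(d)
    return d


def _check_matrix(d: np.ndarray) -> None:
    if not np.array_equal(d, d.T):
        raise AssertionError("distance matrix not symmetric")
    if np.any(np.diag(d) != 0):
        raise AssertionError("distance matrix diagonal not zero")


def affinity_propagation_exemplars(
    d: np.ndarray, seed: int, damping: float = 0.9, max_iter: int = 500
) -> Optional[List[int]]:
    """Exemplar indices from affinity propagation on -distance.

    Similarity is the negated distance with the (sklearn default) median
    preference.  Returns ``None`` on non-convergence so callers can fall
    back deterministically.
    """
    sim = -d.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                affinity="precomputed",
                damping=damping,
                max_iter=max_iter,
                random_state=seed,
            ).fit(sim)
        except ConvergenceWarning:
            return None
    centers = getattr(ap, "cluster_centers_indices_", None)
    if centers is None or len(centers) == 0:
        return None
    return sorted(int(i) for i in centers)


def _k_medoids(d: np.ndarray, k: int, seed: int, n_iter: int = 50) -> List[int]:
    """Small PAM-style k-medoids used only as a clustering fallback."""
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    medoids = list(rng.choice(n, size=min(k, n), replace=False))
    for _ in range(n_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new = []
        for ci in range(len(medoids)):
            members = np.where(assign == ci)[0]
            if len(members) == 0:
                new.append(medoids[ci])
                continue
            costs = d[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[int(np.argmin(costs))]))
        if sorted(new) == sorted(medoids):
            break
        medoids = new
    return sorted(set(medoids))


def cluster_candidates(seqs: Sequence[str], seed: int = 0) -> List[int]:
    """Exemplar indices for a candidate pool.

    Affinity propagation on the negated Levenshtein matrix; if it fails to
    converge, falls back to k-medoids with k = ceil(sqrt(n)) (logged).
    """
    if len(seqs) < 2:
        return list(range(len(seqs)))
    d = distance_matrix(seqs)
    if np.all(d == 0):
        return [0]
    ex = affinity_propagation_exemplars(d, seed)
    if ex is None:
        k = math.ceil(math.sqrt(len(seqs)))
        log.warning(
            "affinity propagation did not converge; falling back to "
            "k-medoids with k=%d",
            k,
        )
        ex = _k_medoids(d, k, seed)
    return ex


def mismatch_prefilter(
    seqs: Sequence[str],
    parent: str,
    cap: int = 200,
    hard_threshold: Optional[int] = None,
) -> Tuple[List[str], Optional[int]]:
    """Trim a pool toward ``cap`` by distance to the parent tRNA.

    With ``hard_threshold`` set, sequences more than that many edits from
    the parent are discarded outright.  Otherwise whole tie-groups at the
    current maximum distance are removed until fewer than ``cap`` remain;
    removal stops (with a warning) before a step that would drop the pool
    below cap/2.  Returns the kept sequences (input order preserved) and
    the final distance cutoff applied, if any.
    """
    dists = {s: levenshtein(s, parent) for s in seqs}
    if hard_threshold is not None:
        kept = [s for s in seqs if dists[s] <= hard_threshold]
        return kept, hard_threshold
    kept = list(seqs)
    cutoff: Optional[int] = None
    while len(kept) >= cap:
        dmax = max(dists[s] for s in kept)
        survivors = [s for s in kept if dists[s] < dmax]
        if len(survivors) < cap / 2:
            log.warning(
                "stopping prefilter: removing the %d-edit tie group would "
                "leave %d < cap/2 sequences",
                dmax,
                len(survivors),
            )
            break
        kept = survivors
        cutoff = dmax - 1
    return kept, cutoff


@dataclass
class SelectionResult:
    exemplars: List[str]
    chosen: List[str]
    min_distance: int
    mode: str  # exhaustive | heuristic

    def pairwise(self) -> np.ndarray:
        return distance_matrix(self.chosen)


def _min_pair(d: np.ndarray, idx: Sequence[int]) -> int:
    return int(min(d[i, j] for i, j in combinations(idx, 2)))


def _greedy_maximin(d: np.ndarray, k: int) -> List[int]:
    n = d.shape[0]
    i, j = np.unravel_index(np.argmax(d), d.shape)
    chosen = [int(i), int(j)]
    while len(chosen) < k:
        rest = [x for x in range(n) if x not in chosen]
        best = max(rest, key=lambda x: min(d[x, c] for c in chosen))
        chosen.append(int(best))
    return chosen


def pick_diverse_group(seqs: Sequence[str], k: int, seed: int = 0) -> SelectionResult:
    """The k-subset maximizing the minimum pairwise Levenshtein distance.

    Exhaustive over all C(n, k) subsets when that count is at most 10^6;
    otherwise farthest-point greedy followed by single-swap hill climbing,
    with the search mode recorded in the result.
    """
    n = len(seqs)
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    if k == n:
        d = distance_matrix(seqs)
        mind = _min_pair(d, range(n)) if n > 1 else 0
        return SelectionResult(list(seqs), list(seqs), mind, "exhaustive")
    if k < 2:
        return SelectionResult(list(seqs), list(seqs[:k]), 0, "exhaustive")
    d = distance_matrix(seqs)
    if math.comb(n, k) <= EXHAUSTIVE_SUBSET_LIMIT:
        best_idx, best_val = None, -1
        for idx in combinations(range(n), k):
            val = _min_pair(d, idx)
            if val > best_val:
                best_idx, best_val = idx, val
        chosen = list(best_idx)
        mode = "exhaustive"
    else:
        chosen = _greedy_maximin(d, k)
        best_val = _min_pair(d, chosen)
        improved = True
        while improved:
            improved = False
            for ci in range(k):
                for cand in range(n):
                    if cand in chosen:
                        continue
                    trial = chosen[:ci] + [cand] + chosen[ci + 1 :]
                    val = _min_pair(d, trial)
                    if val > best_val:
                        chosen, best_val = trial, val
                        improved = True
        mode = "heuristic"
    return SelectionResult(
        list(seqs), [seqs[i] for i in chosen], int(best_val), mode
    )
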