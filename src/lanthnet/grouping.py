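"""Sequence grouping by identity-threshold connected components.

Stand-in for large-scale clusterers run in connected-component mode: an
all-vs-all pairwise-identity graph is thresholded and its connected components
become the groups, which transitively merges remote homologs (A~B and B~C
place A and C together even when A and C are dissimilar).  Default identity
cutoffs are 0.45 for proteases and 0.6 for precursor peptides; groups are then
size-filtered (defaults 100 and 10 members) and labelled ``Prot_k`` / ``Pre_k``
by descending size.

Identity metric
---------------
Identical positions of an optimal global (end-to-end) alignment divided by the
number of alignment columns.  Scoring is fixed at match +1 / mismatch 0 /
gap −1 (linear).  The dynamic program optimizes the triple
``(score, matches, −columns)`` lexicographically, so tie-breaking among
co-optimal alignments cannot change the identity value.  This is not
bit-compatible with any external clusterer's local-alignment identity; it
preserves the algorithmic role (threshold graph + connected components) with
desk-scale determinism.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import GROUP_PREFIX, GroupAssignment

DEFAULT_MIN_IDENTITY = {"protease": 0.45, "precursor": 0.6}
DEFAULT_MIN_SIZE = {"protease": 100, "precursor": 10}

# Lexicographic (score, matches, -columns) packed into one additive int64.
# Ranges: |score| <= L1+L2 <= 2^13, matches <= 2^13, columns <= 2^13, so the
# three fields cannot interfere.
_A = 1 << 40  # weight of one score unit
_B = 1 << 20  # weight of one matched column


def _nw_kernel(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Global alignment of two byte arrays; returns (matches, columns)."""
    n, m = len(a), len(b)
    E = np.empty((n + 1, m + 1), np.int64)
    M = np.zeros((n + 1, m + 1), np.int32)
    C = np.zeros((n + 1, m + 1), np.int32)
    E[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = E[0, j - 1] - _A - 1
        C[0, j] = j
    for i in range(1, n + 1):
        E[i, 0] = E[i - 1, 0] - _A - 1
        C[i, 0] = i
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1]
            e_diag = E[i - 1, j - 1] + ((_A + _B - 1) if is_match else -1)
            e_up = E[i - 1, j] - _A - 1
            e_left = E[i, j - 1] - _A - 1
            if e_diag >= e_up and e_diag >= e_left:
                E[i, j] = e_diag
                M[i, j] = M[i - 1, j - 1] + (1 if is_match else 0)
                C[i, j] = C[i - 1, j - 1] + 1
            elif e_up >= e_left:
                E[i, j] = e_up
                M[i, j] = M[i - 1, j]
                C[i, j] = C[i - 1, j] + 1
            else:
                E[i, j] = e_left
                M[i, j] = M[i, j - 1]
                C[i, j] = C[i, j - 1] + 1
    return int(M[n, m]), int(C[n, m])


try:  # JIT makes all-vs-all identity matrices cheap at desk scale
    from numba import njit

    _nw_kernel = njit(cache=False)(_nw_kernel)  # type: ignore[assignment]
except Exception:  # pragma: no cover - numba present in supported environments
    pass


def _encode(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence")
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment of a and b.

    Symmetric; 1.0 iff the sequences are identical; 0.0 when no position
    matches.  Empty sequences are an error.
    """
    matches, columns = _nw_kernel(_encode(a), _encode(b))
    return matches / columns


def identity_matrix(sequences: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """All-vs-all identity matrix over ``sequences`` (ids sorted for determinism)."""
    ids = sorted(sequences)
    encoded = [_encode(sequences[i]) for i in ids]
    n = len(ids)
    mat = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            matches, columns = _nw_kernel(encoded[i], encoded[j])
            mat[i, j] = mat[j, i] = matches / columns
    return ids, mat


def components_at(
    ids: Sequence[str], identities: np.ndarray, min_identity: float
) -> list[set[str]]:
    """Connected components of the identity graph thresholded at ``min_identity``."""
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identities[i, j] >= min_identity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, set[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(ids[i])
    return sort_groups(comps.values())


def sort_groups(groups: Iterable[set[str]]) -> list[set[str]]:
    """Canonical group order: descending size, ties by smallest member id."""
    return sorted(groups, key=lambda g: (-len(g), min(g)))


def cluster_members(sequences: Mapping[str, str], min_identity: float) -> list[set[str]]:
    """Partition sequences into identity-threshold connected components.

    ``min_identity`` must lie in (0, 1]; every member ends up in exactly one
    group.  The returned partition is independent of input order.
    """
    if not 0.0 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    if not sequences:
        return []
    ids, mat = identity_matrix(sequences)
    return components_at(ids, mat, min_identity)


def filter_groups(groups: Iterable[set[str]], min_size: int) -> list[set[str]]:
    """Retain groups with at least ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return sort_groups(g for g in groups if len(g) >= min_size)


def name_groups(groups: Iterable[set[str]], group_kind: str) -> list[GroupAssignment]:
    """Label groups ``Pre_k`` / ``Prot_k`` with k ranked by descending size.

    Ties are broken by the lexicographically smallest member id, making labels
    deterministic and input-order independent.
    """
    prefix = GROUP_PREFIX[group_kind]
    assignments: list[GroupAssignment] = []
    for k, group in enumerate(sort_groups(groups), start=1):
        label = f"{prefix}_{k}"
        for member in sorted(group):
            assignments.append(GroupAssignment(member, label, group_kind))
    return assignments
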