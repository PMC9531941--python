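"""Consensus network partitioning of boundary-overlap matrices.

Searchlights that share state boundaries form networks.  The overlap
matrix is clustered by maximizing an asymmetric signed modularity Q* that
weights positive edges fully but down-weights negative edges by the total
strength::

    Q* = Q+ - (v- / (v+ + v-)) * Q-

with Q± the resolution-γ modularity of the positive/negative part of the
matrix.  A Louvain-style greedy search with node-level fine-tuning
maximizes Q*; because the search is stochastic it is repeated many times
and the repetitions are summarized in a consensus matrix (co-assignment
proportions), thresholded at the chance level expected from random module
labels, and re-clustered until a single stable partition remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

__all__ = [
    "Partition",
    "modularity_signed",
    "louvain_once",
    "consensus_partition",
    "adjusted_mutual_information",
    "gamma_sweep",
]


@dataclass(frozen=True)
class Partition:
    """Searchlight -> network labels with their provenance."""

    labels: np.ndarray  # contiguous network ids 1..m
    gamma: float
    quality: float
    reps: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))


def _clean_matrix(w: np.ndarray) -> np.ndarray:
    w = np.array(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("weight matrix must be symmetric")
    n_missing = int(np.count_nonzero(~np.isfinite(w)))
    if n_missing:
        warnings.warn(f"{n_missing} missing matrix entries treated as zero weight")
        w = np.nan_to_num(w, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(w, 0.0)
    return w


def _modularity_matrix(w: np.ndarray, gamma: float) -> np.ndarray:
    """Generalized modularity matrix of the asymmetric signed Q*.

    Q*(labels) = sum of B[i, j] over same-community pairs (i, j).
    """
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp, vn = wp.sum(), wn.sum()
    if vp == 0 and vn == 0:
        raise ValueError("all-zero weight matrix")
    B = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        B += (wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        B -= (wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    return B


def modularity_signed(w: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Asymmetric signed modularity Q* of a labeling."""
    w = _clean_matrix(w)
    labels = np.asarray(labels)
    B = _modularity_matrix(w, gamma)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _local_move(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One round of greedy single-node moves on modularity matrix B."""
    n = B.shape[0]
    improved = False
    for i in rng.permutation(n):
        row = B[i].copy()
        row[i] = 0.0  # self-term identical in every community
        comms = np.unique(labels)
        gains = np.array([row[labels == c].sum() for c in comms])
        cur = gains[comms == labels[i]][0]
        best = int(np.argmax(gains))
        if gains[best] > cur + 1e-12:
            labels[i] = comms[best]
            improved = True
    return improved


def louvain_once(w: np.ndarray, gamma: float = 1.0, seed: int = 0) -> Partition:
    """One stochastic Louvain run plus node-level fine-tuning.

    Greedy local moving and community aggregation maximize Q*; the
    fine-tuning stage then reassigns single nodes of the full matrix while
    Q* keeps improving.  Deterministic given ``seed``.
    """
    w = _clean_matrix(w)
    rng = np.random.default_rng(seed)
    B0 = _modularity_matrix(w, gamma)
    n = w.shape[0]
    labels = np.arange(n)

    # Louvain: local moving to convergence, then community aggregation
    B = B0.copy()
    node_comm = np.arange(n)  # community of each original node
    while True:
        sub = np.arange(B.shape[0])
        any_move = False
        for _ in range(100):
            if not _local_move(B, sub, rng):
                break
            any_move = True
        if not any_move:
            break
        comms, inv = np.unique(sub, return_inverse=True)
        node_comm = inv[node_comm]
        m = comms.size
        if m == B.shape[0]:
            break
        onehot = np.eye(m)[inv]
        B = onehot.T @ B @ onehot

    labels = node_comm.copy()
    # fine-tuning: single-node refinement on the unaggregated matrix
    for _ in range(100):
        if not _local_move(B0, labels, rng):
            break

    _, labels = np.unique(labels, return_inverse=True)
    q = modularity_signed(w, labels, gamma)
    return Partition(labels=labels + 1, gamma=gamma, quality=q, reps=1, seed=seed)


def _chance_coassignment(
    partitions: list[np.ndarray], rng: np.random.Generator, draws: int = 1000
) -> float:
    """Chance that two searchlights share a label under random assignment.

    Module labels are shuffled uniformly, so the chance level depends only
    on the module-size distributions of the sampled partitions.
    """
    vals = np.empty(draws)
    for d in range(draws):
        lab = partitions[rng.integers(len(partitions))]
        n = lab.size
        _, counts = np.unique(lab, return_counts=True)
        vals[d] = float((counts * (counts - 1)).sum()) / (n * (n - 1))
    return float(vals.mean())


def consensus_partition(
    w: np.ndarray,
    gamma: float = 1.0,
    reps: int = 100,
    seed: int = 0,
    max_iter: int = 20,
    chance_draws: int = 1000,
) -> Partition:
    """Iterated consensus clustering of a (signed) overlap matrix.

    ``reps`` Louvain runs are summarized in a co-assignment matrix whose
    entries below the random-label chance level are zeroed; the thresholded
    matrix is re-clustered until every repetition agrees (the consensus
    matrix is binary).  The reported quality is Q* of the final labels on
    the *original* matrix.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    w = _clean_matrix(w)
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    current = w
    for it in range(max_iter):
        seeds = rng.integers(0, 2**31 - 1, size=reps)
        parts = [louvain_once(current, gamma=gamma, seed=int(s)).labels for s in seeds]
        stack = np.stack(parts)
        co = (stack[:, :, None] == stack[:, None, :]).mean(axis=0)
        if np.all((co == 0.0) | (co == 1.0)):
            labels = parts[0]
            q = modularity_signed(w, labels, gamma)
            return Partition(labels=labels, gamma=gamma, quality=q, reps=reps, seed=seed)
        thresh = _chance_coassignment(parts, rng, draws=chance_draws)
        co[co < thresh] = 0.0
        np.fill_diagonal(co, 0.0)
        if np.all(co == 0.0):  # no above-chance agreement at all: every node alone
            labels = np.arange(1, n + 1)
            q = modularity_signed(w, labels, gamma)
            return Partition(labels=labels, gamma=gamma, quality=q, reps=reps, seed=seed)
        current = co
    raise RuntimeError(
        f"consensus clustering did not converge in {max_iter} iterations "
        f"(gamma={gamma}, reps={reps}); last consensus matrix had "
        f"{np.count_nonzero((co > 0) & (co < 1))} non-binary entries"
    )


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """Chance-corrected similarity of two labelings (max-entropy normalization).

    Equals 1 for identical partitions (up to label permutation) and ~0 for
    independent ones; when both sides are a single cluster the partitions
    are identical and 1 is returned.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    if np.unique(a).size == 1 and np.unique(b).size == 1:
        return 1.0
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def gamma_sweep(
    w: np.ndarray,
    reference_labels,
    gammas=None,
    reps: int = 100,
    seed: int = 0,
) -> Partition:
    """Consensus-partition at each resolution; keep the partition most
    similar (by aMI) to a reference labeling.  Ties go to the lower γ."""
    if gammas is None:
        gammas = np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)
    reference_labels = np.asarray(reference_labels)
    best: Partition | None = None
    best_ami = -np.inf
    errors: list[str] = []
    for g in gammas:
        try:
            p = consensus_partition(w, gamma=float(g), reps=reps, seed=seed)
        except (RuntimeError, ValueError) as exc:
            errors.append(f"gamma={g}: {exc}")
            continue
        ami = adjusted_mutual_information(p.labels, reference_labels)
        if ami > best_ami:
            best, best_ami = p, ami
    if best is None:
        raise RuntimeError("no resolution converged: " + "; ".join(errors))
    return best
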