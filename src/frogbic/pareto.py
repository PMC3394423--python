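"""Dominance relations, the ε-dominance archive, crowding and sigma guides.

All objective vectors are minimized.  The archive keeps an ε-Pareto set: the
objective space is cut into axis-aligned boxes of side ε_i, at most one
member may occupy a box, and boxes (as well as raw vectors) are compared by
dominance.  This bounds the archive size over any observed objective range
and guarantees that every candidate ever presented stays covered within an
ε margin by some surviving member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = [
    "dominates",
    "pareto_set",
    "eps_dominates",
    "ArchiveMember",
    "EpsArchive",
    "crowding_distance",
    "sigma_value",
    "select_local_guide",
]


def dominates(f: np.ndarray, g: np.ndarray) -> bool:
    """Pareto dominance (minimization): f_i ≤ g_i for all i, strictly for some i."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValidationError(f"dimension mismatch: {f.shape} vs {g.shape}")
    return bool(np.all(f <= g) and np.any(f < g))


def pareto_set(vectors: Sequence[np.ndarray]) -> list[int]:
    """Indices of the non-dominated members of *vectors* (duplicates all kept)."""
    arr = np.asarray(vectors, dtype=float)
    if arr.size == 0:
        raise ValidationError("pareto_set of an empty collection is undefined")
    k = arr.shape[0]
    keep = []
    for i in range(k):
        diff_le = np.all(arr <= arr[i], axis=1)
        diff_lt = np.any(arr < arr[i], axis=1)
        if not np.any(diff_le & diff_lt):
            keep.append(i)
    return keep


def eps_dominates(f: np.ndarray, g: np.ndarray, epsilon: np.ndarray) -> bool:
    """Relaxed dominance for minimization: f_i ≤ (1+ε_i)·g_i for all i.

    As ε→0 this reduces to weak dominance, and ordinary dominance implies
    ε-dominance for every ε > 0.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), f.shape)
    if f.shape != g.shape:
        raise ValidationError(f"dimension mismatch: {f.shape} vs {g.shape}")
    if np.any(eps <= 0):
        raise ParameterError("epsilon components must be > 0")
    return bool(np.all(f <= (1.0 + eps) * g))


def _box_index(objectives: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    return np.floor(objectives / epsilon).astype(np.int64)


@dataclass
class ArchiveMember:
    objectives: np.ndarray
    box: np.ndarray
    payload: Any = None
    _sigma: np.ndarray | None = None

    @property
    def sigma(self) -> np.ndarray:
        """Cached sigma signature of this member's objectives."""
        if self._sigma is None:
            self._sigma = sigma_value(self.objectives)
        return self._sigma


class EpsArchive:
    """ε-Pareto archive with additive boxes floor(f_i/ε_i).

    Update rule for a candidate:

    * reject it if its box is dominated by a member's box, or a member's
      vector dominates its vector;
    * if it lands in an occupied box, keep whichever of the two vectors is
      closer (Euclidean) to the box's lower corner, incumbent on ties;
    * otherwise insert it and evict every member whose box is dominated by
      the candidate's box or whose vector it dominates.

    On exit the members are mutually non-dominated and one-per-box.
    """

    def __init__(self, epsilon: Sequence[float], track_history: bool = False):
        eps = np.asarray(epsilon, dtype=float)
        if eps.ndim != 1 or np.any(eps <= 0):
            raise ParameterError("epsilon must be a 1-D vector of positive reals")
        self.epsilon = eps
        self.members: list[ArchiveMember] = []
        self.track_history = track_history
        self.inserted_history: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def objectives_array(self) -> np.ndarray:
        if not self.members:
            return np.empty((0, len(self.epsilon)))
        return np.stack([m.objectives for m in self.members])

    def boxes_array(self) -> np.ndarray:
        if not self.members:
            return np.empty((0, len(self.epsilon)), dtype=np.int64)
        return np.stack([m.box for m in self.members])

    def add(self, objectives: np.ndarray, payload: Any = None) -> bool:
        """Offer a candidate; returns True if it was inserted (or replaced a member)."""
        f = np.asarray(objectives, dtype=float).ravel()
        if f.shape != self.epsilon.shape:
            raise ValidationError("objective dimensionality does not match epsilon")
        if not np.all(np.isfinite(f)):
            return False
        box = _box_index(f, self.epsilon)
        if not self.members:
            self._insert(f, box, payload)
            return True

        objs = self.objectives_array()
        boxes = self.boxes_array()

        same_box = np.all(boxes == box, axis=1)
        if same_box.any():
            idx = int(np.flatnonzero(same_box)[0])
            incumbent = self.members[idx]
            corner = box * self.epsilon
            if np.linalg.norm(f - corner) < np.linalg.norm(incumbent.objectives - corner):
                self.members[idx] = ArchiveMember(f.copy(), box, payload)
                if self.track_history:
                    self.inserted_history.append(f.copy())
                return True
            return False

        # Rejection: candidate's box dominated by some member's box, or its
        # vector dominated by some member's vector.
        box_dom_by = np.all(boxes <= box, axis=1) & np.any(boxes < box, axis=1)
        vec_dom_by = np.all(objs <= f, axis=1) & np.any(objs < f, axis=1)
        if (box_dom_by | vec_dom_by).any():
            return False

        # Insertion: evict members whose box or vector the candidate dominates.
        box_dom_of = np.all(box <= boxes, axis=1) & np.any(box < boxes, axis=1)
        vec_dom_of = np.all(f <= objs, axis=1) & np.any(f < objs, axis=1)
        evict = box_dom_of | vec_dom_of
        if evict.any():
            self.members = [m for m, dead in zip(self.members, evict) if not dead]
        self._insert(f, box, payload)
        return True

    def _insert(self, f: np.ndarray, box: np.ndarray, payload: Any) -> None:
        self.members.append(ArchiveMember(f.copy(), box.copy(), payload))
        if self.track_history:
            self.inserted_history.append(f.copy())


def crowding_distance(front: Sequence[np.ndarray]) -> np.ndarray:
    """NSGA-II crowding distance for one front (larger = less crowded).

    Boundary members per objective get infinite distance; interior members
    get the normalized gap between their neighbours, summed over objectives.
    Objectives with zero range contribute nothing.
    """
    arr = np.asarray(front, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    k, n_obj = arr.shape
    if k <= 2:
        return np.full(k, np.inf)
    dist = np.zeros(k)
    for j in range(n_obj):
        order = np.argsort(arr[:, j], kind="stable")
        span = arr[order[-1], j] - arr[order[0], j]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            gaps = (arr[order[2:], j] - arr[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def sigma_value(f: np.ndarray) -> np.ndarray:
    """Sigma direction signature of an objective vector.

    Two objectives: the scalar (f1²−f2²)/(f1²+f2²).  Three objectives: the
    vector (f1²−f2², f2²−f3², f3²−f1²)/(f1²+f2²+f3²).  Scale-invariant:
    sigma(k·f) = sigma(f) for k > 0; undefined at the all-zero vector.
    """
    f = np.asarray(f, dtype=float).ravel()
    sq = f**2
    total = sq.sum()
    if total == 0:
        raise ValidationError("sigma value undefined for the all-zero objective vector")
    if f.shape[0] == 2:
        return np.array([(sq[0] - sq[1]) / total])
    if f.shape[0] == 3:
        return np.array([sq[0] - sq[1], sq[1] - sq[2], sq[2] - sq[0]]) / total
    raise ValidationError("sigma value defined for 2 or 3 objectives only")


def select_local_guide(f: np.ndarray, archive: EpsArchive,
                       rng: np.random.Generator | None = None) -> ArchiveMember:
    """The archive member whose sigma value is nearest (Euclidean) to sigma(f).

    Ties are broken uniformly at random under *rng* (first member if absent).
    """
    if len(archive) == 0:
        raise ValidationError("cannot select a guide from an empty archive")
    target = sigma_value(f)
    sigmas = np.stack([m.sigma for m in archive.members])
    d = np.linalg.norm(sigmas - target, axis=1)
    best = np.flatnonzero(d == d.min())
    if len(best) > 1 and rng is not None:
        return archive.members[int(rng.choice(best))]
    return archive.members[int(best[0])]
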