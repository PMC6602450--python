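"""Rigid-body superposition and the GDT-TS similarity score.

GDT-TS (Global Distance Test, total score) between two CA traces is the
average, over the distance cutoffs 1, 2, 4 and 8 A, of the maximal fraction
of corresponding CA pairs that can be brought within the cutoff by a single
rigid superposition.  The maximum is approximated by a deterministic
seed-and-extend search (see :func:`gdt_ts`); an exhaustive-subset oracle is
provided for small instances so the heuristic can be audited.

Scores are reported as fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ValidationError
from .structio import CaTrace

#: The four distance cutoffs (Angstroms) averaged into GDT-TS.
CUTOFFS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

_CUTOFFS_ARR = np.array(CUTOFFS)

#: Contiguous-window seed lengths for the heuristic search (plus full length).
SEED_WINDOWS: tuple[int, ...] = (3, 5, 7)

#: Maximum refit iterations per seed/cutoff.
MAX_ITER = 20

#: Instance-size guard for the exhaustive oracle (2^n subsets).
ORACLE_MAX_PAIRS = 12


@dataclass(frozen=True)
class Correspondence:
    """Matched index pairs into two CA traces.

    Indices must be valid and strictly increasing in both coordinates
    (sequence-order-preserving matching, as in CASP model evaluation).
    """

    idx_a: np.ndarray
    idx_b: np.ndarray

    def __post_init__(self) -> None:
        ia = np.asarray(self.idx_a, dtype=np.int64)
        ib = np.asarray(self.idx_b, dtype=np.int64)
        object.__setattr__(self, "idx_a", ia)
        object.__setattr__(self, "idx_b", ib)
        if ia.shape != ib.shape or ia.ndim != 1:
            raise ValidationError("correspondence index arrays must be 1-D and equal length")
        if len(ia) < 1:
            raise ValidationError("correspondence must contain at least one pair")
        if np.any(np.diff(ia) <= 0) or np.any(np.diff(ib) <= 0):
            raise ValidationError("correspondence indices must be strictly increasing")
        if ia[0] < 0 or ib[0] < 0:
            raise ValidationError("correspondence indices must be non-negative")

    def __len__(self) -> int:
        return len(self.idx_a)

    @classmethod
    def from_pairs(cls, pairs) -> "Correspondence":
        arr = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class GdtResult:
    """GDT-TS score breakdown.

    ``gdt_ts`` is the mean of the four per-cutoff fractions; ``per_pair_flags``
    counts, for each corresponded pair, how many of the four best
    superpositions place it within the respective cutoff (0..4).
    """

    gdt_ts: float
    per_cutoff: dict[float, float]
    per_pair_flags: np.ndarray

    def __post_init__(self) -> None:
        fr = [self.per_cutoff[c] for c in CUTOFFS]
        if abs(self.gdt_ts - float(np.mean(fr))) > 1e-12:
            raise ValidationError("gdt_ts must equal the mean of the per-cutoff fractions")
        if any(fr[i] > fr[i + 1] + 1e-12 for i in range(3)):
            raise ValidationError("per-cutoff fractions must be non-decreasing in the cutoff")


def common_positions(a: CaTrace, b: CaTrace) -> Correspondence:
    """Correspondence over target positions present in both traces."""
    shared, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    if len(shared) == 0:
        raise ValidationError(f"no common positions between {a.name!r} and {b.name!r}")
    order = np.argsort(ia)
    return Correspondence(ia[order], ib[order])


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Optimal rigid map of point set A onto point set B (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    rotation (det +1) and ``rotation @ x + translation`` minimizing the RMSD
    of A onto B.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"coordinate shapes disagree: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValidationError(f"superposition needs >= 3 points, got {len(a)}")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    h = (a - mu_a).T @ (b - mu_b)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_b - rot @ mu_a
    rmsd = float(np.sqrt(np.mean(np.sum((a @ rot.T + trans - b) ** 2, axis=1))))
    return rot, trans, rmsd


def _paired_coords(model: CaTrace, reference: CaTrace, corr: Correspondence):
    if corr.idx_a[-1] >= len(model) or corr.idx_b[-1] >= len(reference):
        raise ValidationError("correspondence index out of range")
    if len(corr) < 3:
        raise ValidationError(f"GDT needs >= 3 corresponded pairs, got {len(corr)}")
    a = np.ascontiguousarray(model.coords[corr.idx_a], dtype=np.float64)
    b = np.ascontiguousarray(reference.coords[corr.idx_b], dtype=np.float64)
    return a, b


def _result(counts: np.ndarray, masks: np.ndarray, n: int) -> GdtResult:
    fractions = counts / n
    return GdtResult(
        gdt_ts=float(fractions.mean()),
        per_cutoff={c: float(f) for c, f in zip(CUTOFFS, fractions)},
        per_pair_flags=masks.sum(axis=0).astype(np.int64),
    )


def gdt_ts(model: CaTrace, reference: CaTrace,
           corr: Correspondence | None = None) -> GdtResult:
    """GDT-TS of ``model`` against ``reference`` over ``corr``.

    ``corr`` defaults to the pairs of common target positions.  Per-cutoff
    fractions are normalized by the number of corresponded pairs.  The search
    seeds a superposition from every contiguous window of lengths 3, 5, 7 and
    the full correspondence, then alternates refitting on the included pairs
    with re-inclusion of all pairs within the cutoff until stable; the best
    count per cutoff over all seeds is reported.  Deterministic.
    """
    if corr is None:
        corr = common_positions(model, reference)
    a, b = _paired_coords(model, reference, corr)
    windows = np.array(sorted({3, 5, 7, len(a)}), dtype=np.int64)
    counts, masks = _kernels.gdt_search(a, b, _CUTOFFS_ARR, windows, MAX_ITER)
    return _result(counts, masks, len(a))


def gdt_oracle(model: CaTrace, reference: CaTrace,
               corr: Correspondence | None = None) -> GdtResult:
    """Exhaustive-subset GDT-TS reference for small instances (<= 12 pairs).

    Superposes on every subset of >= 3 pairs and takes the best count per
    cutoff; upper-bounds (or equals) the heuristic on the same input.
    """
    if corr is None:
        corr = common_positions(model, reference)
    a, b = _paired_coords(model, reference, corr)
    if len(a) > ORACLE_MAX_PAIRS:
        raise ValidationError(
            f"oracle limited to {ORACLE_MAX_PAIRS} pairs (got {len(a)}): "
            "subset enumeration is exponential"
        )
    counts, masks = _kernels.oracle_search(a, b, _CUTOFFS_ARR)
    return _result(counts, masks, len(a))
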