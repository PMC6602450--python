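"""Consensus quality assessment over a pool of decoys.

Every decoy is first scored by the template-based method (:mod:`gdtqa.qascore`).
The top ``n_ref`` decoys by that global score become reference models, and a
decoy's consensus score is the weighted mean of its pairwise GDT-TS against
each reference, weighted by the reference's own template-based global score -
so better models contribute more.  A decoy never serves as its own reference
(configurable); with all references weighted equally the score reduces to the
naive consensus (mean pairwise GDT).

A per-position variant is available behind ``position_weighted=True``: pairwise
agreement at each position (fraction of the four GDT cutoffs satisfied by that
CA pair) is weighted by the reference's *local* score there, then pooled over
references and positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .gdt import CUTOFFS, common_positions, gdt_ts
from .qascore import QasResult, run_qas
from .structio import CaTrace, TargetSequence
from .templates import TemplatePool


@dataclass(frozen=True)
class QacResult:
    """Per-decoy consensus output.

    ``references`` lists (reference name, weight used, pairwise GDT-TS); the
    score is the weighted mean of the listed pairwise values.
    """

    decoy_name: str
    score: float
    references: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValidationError(f"consensus score out of [0, 1]: {self.score}")


def default_n_ref(pool_size: int) -> int:
    """Default reference count: max(5, ceil(0.2 * pool size)), capped at pool size."""
    return min(pool_size, max(5, math.ceil(0.2 * pool_size)))


def select_references(qas_results: list[QasResult], n_ref: int) -> list[str]:
    """Names of the ``n_ref`` decoys with the highest global scores (ties: name)."""
    if n_ref < 1:
        raise ValidationError(f"n_ref must be >= 1, got {n_ref}")
    if not qas_results:
        raise ValidationError("cannot select references from an empty pool")
    ranked = sorted(qas_results, key=lambda r: (-r.global_score, r.decoy_name))
    return [r.decoy_name for r in ranked[: min(n_ref, len(ranked))]]


def consensus_score(decoy: CaTrace,
                    references: list[CaTrace],
                    weights: dict[str, float],
                    self_exclude: bool = True) -> QacResult:
    """Weighted mean of pairwise GDT-TS against the reference models.

    ``weights`` maps reference name -> its template-based global score.  If
    the decoy is the only reference, its own weight is returned as the score
    (nothing to compare against); if every weight is 0 the plain mean is used
    with a warning.
    """
    usable = [r for r in references if not (self_exclude and r.name == decoy.name)]
    if not usable:
        if any(r.name == decoy.name for r in references):
            return QacResult(decoy.name, float(weights[decoy.name]), ())
        raise ValidationError(f"no usable reference for decoy {decoy.name!r}")
    rows = []
    for ref in usable:
        g = gdt_ts(decoy, ref, common_positions(decoy, ref)).gdt_ts
        rows.append((ref.name, float(weights[ref.name]), g))
    wsum = sum(w for _, w, _ in rows)
    if wsum <= 0:
        warnings.warn(
            f"all reference weights are zero for decoy {decoy.name!r}; "
            "falling back to the unweighted mean", stacklevel=2)
        score = float(np.mean([g for _, _, g in rows]))
    else:
        score = sum(w * g for _, w, g in rows) / wsum
    return QacResult(decoy.name, score, tuple(rows))


def _position_weighted_score(decoy: CaTrace, refs: list[CaTrace],
                             qas_by_name: dict[str, QasResult]) -> QacResult:
    rows = []
    num = den = 0.0
    for ref in refs:
        corr = common_positions(decoy, ref)
        res = gdt_ts(decoy, ref, corr)
        agree = res.per_pair_flags / len(CUTOFFS)
        h_ref = qas_by_name[ref.name].local
        # reference's local score at each shared target position
        w_j = h_ref[ref.positions[corr.idx_b] - 1]
        num += float(w_j @ agree)
        den += float(w_j.sum())
        rows.append((ref.name, float(qas_by_name[ref.name].global_score), res.gdt_ts))
    if den <= 0:
        warnings.warn(
            f"all per-position weights are zero for decoy {decoy.name!r}; "
            "falling back to the unweighted mean of pairwise GDT", stacklevel=2)
        score = float(np.mean([g for _, _, g in rows]))
    else:
        score = num / den
    return QacResult(decoy.name, score, tuple(rows))


def run_qac(target: TargetSequence,
            decoys: list[CaTrace],
            pool: TemplatePool,
            n_ref: int | None = None,
            self_exclude: bool = True,
            position_weighted: bool = False,
            transform: str = "minmax",
            qas_results: list[QasResult] | None = None) -> list[QacResult]:
    """Consensus-score a pool of decoys (>= 2), sorted by score descending.

    Runs the template-based score on every decoy (unless precomputed results
    are passed), selects the top-``n_ref`` as references, then scores each
    decoy against them.  Deterministic and invariant to the input order.
    """
    if len(decoys) < 2:
        raise ValidationError(
            "consensus needs at least 2 decoys; use the single-model score instead")
    names = [d.name for d in decoys]
    if len(set(names)) != len(names):
        raise ValidationError("decoy names must be unique")
    if qas_results is None:
        qas_results = [run_qas(target, d, pool, transform) for d in decoys]
    by_name = {r.decoy_name: r for r in qas_results}
    if n_ref is None:
        n_ref = default_n_ref(len(decoys))
    ref_names = set(select_references(qas_results, n_ref))
    refs = sorted((d for d in decoys if d.name in ref_names), key=lambda d: d.name)
    weights = {r.decoy_name: r.global_score for r in qas_results}
    out = []
    for decoy in sorted(decoys, key=lambda d: d.name):
        usable = [r for r in refs if not (self_exclude and r.name == decoy.name)]
        if position_weighted and usable:
            out.append(_position_weighted_score(decoy, usable, by_name))
        else:
            out.append(consensus_score(decoy, refs, weights, self_exclude))
    out.sort(key=lambda r: (-r.score, r.decoy_name))
    return out


def naive_consensus(decoys: list[CaTrace]) -> dict[str, float]:
    """Unweighted mean pairwise GDT-TS of each decoy against all others.

    The classic consensus baseline; used as an oracle for the equal-weight
    reduction of :func:`consensus_score`.
    """
    if len(decoys) < 2:
        raise ValidationError("naive consensus needs at least 2 decoys")
    out = {}
    for d in decoys:
        vals = [gdt_ts(d, o, common_positions(d, o)).gdt_ts
                for o in decoys if o.name != d.name]
        out[d.name] = float(np.mean(vals))
    return out
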