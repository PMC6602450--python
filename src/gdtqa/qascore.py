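"""Quasi-single-model quality scores from a template pool.

For a decoy ``D`` of target sequence of length ``L`` and a pool of ``K``
template hits, the score has three ingredients:

* per-position weights ``W[k, j]`` in [0, 1]: how strongly template ``k``'s
  residue aligned to target position ``j`` resembles the target residue,
  measured on the BLOSUM62 substitution matrix rescaled to [0, 1]
  (``(s - s_min) / (s_max - s_min)`` with ``s_min = -4``, ``s_max = 11``);
  0 where the template does not align position ``j`` or a residue is unknown;
* per-template structural agreement ``S[k]``: the GDT-TS between the decoy
  and template ``k``'s fragment over their aligned positions;
* local score ``H[j] = sum_k W[k, j] S[k] / sum_k W[k, j]`` where any weight
  is positive, else 0 (the position is flagged uncovered).

The global score is the plain mean of ``H`` over *all* target positions, so
regions without template evidence pull the score down rather than being
ignored.  All scores live in [0, 1], higher is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .gdt import Correspondence, gdt_ts
from .structio import CaTrace, TargetSequence, check_against_target
from .templates import TemplateHit, TemplatePool

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
BLOSUM_MIN = -4.0
BLOSUM_MAX = 11.0

#: Weight transforms mapping a BLOSUM62 score onto [0, 1].
WEIGHT_TRANSFORMS = ("minmax", "relu")

#: Minimum aligned pairs for a usable template superposition.
MIN_PAIRS = 3


@dataclass(frozen=True)
class QasResult:
    """Per-decoy template-based quality output.

    ``S`` holds one GDT-TS per pool template (NaN where the template was
    dropped for sharing < 3 positions with the decoy); ``W`` is the
    (K x L) weight matrix; ``local`` the per-position scores ``H``;
    ``covered`` flags positions with any positive weight from a usable
    template.  ``global_score`` is exactly ``local.mean()``.
    """

    decoy_name: str
    S: np.ndarray
    W: np.ndarray
    local: np.ndarray
    global_score: float
    covered: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.global_score - float(np.mean(self.local))) > 1e-12:
            raise ValidationError("global score must equal the mean of local scores")
        if np.any((self.local < 0) | (self.local > 1)):
            raise ValidationError("local scores must lie in [0, 1]")
        if np.any(self.local[~self.covered] != 0):
            raise ValidationError("uncovered positions must score 0")


def blosum_weight(target_residue: str, template_residue: str,
                  transform: str = "minmax") -> float:
    """Similarity weight in [0, 1] for one aligned residue pair.

    ``minmax`` (default) rescales the BLOSUM62 score from [-4, 11] onto
    [0, 1]; ``relu`` uses ``max(0, s) / 11``, zeroing all unfavourable
    substitutions.  Any pair involving 'X' weighs 0.
    """
    a, b = target_residue.upper(), template_residue.upper()
    for r in (a, b):
        if len(r) != 1 or (r != "X" and r not in _BLOSUM62.alphabet):
            raise ValidationError(f"unknown residue letter {r!r}")
    if "X" in (a, b):
        return 0.0
    s = float(_BLOSUM62[a, b])
    if transform == "minmax":
        w = (s - BLOSUM_MIN) / (BLOSUM_MAX - BLOSUM_MIN)
    elif transform == "relu":
        w = max(0.0, s) / BLOSUM_MAX
    else:
        raise ValidationError(f"unknown weight transform {transform!r}")
    return float(min(max(w, 0.0), 1.0))


def weight_matrix(pool: TemplatePool, transform: str = "minmax") -> np.ndarray:
    """(K x L) matrix of per-position template weights (0 where unaligned)."""
    target = pool.target
    W = np.zeros((len(pool), len(target)))
    for k, hit in enumerate(pool.hits):
        if hit.alignment is None:
            continue
        for pair in hit.alignment:
            W[k, pair.target_position - 1] = blosum_weight(
                target.seq[pair.target_position - 1], pair.template_residue, transform)
    return W


def template_gdt(decoy: CaTrace, hit: TemplateHit) -> float | None:
    """GDT-TS between decoy and template fragment over their shared positions.

    The correspondence pairs the decoy residue at target position ``j`` with
    the template residue aligned to ``j``.  Returns None (caller drops the
    template) when fewer than 3 positions are shared.
    """
    if hit.alignment is None or hit.structure is None:
        return None
    decoy_idx = decoy.index_of()
    tmpl_idx = hit.structure.index_of()
    ia, ib = [], []
    for pair in hit.alignment:
        di = decoy_idx.get(pair.target_position)
        ti = tmpl_idx.get(pair.template_position)
        if di is not None and ti is not None:
            ia.append(di)
            ib.append(ti)
    if len(ia) < MIN_PAIRS:
        warnings.warn(
            f"template {hit.hit_id} shares only {len(ia)} position(s) with "
            f"decoy {decoy.name!r}; dropped", stacklevel=2)
        return None
    corr = Correspondence(np.array(ia), np.array(ib))
    return gdt_ts(decoy, hit.structure, corr).gdt_ts


def local_scores(S: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted per-position scores ``H`` and coverage flags.

    ``H[j] = sum_k W[k, j] S[k] / sum_k W[k, j]`` where the weight column sums
    positive, else 0.  Rows with NaN ``S`` (dropped templates) are excluded.
    """
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != len(S):
        raise ValidationError("weight matrix rows must match the number of templates")
    usable = np.isfinite(S)
    Su, Wu = S[usable], W[usable]
    denom = Wu.sum(axis=0)
    covered = denom > 0
    H = np.zeros(W.shape[1])
    if Wu.size:
        np.divide(Wu.T @ Su, denom, out=H, where=covered)
        np.clip(H, 0.0, 1.0, out=H)  # guard float round-off at the boundaries
    return H, covered


def global_score(H: np.ndarray) -> float:
    """Plain mean of the local scores over all target positions."""
    return float(np.mean(H))


def run_qas(target: TargetSequence, decoy: CaTrace, pool: TemplatePool,
            transform: str = "minmax") -> QasResult:
    """Score one decoy against a template pool (the full quasi-single pipeline)."""
    decoy = check_against_target(decoy, target)
    W = weight_matrix(pool, transform)
    S = np.full(len(pool), np.nan)
    for k, hit in enumerate(pool.hits):
        s = template_gdt(decoy, hit)
        if s is not None:
            S[k] = s
    if len(pool) == 0:
        H = np.zeros(len(target))
        covered = np.zeros(len(target), dtype=bool)
    else:
        H, covered = local_scores(S, W)
    return QasResult(
        decoy_name=decoy.name, S=S, W=W, local=H,
        global_score=global_score(H), covered=covered,
    )


def local_scores_table(target: TargetSequence, result: QasResult):
    """Per-position table (position, residue, local_score, covered), TSV-ready."""
    import pandas as pd

    return pd.DataFrame({
        "position": np.arange(1, len(target) + 1),
        "residue": list(target.seq),
        "local_score": np.round(result.local, 6),
        "covered": result.covered.astype(int),
    })
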