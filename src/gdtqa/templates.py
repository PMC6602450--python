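"""Template hit ingestion, heuristic T-score ranking, and pool assembly.

A template hit is one homolog found by a sequence search (Blast or HHsearch)
against structures of known fold: an E-value ``E``, sequence identity ``I``,
target coverage ``C``, a pairwise target-template alignment and the CA
coordinates of the aligned template fragment.  Hits are ranked by the
heuristic score

    T = (3 - log10 E) * I * C

whose first factor stays positive for every E < 1000, so marginal hits still
rank but never outrank significant ones.  The top 10 hits per search method
are merged - duplicates deliberately retained - into a pool of up to 20
templates that drives the downstream quality scores.

Live database searches are out of scope: hits arrive as a "bundle" directory
(hits.tsv + one aligned-FASTA and one fragment-PDB per hit), which keeps the
method independent of database versions.  Standard 12-column Blast tabular
output can also be ingested directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError
from .structio import CaTrace, TargetSequence, read_ca_trace, read_fasta

#: Blast E-values of 0.0 (reported underflow) are clamped here before log10.
EVALUE_MIN = 1e-180

METHODS = ("blast", "hhsearch")


@dataclass(frozen=True)
class AlignedPair:
    """One aligned column: target position/residue vs template position/residue."""

    target_position: int
    template_position: int
    target_residue: str
    template_residue: str


@dataclass(frozen=True)
class TemplateHit:
    """One homolog record with alignment and (optionally) coordinates.

    ``identity`` and ``coverage`` are fractions in [0, 1]; ``alignment`` is
    ``None`` while a tabular hit awaits its fragment ("alignment-pending").
    """

    method: str
    hit_id: str
    source: str
    evalue: float
    identity: float
    coverage: float
    alignment: tuple[AlignedPair, ...] | None = None
    structure: CaTrace | None = None
    tscore: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown search method {self.method!r}")
        if self.evalue < 0 or self.identity < 0 or self.coverage < 0:
            raise ValidationError("E-value, identity and coverage must be non-negative")
        if self.tscore is None:
            object.__setattr__(self, "tscore", t_score(self.evalue, self.identity, self.coverage))

    def aligned_target_positions(self) -> np.ndarray:
        if self.alignment is None:
            return np.empty(0, dtype=np.int64)
        return np.array([p.target_position for p in self.alignment], dtype=np.int64)

    def validate_against(self, target: TargetSequence) -> None:
        """Check alignment positions and residues against target and structure."""
        if self.alignment is None:
            return
        idx = self.structure.index_of() if self.structure is not None else None
        for pair in self.alignment:
            if not 1 <= pair.target_position <= len(target):
                raise ValidationError(
                    f"hit {self.hit_id}: aligned target position {pair.target_position} "
                    f"outside target of length {len(target)}"
                )
            if idx is not None:
                row = idx.get(pair.template_position)
                if row is None:
                    raise ValidationError(
                        f"hit {self.hit_id}: template position {pair.template_position} "
                        "has no coordinates in the fragment PDB"
                    )
                have = self.structure.seq[row]
                if have != pair.template_residue and "X" not in (have, pair.template_residue):
                    raise ValidationError(
                        f"hit {self.hit_id}: residue mismatch at template position "
                        f"{pair.template_position}: alignment says {pair.template_residue}, "
                        f"fragment PDB says {have}"
                    )


@dataclass(frozen=True)
class TemplatePool:
    """Merged pool of ranked hits (Blast top-k first, then HHsearch top-k).

    Duplicates are permitted: two hits to the same protein carry independent
    evidence (different alignments/fragments) and are deliberately kept.
    """

    hits: tuple[TemplateHit, ...]
    target: TargetSequence

    def __post_init__(self) -> None:
        if len(self.hits) > 20:
            raise ValidationError(f"template pool holds at most 20 hits, got {len(self.hits)}")

    def __len__(self) -> int:
        return len(self.hits)


def t_score(evalue: float, identity: float, coverage: float) -> float:
    """Heuristic template ranking score ``(3 - log10 E) * I * C``.

    ``E == 0`` (search-engine underflow) is clamped to ``EVALUE_MIN`` so the
    score stays finite with the ordering intact.
    """
    if evalue < 0:
        raise ValidationError(f"E-value must be >= 0, got {evalue}")
    if identity < 0 or coverage < 0:
        raise ValidationError("identity and coverage must be >= 0")
    return (3.0 - math.log10(max(evalue, EVALUE_MIN))) * identity * coverage


def rank_select_topk(hits: list[TemplateHit], k: int = 10) -> list[TemplateHit]:
    """Top-``k`` hits by T-score (ties: lower E first, then hit_id).

    Deterministic under any permutation of the input.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    ranked = sorted(hits, key=lambda h: (-h.tscore, h.evalue, h.hit_id))
    return ranked[: min(k, len(ranked))]


def merge_pools(blast10: list[TemplateHit], hh10: list[TemplateHit],
                target: TargetSequence) -> TemplatePool:
    """Concatenate the two per-method top-10 lists into one pool (no dedup)."""
    if len(blast10) > 10 or len(hh10) > 10:
        raise ValidationError("each per-method list holds at most 10 hits")
    return TemplatePool(hits=tuple(blast10) + tuple(hh10), target=target)


def build_pool(hits: list[TemplateHit], target: TargetSequence, k: int = 10) -> TemplatePool:
    """Rank hits per method and merge the two top-k lists (the full intake path)."""
    blast = rank_select_topk([h for h in hits if h.method == "blast"], k)
    hh = rank_select_topk([h for h in hits if h.method == "hhsearch"], k)
    return merge_pools(blast, hh, target)


def _alignment_from_fasta(text: str, hit_id: str) -> tuple[tuple[AlignedPair, ...], float, int]:
    """Parse a 2-record aligned FASTA (target row first, '-' gaps).

    Returns (pairs, identity, n_target_positions_in_row).
    """
    rows = []
    header, chunks = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                rows.append("".join(chunks))
            header, chunks = line, []
        else:
            chunks.append(line.upper())
    if header is not None:
        rows.append("".join(chunks))
    if len(rows) != 2:
        raise FormatError(f"hit {hit_id}: alignment FASTA must hold exactly 2 records")
    trow, qrow = rows
    if len(trow) != len(qrow):
        raise FormatError(f"hit {hit_id}: aligned rows differ in length")
    pairs: list[AlignedPair] = []
    matches = 0
    tpos = qpos = 0
    for ta, qa in zip(trow, qrow):
        if ta != "-":
            tpos += 1
        if qa != "-":
            qpos += 1
        if ta != "-" and qa != "-":
            pairs.append(AlignedPair(tpos, qpos, ta, qa))
            if ta == qa and ta != "X":
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return tuple(pairs), identity, tpos


def read_hits_bundle(bundle_dir: str | Path,
                     target: TargetSequence | None = None,
                     tolerance: float = 0.01) -> list[TemplateHit]:
    """Read a template-bundle directory into fully populated hits.

    The bundle holds ``hits.tsv`` (columns: method, hit_id, source, evalue,
    identity, coverage, aln_file, pdb_file) plus the referenced per-hit
    alignment FASTA and fragment PDB files.  Identity and coverage are
    recomputed from the alignment and must agree with the table within
    ``tolerance``; alignment/structure inconsistencies raise.
    """
    bundle = Path(bundle_dir)
    table_path = bundle / "hits.tsv"
    if not table_path.is_file():
        raise InputError(f"bundle not found: missing {table_path}")
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    required = ["method", "hit_id", "source", "evalue", "identity", "coverage",
                "aln_file", "pdb_file"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"hits.tsv lacks columns: {missing}")
    if len(table) == 0:
        warnings.warn(f"bundle {bundle} contains no hits", stacklevel=2)
        return []

    hits: list[TemplateHit] = []
    for row in table.itertuples(index=False):
        aln_path = bundle / row.aln_file
        pdb_path = bundle / row.pdb_file
        for p in (aln_path, pdb_path):
            if not p.is_file():
                raise InputError(f"hit {row.hit_id}: missing file {p}")
        pairs, identity, n_target = _alignment_from_fasta(
            aln_path.read_text(), row.hit_id)
        structure = read_ca_trace(pdb_path.read_text(), name=row.hit_id)
        target_len = len(target) if target is not None else n_target
        coverage = len(pairs) / target_len if target_len else 0.0
        stated_i, stated_c = float(row.identity), float(row.coverage)
        if abs(identity - stated_i) > tolerance:
            raise ValidationError(
                f"hit {row.hit_id}: stated identity {stated_i:.3f} disagrees with "
                f"alignment ({identity:.3f})"
            )
        if abs(coverage - stated_c) > tolerance:
            raise ValidationError(
                f"hit {row.hit_id}: stated coverage {stated_c:.3f} disagrees with "
                f"alignment ({coverage:.3f})"
            )
        hit = TemplateHit(
            method=row.method, hit_id=row.hit_id, source=row.source,
            evalue=float(row.evalue), identity=identity, coverage=coverage,
            alignment=pairs, structure=structure,
        )
        if target is not None:
            hit.validate_against(target)
        hits.append(hit)
    return hits


def read_blast_tabular(text: str, target_length: int,
                       method: str = "blast") -> list[TemplateHit]:
    """Parse standard 12-column Blast tabular output (``-outfmt 6``).

    Identity arrives as a percentage and is converted to a fraction; coverage
    is the aligned target span over the target length, capped at 1.  Hits
    with gapped alignments have no per-column mapping in this format and are
    returned alignment-pending (``alignment is None``); ungapped hits get the
    implied one-to-one run of aligned pairs with residues marked 'X' (tabular
    output carries no sequences).
    """
    hits: list[TemplateHit] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 12:
            raise FormatError(f"line {ln}: expected 12 tabular columns, got {len(fields)}")
        try:
            (_query, subject, pident, length, _mism, gaps,
             qstart, qend, sstart, send, evalue, _bits) = fields
            pident, evalue = float(pident), float(evalue)
            length, gaps = int(length), int(gaps)
            qstart, qend, sstart, send = map(int, (qstart, qend, sstart, send))
        except ValueError as exc:
            raise FormatError(f"line {ln}: {exc}") from None
        identity = pident / 100.0
        coverage = min((qend - qstart + 1) / target_length, 1.0)
        alignment = None
        if gaps == 0 and (qend - qstart) == (send - sstart):
            alignment = tuple(
                AlignedPair(qstart + i, sstart + i, "X", "X")
                for i in range(qend - qstart + 1)
            )
        hits.append(TemplateHit(
            method=method, hit_id=f"{subject}:{ln}", source=subject,
            evalue=evalue, identity=identity, coverage=coverage,
            alignment=alignment,
        ))
    return hits
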