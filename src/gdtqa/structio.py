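"""Structure and sequence I/O plus geometric summaries.

Everything downstream works on C-alpha traces: an ordered list of residues,
each carrying a 1-based target position, a one-letter amino-acid code and a
single CA coordinate in Angstroms.  Full-atom models are reduced to CA traces
on read because the quality scores computed here only ever look at CA atoms.

Dialect rules for PDB input (CASP-model convention):

* only ``ATOM`` records with atom name ``CA`` are used;
* residue sequence numbers are interpreted as 1-based target positions;
* alternate locations other than blank or ``A`` are ignored;
* insertion codes are rejected;
* only the first ``MODEL`` of a multi-model file is read.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.spatial.distance import pdist, squareform

from .errors import FormatError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass(frozen=True)
class TargetSequence:
    """A single-chain target amino-acid sequence."""

    seq: str
    name: str = "target"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValidationError("target sequence is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(f"unknown residue letters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CaTrace:
    """Ordered C-alpha trace of one chain.

    Parameters
    ----------
    positions
        1-based target positions, strictly increasing (gaps allowed).
    seq
        One-letter residue codes, same length as ``positions``.
    coords
        ``(n, 3)`` CA coordinates in Angstroms.
    name
        Label used in reports.
    """

    positions: np.ndarray
    seq: str
    coords: np.ndarray
    name: str = "trace"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        xyz = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "coords", xyz)
        if pos.ndim != 1 or len(pos) < 1:
            raise ValidationError("trace must contain at least one residue")
        if len(self.seq) != len(pos) or xyz.shape != (len(pos), 3):
            raise ValidationError("positions, seq and coords lengths disagree")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("target positions must be strictly increasing")
        if pos[0] < 1:
            raise ValidationError("target positions are 1-based")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("non-finite coordinate in trace")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(f"unknown residue letters in trace: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def residues(self):
        """Iterate ``(target_position, residue, coord)`` tuples."""
        for i in range(len(self)):
            yield int(self.positions[i]), self.seq[i], self.coords[i]

    def index_of(self) -> dict[int, int]:
        """Map target position -> row index."""
        return {int(p): i for i, p in enumerate(self.positions)}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CaTrace":
        """Return a copy with ``R @ x + t`` applied to every coordinate."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return CaTrace(self.positions.copy(), self.seq, new, self.name)


def read_ca_trace(pdb_text: str, chain: str | None = None, name: str = "trace") -> CaTrace:
    """Parse standard PDB content into a :class:`CaTrace`.

    Only CA atoms of the first model are used; ``chain`` selects a chain id
    (default: the first chain containing CA atoms).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB: {exc}") from None
    if len(st) == 0:
        raise FormatError("no model in PDB input")
    model = st[0]  # first MODEL only

    entries: list[tuple[int, str, np.ndarray]] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            ca = None
            for atom in res:
                if atom.name != "CA":
                    continue
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                ca = atom
                break
            if ca is None:
                continue
            if res.seqid.icode not in (" ", "\x00", ""):
                raise FormatError(
                    f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: "
                    "insertion codes are not supported"
                )
            tab = gemmi.find_tabulated_residue(res.name)
            letter = tab.one_letter_code.upper() if tab else "X"
            if letter not in ALPHABET:
                letter = "X"
            entries.append(
                (res.seqid.num, letter, np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
            )
        if chain is None and entries:
            break  # first chain with CA atoms
    if not entries:
        raise FormatError("no C-alpha atoms found" + (f" in chain {chain!r}" if chain else ""))

    entries.sort(key=lambda e: e[0])
    nums = [e[0] for e in entries]
    if len(set(nums)) != len(nums):
        raise FormatError("duplicate residue numbers after altloc filtering")
    return CaTrace(
        positions=np.array(nums, dtype=np.int64),
        seq="".join(e[1] for e in entries),
        coords=np.vstack([e[2] for e in entries]),
        name=name,
    )


def write_ca_trace(trace: CaTrace, chain: str = "A") -> str:
    """Serialize a CA trace as minimal standard PDB text.

    ``read_ca_trace(write_ca_trace(t)) == t`` holds for any valid trace
    (coordinates survive at the PDB's three-decimal precision, which is why
    generated fixtures are rounded on construction upstream).
    """
    lines = []
    for i, (pos, aa, xyz) in enumerate(trace.residues, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  {_THREE[aa]:>3s} {chain}{pos:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"           C  "
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fasta(text: str) -> TargetSequence:
    """Read a single-record FASTA into a :class:`TargetSequence`.

    Whitespace inside sequence lines is stripped and letters uppercased.
    Multiple records are rejected: the tool scores one target at a time.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) == 0:
        raise FormatError("no FASTA record found")
    if len(records) > 1:
        raise FormatError(f"expected one FASTA record, found {len(records)}")
    rec = records[0]
    seq = "".join(str(rec.seq).split()).upper()
    if not seq:
        raise FormatError("FASTA record has an empty sequence")
    return TargetSequence(seq=seq, name=rec.id or "target")


def check_against_target(trace: CaTrace, target: TargetSequence) -> CaTrace:
    """Validate a decoy trace against the target sequence.

    Residue numbers must fall inside the target; residues whose letter
    disagrees with the target at that position are dropped with a warning
    (no re-alignment is attempted).  'X' in either sequence matches anything.
    """
    pos = trace.positions
    if pos[-1] > len(target):
        raise ValidationError(
            f"trace {trace.name!r} has residue number {int(pos[-1])} beyond "
            f"target length {len(target)}"
        )
    keep = np.ones(len(trace), dtype=bool)
    for i, p in enumerate(pos):
        t, d = target.seq[p - 1], trace.seq[i]
        if t != d and t != "X" and d != "X":
            keep[i] = False
    if not keep.all():
        dropped = [int(p) for p, k in zip(pos, keep) if not k]
        warnings.warn(
            f"trace {trace.name!r}: dropped {len(dropped)} residue(s) that "
            f"disagree with the target sequence at positions {dropped[:10]}",
            stacklevel=2,
        )
        if not keep.any():
            raise ValidationError(f"trace {trace.name!r} shares no residues with target")
        return CaTrace(pos[keep], "".join(c for c, k in zip(trace.seq, keep) if k),
                       trace.coords[keep], trace.name)
    return trace


def distance_matrix(trace: CaTrace) -> np.ndarray:
    """Symmetric matrix of pairwise CA-CA Euclidean distances in Angstroms."""
    return squareform(pdist(trace.coords))


def contact_map(dist: np.ndarray, cutoff: float) -> np.ndarray:
    """Binary contact map: 1 where the CA-CA distance is <= ``cutoff`` (i != j)."""
    if cutoff <= 0:
        raise ValidationError(f"contact cutoff must be positive, got {cutoff}")
    m = (np.asarray(dist) <= cutoff).astype(np.int8)
    np.fill_diagonal(m, 0)
    return m


def distance_matrix_frame(trace: CaTrace) -> pd.DataFrame:
    """Distance matrix as a DataFrame indexed by target positions (TSV-ready)."""
    pos = [int(p) for p in trace.positions]
    return pd.DataFrame(distance_matrix(trace), index=pos, columns=pos)
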