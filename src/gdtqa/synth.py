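"""Seeded synthetic fixtures: targets, natives, graded decoys, template bundles.

Real inputs to the scoring pipeline are a target sequence, predicted models
and a template search result; all three are emulated here with known ground
truth so every stage is testable offline.  The native backbone is an
idealized helical curve (rise 1.5 A, ~100 deg/residue, radius chosen so the
consecutive CA-CA distance is exactly 3.8 A), which guarantees protein-like
spacing and non-degenerate geometry without clash checking.  Decoys add
isotropic Gaussian coordinate noise followed by a random rigid motion (so
superposition is always exercised); templates are contiguous native fragments
with point-mutated sequences and lightly perturbed coordinates (sigma 0.3 A).

All generators take an integer seed and are byte-identical across runs:
coordinates are rounded to the PDB's three decimals at generation time, so
writing and re-reading a fixture is the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gdt import gdt_ts
from .structio import AMINO_ACIDS, CaTrace, TargetSequence, write_ca_trace
from .templates import read_hits_bundle

#: Helical backbone geometry: rise per residue (A) and turn per residue (deg).
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
#: Radius solving 3.8 A consecutive CA spacing for the rise/turn above.
HELIX_RADIUS = math.sqrt(3.8**2 - HELIX_RISE**2) / (2.0 * math.sin(math.radians(HELIX_TURN_DEG / 2)))

#: Coordinate noise added to template fragments (A).
TEMPLATE_COORD_SIGMA = 0.3

#: Synthetic E-value range (log-uniform).
EVALUE_RANGE = (1e-50, 1.0)


def _random_rigid(rng: np.random.Generator):
    """Uniform random rotation (quaternion method) + translation in [-20, 20]^3."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans


def make_native(length: int, seed: int) -> tuple[TargetSequence, CaTrace]:
    """Random target sequence + idealized helical native CA trace."""
    if length < 10:
        raise ValidationError(f"native length must be >= 10, got {length}")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    i = np.arange(length)
    theta = np.radians(HELIX_TURN_DEG) * i
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ]).round(3)
    target = TargetSequence(seq=seq, name=f"synth_t{length}_s{seed}")
    native = CaTrace(np.arange(1, length + 1), seq, coords, name="native")
    return target, native


def make_decoy(native: CaTrace, sigma: float, seed: int, name: str | None = None) -> CaTrace:
    """Decoy = native + isotropic Gaussian noise (std ``sigma`` per axis) + rigid motion."""
    if sigma < 0:
        raise ValidationError(f"noise sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    coords = native.coords + rng.normal(0.0, sigma, size=native.coords.shape) if sigma > 0 \
        else native.coords.copy()
    rot, trans = _random_rigid(rng)
    coords = (coords @ rot.T + trans).round(3)
    return CaTrace(native.positions.copy(), native.seq, coords,
                   name=name or f"decoy_s{sigma:g}_r{seed}")


@dataclass(frozen=True)
class BundleHit:
    """In-memory form of one synthetic template-bundle entry."""

    row: dict
    aln_text: str
    pdb_text: str


@dataclass(frozen=True)
class Bundle:
    """Template-bundle directory content, writable and re-readable."""

    hits: tuple[BundleHit, ...]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = ["method", "hit_id", "source", "evalue", "identity", "coverage",
                "aln_file", "pdb_file"]
        lines = ["\t".join(cols)]
        for h in self.hits:
            lines.append("\t".join(str(h.row[c]) for c in cols))
            (out / h.row["aln_file"]).write_text(h.aln_text)
            (out / h.row["pdb_file"]).write_text(h.pdb_text)
        (out / "hits.tsv").write_text("\n".join(lines) + "\n")
        return out


def make_template_bundle(native: CaTrace, target: TargetSequence, n_hits: int,
                         mutation_rate: float = 0.1, fragment_coverage: float = 0.6,
                         seed: int = 0, correlated: bool = False,
                         coord_sigma: float = TEMPLATE_COORD_SIGMA) -> Bundle:
    """Synthetic homolog-search result emulating near-native templates.

    Each hit is a contiguous native fragment (length ``fragment_coverage`` x
    target length) whose sequence is point-mutated at ``mutation_rate`` and
    whose coordinates carry 0.3 A Gaussian noise plus a rigid motion.
    E-values are log-uniform in [1e-50, 1] and, by default, uncorrelated with
    quality; ``correlated=True`` assigns the lowest E-values to the
    least-mutated hits so T-score ranking becomes meaningful.
    """
    if n_hits < 0:
        raise ValidationError("n_hits must be >= 0")
    if not (0 <= mutation_rate <= 1 and 0 < fragment_coverage <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(target)
    frag_len = max(3, round(fragment_coverage * L))
    lo, hi = np.log10(EVALUE_RANGE[0]), np.log10(EVALUE_RANGE[1])
    evalues = 10.0 ** rng.uniform(lo, hi, size=n_hits)
    rates = np.full(n_hits, mutation_rate)
    if correlated and n_hits > 1:
        rates = np.sort(rng.uniform(0.0, min(1.0, 2 * mutation_rate), size=n_hits))
        evalues = np.sort(evalues)  # lowest E <-> lowest mutation rate

    hits = []
    aa = list(AMINO_ACIDS)
    for k in range(n_hits):
        start = int(rng.integers(0, L - frag_len + 1))
        frag_seq = list(target.seq[start:start + frag_len])
        n_mut = 0
        for i in range(frag_len):
            if rng.random() < rates[k]:
                choices = [c for c in aa if c != frag_seq[i]]
                frag_seq[i] = choices[int(rng.integers(0, len(choices)))]
                n_mut += 1
        frag_seq = "".join(frag_seq)
        coords = native.coords[start:start + frag_len] + \
            rng.normal(0.0, coord_sigma, size=(frag_len, 3))
        rot, trans = _random_rigid(rng)
        coords = (coords @ rot.T + trans).round(3)
        frag = CaTrace(np.arange(1, frag_len + 1), frag_seq, coords)

        hit_id = f"h{k:03d}"
        code = "".join(rng.choice(list("0123456789abcdefghijklmnopqrstuvwxyz"), size=4))
        aln_text = (f">{target.name}\n{target.seq}\n"
                    f">{hit_id}\n{'-' * start}{frag_seq}{'-' * (L - start - frag_len)}\n")
        identity = (frag_len - n_mut) / frag_len
        row = {
            "method": "blast" if k % 2 == 0 else "hhsearch",
            "hit_id": hit_id,
            "source": f"{code}_A",
            "evalue": f"{evalues[k]:.3e}",
            "identity": f"{identity:.4f}",
            "coverage": f"{frag_len / L:.4f}",
            "aln_file": f"{hit_id}.aln.fasta",
            "pdb_file": f"{hit_id}.pdb",
        }
        hits.append(BundleHit(row=row, aln_text=aln_text,
                              pdb_text=write_ca_trace(frag)))
    return Bundle(hits=tuple(hits))


@dataclass(frozen=True)
class DecoyRecord:
    trace: CaTrace
    sigma: float
    true_gdt: float


@dataclass(frozen=True)
class FixtureSet:
    """A complete synthetic study: target, native, graded decoys, bundle."""

    target: TargetSequence
    native: CaTrace
    decoys: tuple[DecoyRecord, ...]
    bundle: Bundle
    seed: int


def make_fixture_set(length: int = 75,
                     sigmas: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                     decoys_per_sigma: int = 5,
                     n_hits: int = 20,
                     mutation_rate: float = 0.1,
                     fragment_coverage: float = 0.6,
                     seed: int = 0) -> FixtureSet:
    """Target + native + graded decoy set + template bundle, with true GDT-TS.

    Defaults mirror the demonstration study: a 75-residue target, 30 decoys
    across noise levels sigma in {0, 0.5, 1, 2, 4, 8} A and a pool of 20
    near-native templates.
    """
    rng = np.random.default_rng(seed)
    target, native = make_native(length, int(rng.integers(2**31)))
    decoys = []
    idx = 0
    for sigma in sigmas:
        for _ in range(decoys_per_sigma):
            d = make_decoy(native, sigma, int(rng.integers(2**31)),
                           name=f"d{idx:02d}_s{sigma:g}")
            true = gdt_ts(d, native).gdt_ts
            decoys.append(DecoyRecord(d, sigma, true))
            idx += 1
    bundle = make_template_bundle(native, target, n_hits, mutation_rate,
                                  fragment_coverage, int(rng.integers(2**31)))
    return FixtureSet(target=target, native=native, decoys=tuple(decoys),
                      bundle=bundle, seed=seed)


def write_fixture_set(fs: FixtureSet, out_dir: str | Path) -> Path:
    """Write a fixture set to disk (FASTA, PDBs, bundle dir, ground-truth TSV)."""
    out = Path(out_dir)
    (out / "decoys").mkdir(parents=True, exist_ok=True)
    (out / "target.fasta").write_text(f">{fs.target.name}\n{fs.target.seq}\n")
    (out / "native.pdb").write_text(write_ca_trace(fs.native))
    rows = []
    for rec in fs.decoys:
        (out / "decoys" / f"{rec.trace.name}.pdb").write_text(write_ca_trace(rec.trace))
        rows.append({"decoy": rec.trace.name, "sigma": rec.sigma,
                     "true_gdt": round(rec.true_gdt, 6)})
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    fs.bundle.write(out / "bundle")
    return out


def load_bundle(fs_or_bundle, target: TargetSequence, tmp_dir: str | Path):
    """Write an in-memory bundle to ``tmp_dir`` and read it back as hits."""
    bundle = fs_or_bundle.bundle if isinstance(fs_or_bundle, FixtureSet) else fs_or_bundle
    path = bundle.write(tmp_dir)
    return read_hits_bundle(path, target)
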