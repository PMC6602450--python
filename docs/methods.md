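# Methods

## Scope and data model

Everything operates on C-alpha traces: ordered lists of residues, each with a
1-based *target position* (the residue's index in the target sequence), a
one-letter code and one CA coordinate in Å. Full-atom PDB input is reduced to
CA on read because none of the scores use other atoms. Residue
correspondence between a decoy and the target — and between two decoys — is
by residue number interpreted as target position (the convention of
CASP-style model files); no structural re-alignment is attempted. Decoy
residues whose letter disagrees with the target at that position are dropped
with a warning. Insertion codes are rejected; alternate locations other than
blank/`A` are ignored; only the first `MODEL` of a multi-model file is read.

## GDT-TS engine

For corresponded CA pairs, the score averages over cutoffs c ∈ {1, 2, 4, 8} Å
the maximal fraction of pairs that a single rigid superposition brings within
c. The exact maximum is combinatorial, so a deterministic seed-and-extend
search approximates it:

1. **Seeds**: every contiguous correspondence window of lengths 3, 5, 7 and
   the full correspondence. For instances of ≤ 14 pairs, additionally every
   3-subset of pairs, widened to every 4- and 5-subset — contiguous windows
   cannot reach isolated triples, and at that size dense seeding is cheap.
   Collinear seeds (degenerate rotation) are skipped.
2. **Extension**: per cutoff, alternate (i) Kabsch fit on the included set,
   (ii) re-include all pairs within the cutoff, until the set is stable or
   20 iterations.
3. **Scoring**: *every* evaluated superposition is credited to all four
   cutoffs, which makes the per-cutoff maxima monotone in the cutoff by
   construction. A final cross-seeding round re-extends each cutoff from the
   other cutoffs' best inclusion sets.

Every reported count is measured under a superposition fitted on ≥ 3
included pairs, so the heuristic can never exceed the exhaustive-subset
optimum; `gdt_oracle` (all subsets of 3..n pairs, guarded to n ≤ 12)
provides that optimum for audit. On noisy-copy instances of 8–12 residues
the observed gap stays below 0.05 (see `tests/test_acceptance.py`); on
unrelated random point clouds — not the score's domain — the heuristic can
trail further, as any local search must.

Per-cutoff fractions are normalized by the number of corresponded pairs, not
by target length: a short perfect fragment reports perfect agreement for the
region it covers, and coverage is accounted for separately by the weights
(below).

**Numerics.** The public `kabsch_superpose` uses the SVD route with the
determinant correction (proper rotation, det +1). The inner search uses the
equivalent quaternion formulation: the optimal rotation is the dominant
eigenvector of a 4×4 key matrix, obtained by Newton iteration on its
characteristic polynomial from the upper bound (G_a + G_b)/2, with the
eigenvector read off the adjugate; a shifted power iteration covers
(near-)degenerate spectra, where any maximizing rotation is acceptable. The
two routes agree to ~1e-8 in RMSD and are cross-checked in the tests.
Everything is straight-line deterministic: no randomness, no dependence on
iteration order.

## Template ranking

T = (3 − log₁₀ E) · I · C with E clamped below by 1e-180 (search engines
report underflowed E-values as 0; the clamp keeps T finite and the order
intact). Identity and coverage are stored as fractions in [0, 1]; identity
is recomputed from the alignment as matching columns over aligned columns,
coverage as aligned target positions over target length, capped at 1 —
"template length over target length" would reward unaligned overhang.
Stated and recomputed values must agree within 0.01 or the bundle is
rejected. Ranking sorts by (T desc, E asc, hit id asc), making selection
deterministic under input permutation. The two per-method top-10 lists are
concatenated without deduplication: repeated hits to the same protein carry
independent alignments and fragments.

## Per-residue and global quality

The BLOSUM62 weight is W = (s − s_min)/(s_max − s_min) with s_min = −4,
s_max = 11, clipped to [0, 1]; pairs involving `X` weigh 0. Min–max rescaling
was chosen because a bounded weighted mean needs non-negative weights and
because it preserves the full dynamic range of the matrix; `max(0, s)/11`
("relu") is exposed as an alternative that zeroes all unfavourable
substitutions. The choice affects the weighting, not the [0, 1] bounds.

H_j is the W-weighted mean of the template GDT-TS values S_k at position j.
Positions with no positive weight (no aligned template, or only `X`
columns) score 0 and are flagged uncovered, and the global score is the
plain mean of H over *all* target positions — unsupported regions penalize
the model rather than being ignored. Templates sharing fewer than 3 aligned
positions with the decoy are dropped (superposition undefined) with a
warning.

Weighted-mean consequences worth stating: H is invariant under uniform
scaling of all weights and under duplicating the whole pool, and is monotone
in each S_k; duplicating a *single* hit re-weights it and does change H
unless that template's S already equals H.

## Consensus

References are the n_ref decoys with the highest template-based global
scores (ties broken by name); n_ref defaults to max(5, ⌈0.2 · pool size⌉).
A decoy's score is Σ_r w_r · GDT(decoy, r) / Σ_r w_r with w_r the
reference's global score — the only scalar reduction of the per-position
profile consistent with a weighted average of scalar pairwise GDT values. A
per-position variant (pairwise per-residue agreement weighted by the
reference's local score H_rj) is implemented behind `position_weighted=True`
for experimentation. A decoy is excluded from its own reference set by
default so top models are not trivially inflated (configurable); if a decoy
is the sole reference, its own global score is returned, and an all-zero
weight vector falls back to the unweighted mean with a warning. Output is
sorted by consensus score, descending.

## Synthetic studies

The generator emulates the three real inputs with known ground truth:

- **Native**: CA trace on an idealized helix (rise 1.5 Å, 100°/residue,
  radius ≈ 2.28 Å solving an exact 3.8 Å consecutive CA spacing) with a
  uniformly random 20-letter sequence. The helix guarantees protein-like
  spacing and non-degenerate geometry without clash checking.
- **Decoys**: native + isotropic Gaussian noise (σ per axis) + a uniform
  random rigid motion, so superposition is always exercised; σ = 0 yields an
  exact rigid copy with true GDT-TS 1. The default study uses a 75-residue
  target and 30 decoys, five at each σ ∈ {0, 0.5, 1, 2, 4, 8} Å — spanning
  true GDT-TS from 1.0 down to ≈ 0.1.
- **Templates**: 20 contiguous native fragments (default coverage 0.6 of the
  target, start positions uniform) with sequences point-mutated at rate 0.1,
  coordinates perturbed at σ = 0.3 Å plus a rigid motion, and log-uniform
  synthetic E-values in [1e-50, 1]. E-values are uncorrelated with fragment
  quality by default (they only drive ranking); `correlated=True` links low
  E to low mutation rate for ranking experiments. Mutation rate 0.1 and
  coverage 0.6 keep the pool "near-native but imperfect": informative
  weights, near-full coverage of internal positions, occasional uncovered
  chain ends.

All generators are integer-seeded and byte-identical across runs;
coordinates are rounded to the PDB's three decimals at generation time so a
write/read cycle is the identity.

**What passing the synthetic study does and does not show.** Decoy errors
are isotropic and uniform along the chain, templates are fragments of the
true native, and alignments are exact by construction. Real decoys have
structured, locally correlated errors; real templates are homologs with
their own folds and alignment errors; real identity/coverage correlate with
E-value. Recovery of the noise ordering and high rank correlation with true
GDT-TS on these fixtures therefore validates the scoring machinery — the
search, the weighting, the aggregation — not the method's benchmark
performance on real prediction archives, which additionally depends on
search databases and decoy populations outside this package's scope.

## Problem sizes and defaults

The bundled study scale — 75 residues, 30 decoys, 20 templates, and 100
regenerated studies for the consensus-vs-single-model comparison — keeps the
full test suite in the minutes range on a single core while leaving every
claimed property at its stated sample size. The GDT oracle guard (≤ 12
pairs) bounds its 2^n subset enumeration. Scores are printed to 3 decimals
in [0, 1]; the `gdtts` command offers a ×100 display.

## Known limitations

- Sequence-dependent, numbering-based correspondence only; no structural
  alignment, so mis-numbered decoys lose residues rather than being rescued.
- The GDT search is a heuristic; its oracle-audited guarantee covers small
  instances, and like all LGA-style searches it can undershoot the true
  optimum on adversarial geometry.
- mmCIF, side chains, multi-chain targets and live Blast/HHsearch execution
  are out of scope; an HHR-to-bundle converter is a natural extension point.
- The BLOSUM weight transform and the handling of uncovered positions are
  stated design choices (config-exposed), not values fitted to data.
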