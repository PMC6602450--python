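# gdtqa

Quality assessment of predicted protein 3D structures ("decoys") from
C-alpha geometry: a template-based quasi-single-model score, an optional
consensus score over a pool of predictions, and the GDT-TS engine both are
built on. Intended for structure-prediction practitioners who need a
per-model quality estimate — globally and per residue — before a native
structure exists, and for pipeline authors who want those scores as a
library call rather than a web service.

## The method

**GDT-TS.** The similarity of two structures sharing residue numbering is

> GDT-TS = ¼ · Σ_{c ∈ {1,2,4,8 Å}} max_R ( #{CA pairs within c under rigid motion R} / #pairs )

computed by a deterministic seed-and-extend search over superpositions
(Kabsch fits on contiguous windows, iteratively re-extended; exhaustively
dense seeding on tiny instances). Scores are fractions in [0, 1]. An
exhaustive-subset oracle (`gdt_oracle`, ≤ 12 pairs) bounds and audits the
heuristic.

**Template score (quasi-single-model).** Given a target sequence of length
L and homolog hits from sequence searches (Blast, HHsearch), hits are ranked
by the heuristic

> T = (3 − log₁₀ E) · I · C

(E-value, fractional identity, target coverage; the first factor stays
positive for every E < 1000). The top 10 per method are merged — duplicates
kept — into a pool of ≤ 20 template fragments. For decoy D:

- W_kj ∈ [0, 1]: BLOSUM62 similarity (min–max rescaled) of template k's
  residue aligned to target position j; 0 where unaligned,
- S_k ∈ [0, 1]: GDT-TS of D against fragment k over their shared positions,
- local score H_j = Σ_k W_kj S_k / Σ_k W_kj (0 where no template covers j),
- global score = mean of H_j over **all** L positions.

**Consensus.** With a pool of decoys, each decoy is scored by the weighted
mean of its pairwise GDT-TS against the top-n reference decoys, weighted by
each reference's template-based global score — better models contribute
more. With equal weights this reduces to the classic mean-pairwise-GDT
consensus.

Because live database searches are environment-bound, hits enter as a
*template bundle* directory (`hits.tsv` + per-hit pairwise alignment FASTA +
fragment PDB); the seeded generator in `gdtqa.synth` produces complete
synthetic studies (target, native, graded-noise decoys, bundle) with known
true GDT-TS.

## Worked example

```bash
python examples/03_single_model_qa.py
```

builds a 75-residue synthetic target with 20 near-native template fragments
and scores a rigid copy of the native and a 6 Å-perturbed decoy:

```
good_model  global 0.973   covered 73/75 positions   weakest residue 1 (H=0.000)
bad_model   global 0.196   covered 73/75 positions   weakest residue 1 (H=0.000)
```

The copy scores near 1 because every template fragment superposes onto it
within the GDT cutoffs; the noisy decoy's fragments do not, and the global
score collapses. Two chain-end positions are uncovered by any fragment and
contribute 0 — the global score is the mean over *all* positions, so
unsupported regions count against the model. `examples/04_consensus_pool.py`
continues with a 15-decoy pool (Spearman vs. true GDT-TS: single-model
0.993, consensus 0.997); `01_gdt_score.py` and `02_template_ranking.py` show
the GDT engine and T-score ranking in isolation.

The same workflow is available from a shell:

```bash
gdtqa fixtures --length 75 --seed 1 --out demo
gdtqa score demo/target.fasta demo/decoys/d00_s0.pdb demo/bundle --out out
gdtqa score-pool demo/target.fasta demo/decoys demo/bundle --out out_pool
gdtqa gdtts demo/decoys/d05_s1.pdb demo/native.pdb
```

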