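"""Template-based quality assessment of a single predicted model.

Generates a synthetic 75-residue target with a pool of 20 near-native
template fragments, then scores two decoys: a rigid copy of the native and a
heavily perturbed one.  The local profile H_j estimates per-residue quality;
its mean over all positions is the predicted global GDT-TS.
"""

import tempfile

from gdtqa.qascore import run_qas
from gdtqa.synth import make_decoy, make_fixture_set
from gdtqa.templates import build_pool, read_hits_bundle

fs = make_fixture_set(length=75, seed=42)
with tempfile.TemporaryDirectory() as tmp:
    hits = read_hits_bundle(fs.bundle.write(tmp), fs.target)
pool = build_pool(hits, fs.target)

good = make_decoy(fs.native, sigma=0.0, seed=1, name="good_model")
bad = make_decoy(fs.native, sigma=6.0, seed=2, name="bad_model")

for decoy in (good, bad):
    res = run_qas(fs.target, decoy, pool)
    worst = int(res.local.argmin()) + 1
    print(f"{decoy.name:<11} global {res.global_score:.3f}   "
          f"covered {int(res.covered.sum())}/{len(fs.target)} positions   "
          f"weakest residue {worst} (H={res.local.min():.3f})")

print("\nThe rigid copy scores near 1 because every template fragment agrees "
      "with it; 6 A noise destroys the agreement and the score collapses.")
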