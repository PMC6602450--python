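"""Ranking homolog hits with the T-score and assembling the template pool.

The heuristic T = (3 - log10 E) * I * C trades off search significance (E),
sequence identity (I) and target coverage (C).  The top 10 hits per search
method are merged, duplicates included, into the pool that drives scoring.
"""

from gdtqa.structio import TargetSequence
from gdtqa.templates import TemplateHit, build_pool, t_score

target = TargetSequence("MKVLAEGDWTRFIHNPQSYCMKVLAEGDWT", name="demo")

hits = [
    TemplateHit("blast", "b1", "1abc_A", evalue=1e-30, identity=0.92, coverage=0.95),
    TemplateHit("blast", "b2", "2def_B", evalue=1e-8, identity=0.55, coverage=0.80),
    TemplateHit("blast", "b3", "1abc_A", evalue=1e-3, identity=0.35, coverage=0.60),
    TemplateHit("hhsearch", "q1", "3ghi_A", evalue=1e-22, identity=0.78, coverage=0.90),
    TemplateHit("hhsearch", "q2", "4jkl_C", evalue=5.0, identity=0.22, coverage=0.40),
]

print("hit      method     E-value   I     C     T-score")
for h in sorted(hits, key=lambda h: -h.tscore):
    print(f"{h.hit_id:<8} {h.method:<9} {h.evalue:9.1e}  {h.identity:.2f}  "
          f"{h.coverage:.2f}  {h.tscore:6.3f}")

pool = build_pool(hits, target)
print(f"\npool size: {len(pool)} (top 10 per method, duplicates kept: "
      f"{sum(h.source == '1abc_A' for h in pool.hits)} hits share 1abc_A)")
print("sanity: T =", round(t_score(1e-3, 1.0, 1.0), 3),
      "for E=1e-3, I=C=1  (the (3 - log10 E) factor alone)")
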