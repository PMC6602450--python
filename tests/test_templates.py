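import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdtqa.errors import FormatError, InputError, ValidationError
from gdtqa.structio import TargetSequence
from gdtqa.synth import make_native, make_template_bundle
from gdtqa.templates import (
    EVALUE_MIN, TemplateHit, build_pool, merge_pools, rank_select_topk,
    read_blast_tabular, read_hits_bundle, t_score,
)


def hit(method="blast", hit_id="h", evalue=1e-5, identity=0.5, coverage=0.5):
    return TemplateHit(method=method, hit_id=hit_id, source="0xyz_A",
                       evalue=evalue, identity=identity, coverage=coverage)


class TestTScore:
    @pytest.mark.parametrize("e,i,c,expected", [
        (1e-3, 1.0, 1.0, 6.0),
        (1000.0, 0.5, 0.8, 0.0),
        (1e-10, 0.4, 0.5, 2.6),
    ])
    def test_direct_substitution(self, e, i, c, expected):
        assert t_score(e, i, c) == pytest.approx(expected, abs=1e-12)

    def test_zero_evalue_clamped_finite(self):
        t = t_score(0.0, 1.0, 1.0)
        assert math.isfinite(t)
        assert t == pytest.approx(3.0 - math.log10(EVALUE_MIN))

    def test_negative_inputs_rejected(self):
        for bad in [(-1.0, 0.5, 0.5), (1.0, -0.1, 0.5), (1.0, 0.5, -0.1)]:
            with pytest.raises(ValidationError):
                t_score(*bad)

    def test_monotonicity_over_grid(self):
        evs = np.logspace(-50, 2.9, 25)
        vals = [t_score(e, 0.7, 0.7) for e in evs]
        assert all(a > b for a, b in zip(vals, vals[1:]))  # decreasing in E
        ids = np.linspace(0.01, 1.0, 20)
        vals = [t_score(1e-5, i, 0.7) for i in ids]
        assert all(a < b for a, b in zip(vals, vals[1:]))  # increasing in I
        vals = [t_score(1e-5, 0.7, c) for c in ids]
        assert all(a < b for a, b in zip(vals, vals[1:]))  # increasing in C

    def test_positive_below_1000(self):
        for e in np.logspace(-180, np.log10(999.9), 40):
            assert t_score(e, 0.01, 0.01) > 0


class TestRanking:
    def test_topk_by_tscore(self):
        hits = [hit(hit_id=f"h{i}", evalue=10.0 ** -i) for i in range(15)]
        top = rank_select_topk(hits, k=10)
        assert [h.hit_id for h in top] == [f"h{i}" for i in range(14, 4, -1)]

    def test_fewer_than_k(self):
        hits = [hit(hit_id=f"h{i}") for i in range(4)]
        assert len(rank_select_topk(hits, k=10)) == 4

    def test_tie_break_lower_evalue_first(self):
        # equal T via compensating identity: (3+5)*0.5 == (3+10)*0.25 == 4 * C
        a = hit(hit_id="a", evalue=1e-5, identity=0.5, coverage=1.0)
        b = hit(hit_id="b", evalue=1e-10, identity=8 / 13 / 2, coverage=1.0)
        assert a.tscore == pytest.approx(b.tscore)
        assert [h.hit_id for h in rank_select_topk([a, b], 2)] == ["b", "a"]

    @settings(deadline=None, derandomize=True)
    @given(st.permutations(range(12)))
    def test_permutation_invariant(self, perm):
        hits = [hit(hit_id=f"h{i}", evalue=float(i % 4 + 1), identity=(i % 3 + 1) / 3)
                for i in range(12)]
        base = [h.hit_id for h in rank_select_topk(hits, 5)]
        shuffled = [hits[i] for i in perm]
        assert [h.hit_id for h in rank_select_topk(shuffled, 5)] == base


class TestMerge:
    def test_ten_plus_ten(self):
        target = TargetSequence("M" * 20)
        pool = merge_pools([hit(hit_id=f"b{i}") for i in range(10)],
                           [hit(method="hhsearch", hit_id=f"q{i}") for i in range(10)],
                           target)
        assert len(pool) == 20

    def test_duplicates_kept(self):
        target = TargetSequence("M" * 20)
        blast = [hit(hit_id=f"b{i}") for i in range(10)]
        hh = [hit(method="hhsearch", hit_id=f"b{i}") for i in range(10)]  # same ids
        assert len(merge_pools(blast, hh, target)) == 20

    def test_short_lists(self):
        target = TargetSequence("M" * 20)
        pool = merge_pools([hit(hit_id=f"b{i}") for i in range(7)],
                           [hit(method="hhsearch", hit_id=f"q{i}") for i in range(10)],
                           target)
        assert len(pool) == 17

    def test_method_provenance_and_order(self):
        target = TargetSequence("M" * 20)
        pool = merge_pools([hit(hit_id="b0")], [hit(method="hhsearch", hit_id="q0")], target)
        assert [h.method for h in pool.hits] == ["blast", "hhsearch"]

    def test_oversized_lists_rejected(self):
        target = TargetSequence("M" * 20)
        with pytest.raises(ValidationError):
            merge_pools([hit(hit_id=f"b{i}") for i in range(11)], [], target)


class TestBundle:
    def test_round_trip_satisfies_invariants(self, tmp_path):
        target, native = make_native(30, seed=5)
        bundle = make_template_bundle(native, target, n_hits=4, seed=9)
        path = bundle.write(tmp_path / "b")
        hits = read_hits_bundle(path, target)
        assert len(hits) == 4
        for h in hits:
            h.validate_against(target)
            assert 0 <= h.identity <= 1
            assert 0 <= h.coverage <= 1
            assert h.tscore == pytest.approx(t_score(h.evalue, h.identity, h.coverage))

    def test_stated_identity_mismatch_rejected(self, tmp_path):
        target, native = make_native(30, seed=5)
        bundle = make_template_bundle(native, target, n_hits=2, seed=9)
        path = bundle.write(tmp_path / "b")
        table = (path / "hits.tsv").read_text().splitlines()
        cols = table[1].split("\t")
        cols[4] = f"{float(cols[4]) - 0.5:.4f}"  # corrupt identity by 0.5
        (path / "hits.tsv").write_text("\n".join([table[0], "\t".join(cols)] + table[2:]) + "\n")
        with pytest.raises(ValidationError, match="identity"):
            read_hits_bundle(path, target)

    def test_empty_bundle_warns(self, tmp_path):
        target, native = make_native(30, seed=5)
        path = make_template_bundle(native, target, n_hits=0, seed=1).write(tmp_path / "b")
        with pytest.warns(UserWarning, match="no hits"):
            assert read_hits_bundle(path, target) == []

    def test_missing_bundle_dir(self, tmp_path):
        with pytest.raises(InputError, match="bundle not found"):
            read_hits_bundle(tmp_path / "nope")

    def test_build_pool_caps_per_method(self, tmp_path):
        target, native = make_native(40, seed=2)
        bundle = make_template_bundle(native, target, n_hits=30, seed=2)
        hits = read_hits_bundle(bundle.write(tmp_path / "b"), target)
        pool = build_pool(hits, target)
        assert len(pool) == 20
        assert sum(h.method == "blast" for h in pool.hits) == 10


class TestBlastTabular:
    LINE = "q\tsubj\t85.0\t50\t5\t0\t1\t50\t11\t60\t1e-20\t200.0"

    def test_identity_percent_to_fraction(self):
        hits = read_blast_tabular(self.LINE, target_length=100)
        assert hits[0].identity == pytest.approx(0.85)

    def test_coverage_from_target_span(self):
        hits = read_blast_tabular(self.LINE, target_length=100)
        assert hits[0].coverage == pytest.approx(0.5)
        assert hits[0].alignment is not None
        assert hits[0].alignment[0].target_position == 1
        assert hits[0].alignment[-1].template_position == 60

    def test_gapped_hit_is_alignment_pending(self):
        gapped = "q\tsubj\t85.0\t52\t5\t2\t1\t50\t11\t62\t1e-20\t200.0"
        assert read_blast_tabular(gapped, target_length=100)[0].alignment is None

    def test_wrong_column_count_rejected(self):
        with pytest.raises(FormatError, match="12"):
            read_blast_tabular("a\tb\tc", target_length=100)
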