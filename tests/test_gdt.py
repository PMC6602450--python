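import numpy as np
import pytest

from gdtqa.errors import ValidationError
from gdtqa.gdt import (
    CUTOFFS, Correspondence, common_positions, gdt_oracle, gdt_ts,
    kabsch_superpose,
)
from gdtqa.structio import CaTrace

from conftest import random_trace, rigid_copy


def full_corr(n):
    return Correspondence(np.arange(n), np.arange(n))


def block_toy():
    """8 pairs: 4 agree exactly, 4 are displaced 100 A as a rigid block."""
    rng = np.random.default_rng(42)
    a = rng.normal(size=(8, 3)) * 3
    b = a.copy()
    b[4:] += np.array([100.0, 0.0, 0.0])
    return (CaTrace(np.arange(1, 9), "A" * 8, a),
            CaTrace(np.arange(1, 9), "A" * 8, b))


class TestKabsch:
    def test_identical_inputs(self):
        a = np.random.default_rng(0).normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)

    def test_exact_rigid_motion_recovered(self):
        a = np.random.default_rng(1).normal(size=(7, 3)) * 5
        c, s = np.cos(np.pi / 2), np.sin(np.pi / 2)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        b = a @ rz.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_always(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rot, _, _ = kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_rigid_transforms(self):
        """Optimality lower bound: no random rigid motion does better."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3)) * 4
        b = rng.normal(size=(6, 3)) * 4
        _, _, rmsd = kabsch_superpose(a, b)
        mu_a, mu_b = a.mean(0), b.mean(0)
        for _ in range(1000):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            trial = np.sqrt(np.mean(np.sum(((a - mu_a) @ rot.T + mu_b - b) ** 2, axis=1)))
            assert rmsd <= trial + 1e-12

    def test_length_mismatch_and_too_few_points(self):
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestGdtTs:
    def test_identical_structures_score_one(self):
        t = random_trace(0, n=10)
        res = gdt_ts(t, t, full_corr(10))
        assert res.gdt_ts == 1.0
        assert all(res.per_cutoff[c] == 1.0 for c in CUTOFFS)

    def test_rigid_copy_scores_one(self):
        t = random_trace(1, n=12)
        assert gdt_ts(t, rigid_copy(t, seed=5), full_corr(12)).gdt_ts == 1.0

    def test_block_displacement_half(self):
        a, b = block_toy()
        assert gdt_ts(a, b).gdt_ts == 0.5
        assert gdt_oracle(a, b).gdt_ts == 0.5

    def test_rigid_motion_invariance(self):
        a, b = random_trace(2, n=10), random_trace(3, n=10)
        base = gdt_ts(a, b).gdt_ts
        assert gdt_ts(rigid_copy(a, 7), b).gdt_ts == pytest.approx(base, abs=1e-6)
        assert gdt_ts(a, rigid_copy(b, 8)).gdt_ts == pytest.approx(base, abs=1e-6)

    def test_symmetric_in_arguments(self):
        for seed in range(5):
            a = random_trace(seed, n=9)
            b = CaTrace(a.positions, a.seq,
                        a.coords + np.random.default_rng(seed + 50).normal(0, 2, (9, 3)))
            assert gdt_ts(a, b).gdt_ts == pytest.approx(gdt_ts(b, a).gdt_ts, abs=1e-9)

    def test_per_cutoff_monotone_and_flags(self):
        a = random_trace(4, n=10)
        b = CaTrace(a.positions, a.seq,
                    a.coords + np.random.default_rng(77).normal(0, 2.5, (10, 3)))
        res = gdt_ts(a, b)
        fr = [res.per_cutoff[c] for c in CUTOFFS]
        assert fr == sorted(fr)
        assert res.per_pair_flags.min() >= 0 and res.per_pair_flags.max() <= 4
        # total score is the mean pair flag fraction
        assert res.gdt_ts == pytest.approx(res.per_pair_flags.mean() / len(CUTOFFS))

    def test_default_correspondence_is_common_positions(self):
        a = random_trace(5, n=10)
        b = CaTrace(a.positions[2:], a.seq[2:], a.coords[2:], "part")
        corr = common_positions(a, b)
        assert len(corr) == 8
        assert gdt_ts(a, b).gdt_ts == gdt_ts(a, b, corr).gdt_ts

    def test_too_few_pairs_rejected(self):
        t = random_trace(6, n=5)
        with pytest.raises(ValidationError, match=">= 3"):
            gdt_ts(t, t, Correspondence(np.array([0, 1]), np.array([0, 1])))


class TestOracle:
    def test_identical_scores_one(self):
        t = random_trace(8, n=8)
        assert gdt_oracle(t, t).gdt_ts == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_heuristic_never_exceeds_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = CaTrace(np.arange(1, 9), "A" * 8, rng.normal(size=(8, 3)) * 4)
        b = CaTrace(np.arange(1, 9), "A" * 8, rng.normal(size=(8, 3)) * 4)
        h, o = gdt_ts(a, b), gdt_oracle(a, b)
        assert h.gdt_ts <= o.gdt_ts + 1e-12
        for c in CUTOFFS:
            assert h.per_cutoff[c] <= o.per_cutoff[c] + 1e-12

    def test_large_instances_refused(self):
        t = random_trace(9, n=13)
        with pytest.raises(ValidationError, match="oracle"):
            gdt_oracle(t, t)


class TestCorrespondence:
    def test_indices_must_increase(self):
        with pytest.raises(ValidationError):
            Correspondence(np.array([0, 0]), np.array([0, 1]))
        with pytest.raises(ValidationError):
            Correspondence(np.array([0, 1]), np.array([1, 0]))

    def test_from_pairs(self):
        c = Correspondence.from_pairs([(0, 2), (1, 3), (4, 5)])
        assert list(c.idx_a) == [0, 1, 4]
        assert list(c.idx_b) == [2, 3, 5]

    def test_disjoint_positions_error(self):
        a = CaTrace(np.array([1, 2, 3]), "AAA", np.eye(3))
        b = CaTrace(np.array([7, 8, 9]), "AAA", np.eye(3))
        with pytest.raises(ValidationError, match="common"):
            common_positions(a, b)
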