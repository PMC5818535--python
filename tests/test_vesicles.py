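"""Vesicle cluster classification and condition comparison."""

import numpy as np
import pytest

from synucalc import simulate
from synucalc.errors import InputError
from synucalc.smlm import Rect
from synucalc.vesicles import SpotTable, classify_clusters, compare_conditions

FIELD = Rect(-1000.0, -1000.0, 20000.0, 20000.0)


def _spots(points):
    return SpotTable(points=np.asarray(points, dtype=float), field=FIELD)


class TestClassify:
    def test_all_far_apart_all_singles(self):
        d = classify_clusters(_spots([[0, 0], [1000, 0], [0, 1000], [5000, 5000]]))
        assert d.pct_singles == 100.0
        assert d.n_components == 4

    def test_mixed_singles_and_pair(self):
        d = classify_clusters(_spots([[0, 0], [100, 0], [5000, 5000], [9000, 1000]]))
        assert d.pct_singles == 50.0
        assert d.pct_pairs == 50.0
        assert d.pct_multi == 0.0

    def test_chain_is_one_cluster_of_three(self):
        # A-B and B-C within 250 nm, A-C beyond: transitive linkage
        d = classify_clusters(_spots([[0, 0], [240, 0], [480, 0]]))
        assert d.pct_multi == 100.0
        assert d.n_components == 1

    def test_duplicates_merged(self):
        with pytest.warns(UserWarning, match="merged"):
            d = classify_clusters(_spots([[0, 0], [0.5, 0], [5000, 5000]]))
        assert d.n_vesicles == 2
        assert d.pct_singles == 100.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            classify_clusters(_spots(np.empty((0, 2))))

    def test_percentages_sum_to_100(self, rng):
        pts = rng.uniform(0, 19000, (120, 2))
        d = classify_clusters(SpotTable(points=pts, field=FIELD))
        assert d.pct_singles + d.pct_pairs + d.pct_multi == pytest.approx(100.0)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(2000, 15000, (80, 2))
        d0 = classify_clusters(SpotTable(points=pts, field=FIELD))
        th = 0.5
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts2 = pts @ rot.T + np.array([500.0, -300.0])
        big = Rect(
            pts2[:, 0].min() - 1, pts2[:, 1].min() - 1,
            pts2[:, 0].max() + 1, pts2[:, 1].max() + 1,
        )
        d1 = classify_clusters(SpotTable(points=pts2, field=big))
        assert (d0.pct_singles, d0.pct_pairs, d0.pct_multi) == (
            d1.pct_singles, d1.pct_pairs, d1.pct_multi,
        )

    def test_radius_monotonicity(self, rng):
        pts = rng.uniform(0, 10000, (150, 2))
        table = SpotTable(points=pts, field=FIELD)
        singles = [
            classify_clusters(table, radius=r).pct_singles
            for r in (100.0, 250.0, 500.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(singles, singles[1:]))


class TestGeneratorRecovery:
    def test_single_fraction_recovered(self):
        # realised fractions are exact by construction; the classifier must
        # reproduce them on every seeded field
        fracs = []
        truths = []
        for seed in range(1, 21):
            spots, truth = simulate.generate_vesicle_field(seed=seed, preset="egta")
            fracs.append(classify_clusters(spots).pct_singles)
            truths.append(100.0 * truth["fractions_realized"][0])
        fracs, truths = np.array(fracs), np.array(truths)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs)) + 1e-9
        assert abs(fracs.mean() - truths.mean()) <= max(2 * se, 0.5)

    def test_pure_singles_field(self):
        spots, _ = simulate.generate_vesicle_field(
            seed=3, preset=None, fractions=(1.0, 0.0, 0.0), n_vesicles=100
        )
        assert classify_clusters(spots).pct_singles == 100.0

    def test_pair_members_within_radius(self):
        spots, truth = simulate.generate_vesicle_field(seed=5, preset="calcium")
        d = classify_clusters(spots)
        assert d.pct_pairs == pytest.approx(100.0 * truth["fractions_realized"][1])

    def test_infeasible_density_raises(self):
        with pytest.raises(InputError, match="larger field|packing"):
            simulate.generate_vesicle_field(
                seed=1, preset="egta", n_vesicles=3000, field_um=3.0,
                max_attempts=20000,
            )


class TestCompareConditions:
    def _dists(self, presets, n_fields=6, seed0=100):
        out = {}
        for j, preset in enumerate(presets):
            reps = []
            for i in range(n_fields):
                spots, _ = simulate.generate_vesicle_field(
                    seed=seed0 + 37 * j + i, preset=preset,
                    n_vesicles=140 + 7 * i, field_um=15.0,
                )
                reps.append(classify_clusters(spots))
            out[preset] = reps
        return out

    def test_identical_replicates_degenerate(self):
        spots, _ = simulate.generate_vesicle_field(seed=9, preset="egta", n_vesicles=100)
        d = classify_clusters(spots)
        res = compare_conditions({"a": [d, d], "b": [d, d]})
        for cat in ("singles", "pairs", "multi"):
            assert res[cat]["degenerate"]
            assert all(p["p_adj"] == 1.0 for p in res[cat]["pairwise"])

    def test_egta_vs_asyn_ca_significant_singles(self):
        dists = self._dists(["egta", "asyn_ca"], n_fields=18)
        res = compare_conditions(dists)
        pair = res["singles"]["pairwise"][0]
        assert pair["p_adj"] < 0.05

    def test_label_swap_flips_sign(self):
        dists = self._dists(["egta", "calcium"])
        res = compare_conditions(dists)
        swapped = compare_conditions(
            {"calcium": dists["calcium"], "egta": dists["egta"]}
        )
        d1 = res["singles"]["pairwise"][0]["mean_diff"]
        d2 = swapped["singles"]["pairwise"][0]["mean_diff"]
        assert d1 == pytest.approx(-d2 if d1 != 0 else 0.0, abs=1e-9) or abs(d1) == abs(d2)

    def test_single_replicate_rejected(self):
        spots, _ = simulate.generate_vesicle_field(seed=9, preset="egta", n_vesicles=100)
        d = classify_clusters(spots)
        with pytest.raises(InputError, match="lonely|replicate|fewer"):
            compare_conditions({"a": [d], "b": [d, d]})
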