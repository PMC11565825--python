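"""The moderator statistic: MI estimator, stratification, dMI, resampling null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abtau_modnet.containers import Abundance, Embedding
from abtau_modnet.mindy import (
    DEFAULT_B,
    DEFAULT_FRACTION,
    DEFAULT_Q,
    candidate_moderators,
    default_bins,
    delta_mi,
    mi_from_joint,
    mutual_information,
    resample_pvalue,
    score_moderators,
    stratify,
    StratifiedSamples,
)
from abtau_modnet.synthio import SynthConfig, gen_abundance


def make_abundance(values: dict, samples=None) -> Abundance:
    df = pd.DataFrame(values)
    df.index = samples or [f"S{i:02d}" for i in range(len(df))]
    meta = pd.DataFrame({"diagnosis": ["MCI"] * len(df), "mmse": [25] * len(df)},
                        index=df.index)
    return Abundance(values=df, meta=meta)


def test_printed_defaults():
    assert DEFAULT_Q == 0.05 and DEFAULT_FRACTION == 0.35 and DEFAULT_B == 1000


class TestCandidateModerators:
    def test_node_coincident_with_anchors_always_selected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(40, 3)),
                             index=[f"N{i:02d}" for i in range(40)])
        feats.loc["N01"] = feats.loc["N00"]  # MAPT == APP position
        feats.loc["N02"] = feats.loc["N00"]  # candidate at distance 0 from both
        emb = Embedding(features=feats, zscored=True)
        cands = candidate_moderators(emb, ("N00", "N01"), q=0.05)
        assert cands[0] == "N02"

    def test_matches_brute_force_oracle(self, rng):
        names = [f"N{i:03d}" for i in range(100)]
        feats = pd.DataFrame(rng.normal(size=(100, 4)), index=names)
        emb = Embedding(features=feats, zscored=True)
        anchors = ("N000", "N001")
        got = candidate_moderators(emb, anchors, q=0.1)
        m = int(np.ceil(0.1 * 99))
        sets = []
        dist = {}
        for a in anchors:
            d = {n: np.linalg.norm(feats.loc[n] - feats.loc[a]) for n in names
                 if n not in anchors}
            dist[a] = d
            sets.append(set(sorted(d, key=lambda n: (d[n], n))[:m]))
        expected = sorted(sets[0] & sets[1],
                          key=lambda n: (dist[anchors[0]][n] + dist[anchors[1]][n], n))
        assert got == expected

    def test_missing_anchor_named_in_error(self, random_embedding):
        with pytest.raises(KeyError, match="XX"):
            candidate_moderators(random_embedding, ("N000", "XX"), q=0.1)


class TestStratify:
    def test_floor_rule_sizes(self, rng):
        ab = make_abundance({"M": rng.normal(size=20)})
        s = stratify(ab, "M", 0.35)
        assert len(s.top_ids) == len(s.bottom_ids) == 7
        assert not set(s.top_ids) & set(s.bottom_ids)

    def test_extremes_assigned_correctly(self):
        vals = list(range(10))
        ab = make_abundance({"M": vals})
        s = stratify(ab, "M", 0.3)
        assert set(s.top_ids) == {"S07", "S08", "S09"}
        assert set(s.bottom_ids) == {"S00", "S01", "S02"}

    def test_constant_modulator_name_ordered_with_warning(self):
        ab = make_abundance({"M": [1.0] * 10})
        with pytest.warns(UserWarning, match="constant"):
            s = stratify(ab, "M", 0.3)
        assert s.bottom_ids == ["S00", "S01", "S02"]
        assert s.top_ids == ["S07", "S08", "S09"]

    def test_overlapping_strata_rejected(self):
        ab = make_abundance({"M": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="overlap"):
            stratify(ab, "M", 0.7)

    def test_unknown_modulator_rejected(self):
        ab = make_abundance({"M": [1.0, 2.0]})
        with pytest.raises(KeyError):
            stratify(ab, "X", 0.35)


class TestMutualInformation:
    def test_self_information_two_equal_frequency_bins_is_one_bit(self, rng):
        x = rng.normal(size=100)
        assert mutual_information(x, x, n_bins=2) == pytest.approx(1.0, abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        r = np.random.default_rng(0)
        x, y = r.random(10_000), r.random(10_000)
        assert 0.0 <= mutual_information(x, y, n_bins=4) <= 0.01

    def test_diagonal_joint_table_one_bit(self):
        # joint counts [[5,0],[0,5]] realized as perfectly matched bins
        x = np.arange(10.0)
        y = np.arange(10.0)
        assert mutual_information(x, y, n_bins=2) == pytest.approx(1.0, abs=1e-12)
        assert mi_from_joint([[5, 0], [0, 5]]) == pytest.approx(1.0, abs=1e-12)

    def test_off_diagonal_joint_table_hand_value(self):
        # joint counts [[2,1],[1,2]]: direct summation gives 0.0817042 bits
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.0, 5, 2, 3, 6, 4])
        expected = (2 / 3) * np.log2(4 / 3) + (1 / 3) * np.log2(2 / 3)
        assert mutual_information(x, y, n_bins=2) == pytest.approx(expected, abs=1e-12)
        assert mi_from_joint([[2, 1], [1, 2]]) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(20), np.arange(20.0)) == 0.0

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=50), rng.normal(size=50)
            a = mutual_information(x, y, n_bins=4)
            b = mutual_information(y, x, n_bins=4)
            assert a == pytest.approx(b, abs=1e-12)
            assert a >= 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=40), r.normal(size=40)
        base = mutual_information(x, y, n_bins=4)
        assert mutual_information(np.exp(x), y, n_bins=4) == pytest.approx(base, abs=1e-12)
        assert mutual_information(x, 3.0 * y + 7.0, n_bins=4) == pytest.approx(base, abs=1e-12)

    def test_default_bin_rule(self):
        assert default_bins(10) == 2       # clamp low
        assert default_bins(105) == 4      # floor(sqrt(21))
        assert default_bins(10_000) == 8   # clamp high


class TestDeltaMI:
    def test_identical_strata_zero(self, rng):
        ab = make_abundance({"APP": rng.normal(size=20), "MAPT": rng.normal(size=20),
                             "M": rng.normal(size=20)})
        ids = list(ab.samples[:7])
        strata = StratifiedSamples("M", top_ids=ids, bottom_ids=ids)
        _, _, d = delta_mi(ab, ("APP", "MAPT"), strata, n_bins=2)
        assert d == 0.0

    def test_hand_built_14_sample_composition(self, rng):
        vals = {"APP": rng.normal(size=14), "MAPT": rng.normal(size=14),
                "M": rng.normal(size=14)}
        ab = make_abundance(vals)
        strata = stratify(ab, "M", 0.35)
        mi_top, mi_bot, d = delta_mi(ab, ("APP", "MAPT"), strata, n_bins=2)
        x, y = ab.values["APP"], ab.values["MAPT"]
        exp_top = mutual_information(x.loc[strata.top_ids], y.loc[strata.top_ids], 2)
        exp_bot = mutual_information(x.loc[strata.bottom_ids], y.loc[strata.bottom_ids], 2)
        assert (mi_top, mi_bot) == (exp_top, exp_bot)
        assert d == abs(exp_top - exp_bot)

    def test_anchor_swap_invariance(self, rng):
        ab = make_abundance({"APP": rng.normal(size=40), "MAPT": rng.normal(size=40),
                             "M": rng.normal(size=40)})
        strata = stratify(ab, "M", 0.35)
        _, _, d1 = delta_mi(ab, ("APP", "MAPT"), strata, n_bins=3)
        _, _, d2 = delta_mi(ab, ("MAPT", "APP"), strata, n_bins=3)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_stratum_smaller_than_bins_rejected(self, rng):
        ab = make_abundance({"APP": rng.normal(size=10), "MAPT": rng.normal(size=10),
                             "M": rng.normal(size=10)})
        strata = StratifiedSamples("M", top_ids=ab.samples[:2], bottom_ids=ab.samples[2:4])
        with pytest.raises(ValueError, match="smaller than n_bins"):
            delta_mi(ab, ("APP", "MAPT"), strata, n_bins=3)

    def test_planted_moderator_beats_decoys(self):
        beats = 0
        for seed in range(5):
            ab = gen_abundance(SynthConfig(seed=seed, moderator_effect=0.8, n_samples=300))
            decoys = [p for p in ab.proteins if p not in ("APP", "MAPT", "HSPA5")][:20]
            deltas = {}
            for m in ["HSPA5"] + decoys:
                strata = stratify(ab, m, 0.35)
                deltas[m] = delta_mi(ab, ("APP", "MAPT"), strata)[2]
            decoy_median = np.median([deltas[m] for m in decoys])
            beats += deltas["HSPA5"] > decoy_median
        assert beats >= 4


class TestResampling:
    def test_zero_delta_gives_p_one(self):
        x = np.arange(40.0)
        ab = make_abundance({"APP": x, "MAPT": x, "M": np.arange(40.0)})
        p = resample_pvalue(ab, ("APP", "MAPT"), "M", B=50, seed=0)
        assert p == 1.0

    def test_deterministic_given_seed(self, rng):
        ab = make_abundance({"APP": rng.normal(size=40), "MAPT": rng.normal(size=40),
                             "M": rng.normal(size=40)})
        p1 = resample_pvalue(ab, ("APP", "MAPT"), "M", B=200, seed=5)
        p2 = resample_pvalue(ab, ("APP", "MAPT"), "M", B=200, seed=5)
        assert p1 == p2

    def test_add_one_bounds(self, rng):
        ab = make_abundance({"APP": rng.normal(size=40), "MAPT": rng.normal(size=40),
                             "M": rng.normal(size=40)})
        p = resample_pvalue(ab, ("APP", "MAPT"), "M", B=100, seed=0)
        assert 1 / 101 <= p <= 1.0


class TestScoreModerators:
    def test_empty_candidates_warns_and_returns_empty(self, rng):
        ab = make_abundance({"APP": rng.normal(size=20), "MAPT": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="no candidate"):
            tab = score_moderators(ab, [], ("APP", "MAPT"))
        assert tab.empty

    def test_rerun_byte_identical(self, rng):
        vals = {f"G{i}": rng.normal(size=60) for i in range(6)}
        vals["APP"], vals["MAPT"] = rng.normal(size=60), rng.normal(size=60)
        ab = make_abundance(vals)
        t1 = score_moderators(ab, [f"G{i}" for i in range(6)], ("APP", "MAPT"), B=100, seed=3)
        t2 = score_moderators(ab, [f"G{i}" for i in range(6)], ("APP", "MAPT"), B=100, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_candidate_order_does_not_change_pvalues(self, rng):
        vals = {f"G{i}": rng.normal(size=60) for i in range(4)}
        vals["APP"], vals["MAPT"] = rng.normal(size=60), rng.normal(size=60)
        ab = make_abundance(vals)
        cands = [f"G{i}" for i in range(4)]
        t1 = score_moderators(ab, cands, ("APP", "MAPT"), B=100, seed=3)
        t2 = score_moderators(ab, cands[::-1], ("APP", "MAPT"), B=100, seed=3)
        m1 = t1.set_index("modulator")["p_value"]
        m2 = t2.set_index("modulator")["p_value"]
        pd.testing.assert_series_equal(m1.sort_index(), m2.sort_index())

    def test_rank_column_follows_sort(self, rng):
        vals = {f"G{i}": rng.normal(size=60) for i in range(5)}
        vals["APP"], vals["MAPT"] = rng.normal(size=60), rng.normal(size=60)
        ab = make_abundance(vals)
        tab = score_moderators(ab, [f"G{i}" for i in range(5)], ("APP", "MAPT"), B=50, seed=0)
        assert list(tab["rank"]) == list(range(1, 6))
        assert tab["p_value"].is_monotonic_increasing
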