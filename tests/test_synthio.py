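"""The synthetic generators must plant recoverable structure: co-expression
blocks, a moderated anchor-pair dependence, marker gene sets, a subtype
frequency gradient, and a stratum-specific interaction effect."""

import numpy as np
import pandas as pd
import pytest

from abtau_modnet.synthio import (
    ConfigError,
    SynthConfig,
    gen_abundance,
    gen_cells,
    gen_histo,
    gen_ppi,
    write_all,
)
from abtau_modnet.validate import fit_interaction


def tercile_delta_r(ab, moderator, anchors):
    m = ab.values[moderator]
    x, y = ab.values[anchors[0]], ab.values[anchors[1]]
    top = m >= m.quantile(2 / 3)
    bot = m <= m.quantile(1 / 3)
    return np.corrcoef(x[top], y[top])[0, 1] - np.corrcoef(x[bot], y[bot])[0, 1]


class TestConfig:
    def test_module_sizes_exceeding_protein_count_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(n_proteins=50, module_sizes=(30, 30))

    @pytest.mark.parametrize("field,value", [
        ("within_module_corr", 1.5),
        ("moderator_effect", -0.1),
        ("ppi_density", 2.0),
    ])
    def test_out_of_range_probabilities_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SynthConfig(**{field: value})

    def test_duplicate_anchor_and_moderator_names_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(anchor_pair=("APP", "MAPT"), moderator_names=("APP",))

    def test_special_names_present_in_matrix(self, default_config):
        ab = gen_abundance(default_config)
        for name in ("APP", "MAPT", "HSPA5"):
            assert name in ab.proteins


class TestAbundance:
    def test_seed_fixes_output_bit_for_bit(self):
        a = gen_abundance(SynthConfig(seed=7))
        b = gen_abundance(SynthConfig(seed=7))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_no_missing_values_by_default(self, default_config):
        assert not gen_abundance(default_config).values.isna().any().any()

    def test_mcar_mask_when_configured(self):
        ab = gen_abundance(SynthConfig(seed=0, missing_rate=0.1))
        frac = ab.values.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15

    def test_within_module_correlation_near_target(self, default_config):
        ab = gen_abundance(default_config)
        mods = default_config.planted_modules()
        members = mods.index[mods == 1]
        R = np.corrcoef(ab.values[members].to_numpy(), rowvar=False)
        iu = np.triu_indices(len(members), k=1)
        assert abs(R[iu].mean() - default_config.within_module_corr) < 0.1

    def test_perfect_correlation_in_degenerate_limit(self):
        cfg = SynthConfig(seed=0, within_module_corr=1.0, noise_sd=0.0)
        ab = gen_abundance(cfg)
        mods = cfg.planted_modules()
        members = mods.index[mods == 1]
        R = np.corrcoef(ab.values[members].to_numpy(), rowvar=False)
        assert np.allclose(R, 1.0, atol=1e-10)

    def test_no_moderation_when_effect_zero(self):
        deltas = [
            tercile_delta_r(
                gen_abundance(SynthConfig(seed=s, moderator_effect=0.0, n_samples=500)),
                "HSPA5",
                ("APP", "MAPT"),
            )
            for s in range(10)
        ]
        assert abs(np.mean(deltas)) < 0.08

    def test_planted_moderation_effect_recovered(self):
        # sampling sd of the terciled-correlation difference is ~0.1 at
        # n=300, so the check is on the 20-seed mean plus a loose per-seed band
        deltas = np.array(
            [
                tercile_delta_r(
                    gen_abundance(SynthConfig(seed=s, moderator_effect=0.8, n_samples=300)),
                    "HSPA5",
                    ("APP", "MAPT"),
                )
                for s in range(20)
            ]
        )
        assert 0.65 <= deltas.mean() <= 0.9
        assert np.all((deltas >= 0.45) & (deltas <= 1.0))

    def test_metadata_domains(self, default_config):
        meta = gen_abundance(default_config).meta
        assert set(meta["diagnosis"]) <= {"NCI", "MCI", "AD-dementia", "other"}
        assert meta["mmse"].between(0, 30).all()


class TestPPI:
    def test_within_cliques_when_between_probability_zero(self):
        cfg = SynthConfig(seed=0, ppi_density=0.0, ppi_within_module_enrichment=np.inf)
        net = gen_ppi(cfg)
        mods = cfg.planted_modules()
        hood = set(cfg.anchor_neighborhood())
        expected = set()
        names = cfg.protein_names()
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                same_module = mods[a] == mods[b] and mods[a] > 0
                if same_module or (a in hood and b in hood):
                    expected.add(tuple(sorted((a, b))))
        got = set(zip(net.edges["node_a"], net.edges["node_b"]))
        assert got == expected

    def test_density_one_gives_complete_graph(self):
        cfg = SynthConfig(seed=0, n_proteins=30, module_sizes=(10,), ppi_density=1.0,
                          ppi_within_module_enrichment=1.0)
        net = gen_ppi(cfg)
        n = len(net.nodes)
        assert net.n_edges == n * (n - 1) // 2

    def test_block_edge_frequencies(self):
        cfg = SynthConfig(
            seed=3, n_proteins=50, module_sizes=(10, 10),
            ppi_density=0.05, ppi_within_module_enrichment=10.0,
        )
        net = gen_ppi(cfg)
        mods = cfg.planted_modules()
        got = set(zip(net.edges["node_a"], net.edges["node_b"]))
        within = [
            tuple(sorted((a, b)))
            for m in (1, 2)
            for i, a in enumerate(list(mods.index[mods == m]))
            for b in list(mods.index[mods == m])[i + 1 :]
        ]
        freq = np.mean([e in got for e in within])
        # 90 within-module pairs at p=0.5: allow ~4 binomial sd
        assert 0.3 < freq < 0.7

    def test_no_self_loops_or_duplicates(self, default_config):
        net = gen_ppi(default_config)
        assert (net.edges["node_a"] != net.edges["node_b"]).all()
        pairs = list(zip(net.edges["node_a"], net.edges["node_b"]))
        assert len(pairs) == len(set(pairs))
        assert net.edges["weight"].between(0, 1).all()


class TestCells:
    def test_marker_shift_zero_gives_no_subtype_signal(self):
        cfg = SynthConfig(seed=0, marker_shift=0.0)
        cells = gen_cells(cfg)
        markers = cfg.marker_sets()
        expr = cells.values[markers["S2"]].mean(axis=1)
        by_sub = expr.groupby(cells.labels["subtype"]).mean()
        assert by_sub.max() - by_sub.min() < 0.25

    def test_large_shift_gives_full_positive_proportion(self):
        cfg = SynthConfig(seed=0, marker_shift=5.0)
        cells = gen_cells(cfg)
        markers = cfg.marker_sets()
        own = cells.labels["subtype"] == "S3"
        pos = (cells.values.loc[own, markers["S3"]] > 0).mean().mean()
        assert pos > 0.999

    def test_planted_frequency_gradient(self):
        ordered = 0
        for seed in range(20):
            cells = gen_cells(SynthConfig(seed=seed))
            freq = (
                (cells.labels["subtype"] == "S1")
                .groupby(cells.labels["condition"])
                .mean()
            )
            ordered += freq["Control"] < freq["Abeta"] < freq["AbetaTau"]
        assert ordered >= 18

    def test_values_nonnegative_and_labeled(self, default_config):
        cells = gen_cells(default_config)
        assert (cells.values.to_numpy() >= 0).all()
        assert set(cells.labels.columns) >= {"subtype", "condition", "donor"}


class TestHisto:
    def test_noiseless_beta_recovery(self):
        cfg = SynthConfig(seed=0, histo_noise_sd=0.0, histo_donors_per_status=40)
        fits = fit_interaction(gen_histo(cfg), "tau2_pct", "abeta_pct", "gfap_pct")
        inter = fits[fits["term"] == "abeta_pct:gfap_pct"].set_index(
            pd.MultiIndex.from_frame(fits[fits["term"] == "abeta_pct:gfap_pct"][["region", "dementia"]])
        )
        assert inter.loc[("TCx", "yes"), "beta"] == pytest.approx(5.0, abs=1e-8)
        assert inter.loc[("FWM", "no"), "beta"] == pytest.approx(0.0, abs=1e-8)

    def test_zero_interaction_centered_at_zero(self):
        betas = []
        for s in range(60):
            cfg = SynthConfig(seed=s, histo_beta_interaction=0.0, histo_donors_per_status=40)
            h = gen_histo(cfg)
            sub = h[(h.region == "TCx") & (h.dementia == "yes")]
            f = fit_interaction(sub, "tau2_pct", "abeta_pct", "gfap_pct")
            betas.append(f[f["term"] == "abeta_pct:gfap_pct"]["beta"].iloc[0])
        assert abs(np.mean(betas)) < 0.1

    def test_planted_interaction_recovered_on_average(self):
        betas = []
        for s in range(50):
            cfg = SynthConfig(seed=s, histo_beta_interaction=5.0)
            h = gen_histo(cfg)
            sub = h[(h.region == "TCx") & (h.dementia == "yes")]
            f = fit_interaction(sub, "tau2_pct", "abeta_pct", "gfap_pct")
            betas.append(f[f["term"] == "abeta_pct:gfap_pct"]["beta"].iloc[0])
        assert 4.5 <= np.mean(betas) <= 5.5

    def test_domains(self, default_config):
        h = gen_histo(default_config)
        assert set(h["region"]) == {"FWM", "HIP", "PCx", "TCx"}
        assert set(h["dementia"]) == {"no", "yes"}
        assert h["cerad"].between(1, 4).all()
        assert h["braak"].between(0, 6).all()
        for col in ("abeta_pct", "tau2_pct", "at8_pct", "gfap_pct", "iba1_pct", "gpnmb_fpkm"):
            assert (h[col] >= 0).all()


def test_write_all_round_trip(tmp_path, default_config):
    paths = write_all(default_config, tmp_path)
    assert all(p.exists() for p in paths.values())
    from abtau_modnet.containers import Abundance

    ab = Abundance.from_tsv(paths["abundance"])
    pd.testing.assert_frame_equal(ab.values, gen_abundance(default_config).values)
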