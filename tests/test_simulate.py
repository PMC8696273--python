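"""Synthetic-data generator: planted structure, determinism, truth record."""

import numpy as np
import pytest

from genefc.atlas import connection_pairs
from genefc.simulate import (
    SyntheticConfig,
    best_rank1_pattern,
    generate_atlas,
    generate_connectivity,
    generate_dataset,
    generate_expression,
)


class TestConfigValidation:
    def test_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(n_regions=10, network_sizes=(4, 4))

    def test_effect_range(self):
        with pytest.raises(ValueError, match="coupling_effect"):
            SyntheticConfig(coupling_effect=1.5)

    def test_overlap_forbidden(self):
        with pytest.raises(ValueError, match="overlap"):
            SyntheticConfig(n_coupling_genes=5, network_specific_map={3: 0})

    def test_spread_keeps_effects_valid(self):
        with pytest.raises(ValueError, match="spread"):
            SyntheticConfig(coupling_effect=0.9, coupling_effect_spread=0.2)

    def test_effect_gradient(self):
        cfg = SyntheticConfig(coupling_effect=0.5, coupling_effect_spread=0.2)
        effects = cfg.coupling_effects()
        assert effects.min() == pytest.approx(0.3)
        assert effects.max() == pytest.approx(0.7)
        assert effects.mean() == pytest.approx(0.5)


class TestAtlasGeneration:
    def test_odd_sizes_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_atlas(SyntheticConfig(n_regions=8, network_sizes=(5, 3)))

    def test_interleaved_homologs(self):
        atlas = generate_atlas(SyntheticConfig(n_regions=8, network_sizes=(4, 4)))
        assert atlas.homolog_pairs() == [(0, 1), (2, 3), (4, 5), (6, 7)]


class TestConnectivityGeneration:
    def test_zero_noise_identical_subjects(self):
        cfg = SyntheticConfig(
            n_regions=8, network_sizes=(4, 4), n_subjects=5,
            n_coupling_genes=0, subject_noise_sd=0.0,
        )
        atlas = generate_atlas(cfg)
        fc, template = generate_connectivity(cfg, atlas)
        assert np.all(fc == template[None, :])

    def test_homolog_boost_dominates_template(self):
        sizes = (14, 14, 4, 4, 18, 10, 18, 8)
        cfg = SyntheticConfig(
            n_regions=90, network_sizes=sizes, n_coupling_genes=0,
            system_fc_boost=0.0, intra_network_fc_boost=0.0, homolog_fc_boost=2.0,
        )
        atlas = generate_atlas(cfg)
        _, template = generate_connectivity(cfg, atlas)
        top45 = set(np.argsort(template)[-45:].tolist())
        iu, ju = connection_pairs(90)
        hom = atlas.homolog_ids
        homolog_ids = set(np.flatnonzero(hom[iu] == ju).tolist())
        assert top45 == homolog_ids

    def test_subject_mean_concentrates_on_template(self):
        cfg = SyntheticConfig(
            n_regions=16, network_sizes=(8, 8), n_subjects=50,
            n_coupling_genes=0, subject_noise_sd=0.1, seed=4,
        )
        atlas = generate_atlas(cfg)
        fc, template = generate_connectivity(cfg, atlas)
        r = np.corrcoef(fc.mean(axis=0), template)[0, 1]
        assert r > 0.99


class TestExpressionGeneration:
    def _setup(self, **kw):
        cfg = SyntheticConfig(
            n_regions=16, network_sizes=(8, 8), n_genes=60,
            n_coupling_genes=10, seed=2, **kw,
        )
        atlas = generate_atlas(cfg)
        _, template = generate_connectivity(cfg, atlas)
        return cfg, atlas, template

    def test_columns_z_scored(self):
        cfg, atlas, template = self._setup()
        expr, _ = generate_expression(cfg, atlas, template)
        np.testing.assert_allclose(expr.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(expr.std(0, ddof=0), 1, atol=1e-12)

    def test_noiseless_gene_product_matches_pattern(self):
        cfg, atlas, template = self._setup(coupling_effect=1.0)
        expr, signals = generate_expression(cfg, atlas, template)
        iu, ju = connection_pairs(16)
        _, v = signals[0]
        prod = expr[iu, 0] * expr[ju, 0]
        r = np.corrcoef(prod, v[iu] * v[ju])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_null_effect_uncorrelated_with_template(self):
        cfg, atlas, template = self._setup(coupling_effect=0.0)
        expr, _ = generate_expression(cfg, atlas, template)
        iu, ju = connection_pairs(16)
        rs = [
            abs(np.corrcoef(expr[iu, a] * expr[ju, a], template)[0, 1])
            for a in range(10)
        ]
        assert np.mean(rs) < 0.25  # chance level for 16-region patterns

    def test_planted_genes_beat_background(self):
        """Seeded Monte-Carlo: mean planted |r| with the template exceeds the
        95th percentile of background |r|."""
        cfg = SyntheticConfig(
            n_regions=30, network_sizes=(14, 8, 4, 4), n_genes=300,
            n_coupling_genes=20, coupling_effect=0.5, seed=3,
        )
        atlas = generate_atlas(cfg)
        _, template = generate_connectivity(cfg, atlas)
        expr, _ = generate_expression(cfg, atlas, template)
        iu, ju = connection_pairs(30)
        prods = expr[iu] * expr[ju]
        t = template - template.mean()
        pc = prods - prods.mean(0)
        rs = np.abs(
            (t @ pc) / np.sqrt((t @ t) * (pc**2).sum(0))
        )
        assert rs[:20].mean() > np.quantile(rs[20:], 0.95)

    def test_degenerate_template_error(self):
        cfg, atlas, _ = self._setup()
        with pytest.raises(ValueError, match="degenerate"):
            generate_expression(cfg, atlas, np.zeros(120))

    def test_bilateral_pattern_is_hemisphere_symmetric(self):
        cfg = SyntheticConfig(
            n_regions=16, network_sizes=(8, 8), n_genes=20,
            n_coupling_genes=5, coupling_pattern="bilateral", seed=6,
        )
        atlas = generate_atlas(cfg)
        _, template = generate_connectivity(cfg, atlas)
        _, signals = generate_expression(cfg, atlas, template)
        hom = atlas.homolog_ids
        for a in range(5):
            _, v = signals[a]
            np.testing.assert_allclose(v, v[hom], atol=1e-12)


class TestBestRank1Pattern:
    def test_hemisphere_symmetric_template_gives_symmetric_pattern(self):
        cfg = SyntheticConfig(n_regions=30, network_sizes=(14, 8, 4, 4), n_coupling_genes=0)
        atlas = generate_atlas(cfg)
        _, template = generate_connectivity(cfg, atlas)
        v = best_rank1_pattern(template, 30)
        iu, ju = connection_pairs(30)
        vs = (v - v.mean()) / v.std()
        prod = vs[iu] * vs[ju]
        t = template - template.mean()
        p = prod - prod.mean()
        align = abs(p @ t) / np.sqrt((p @ p) * (t @ t))
        assert align > 0.85  # strong rank-1 alignability of this template


class TestDatasetComposition:
    def test_determinism(self):
        cfg = SyntheticConfig(n_regions=16, network_sizes=(8, 8), n_genes=40,
                              n_coupling_genes=5, n_subjects=6, seed=9)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        np.testing.assert_array_equal(d1.raw_expression, d2.raw_expression)
        np.testing.assert_array_equal(d1.raw_connectivity, d2.raw_connectivity)

    def test_seed_changes_data(self):
        base = dict(n_regions=16, network_sizes=(8, 8), n_genes=40,
                    n_coupling_genes=5, n_subjects=6)
        d1 = generate_dataset(SyntheticConfig(seed=1, **base))
        d2 = generate_dataset(SyntheticConfig(seed=2, **base))
        assert not np.array_equal(d1.raw_expression, d2.raw_expression)

    def test_shapes_and_truth(self):
        cfg = SyntheticConfig(
            n_regions=30, network_sizes=(14, 8, 4, 4), n_genes=300,
            n_coupling_genes=20, n_subjects=40,
            network_specific_map={25: 1}, seed=0,
        )
        ds = generate_dataset(cfg)
        assert ds.expression.values.shape == (30, 300)
        assert ds.connectivity.values.shape == (40, 435)
        assert len(ds.truth["coupling_genes"]) == 20
        assert ds.truth["network_specific"] == {"g0025": "net1"}
        assert len(ds.truth["template"]) == 435

    def test_written_files_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_regions=16, network_sizes=(8, 8), n_genes=20,
                              n_coupling_genes=4, n_subjects=5, seed=3)
        ds = generate_dataset(cfg)
        paths = ds.write(tmp_path)
        import json

        import pandas as pd
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        assert expr.shape == (16, 20)
        truth = json.loads(paths["truth"].read_text())
        assert truth["coupling_genes"] == ds.truth["coupling_genes"]
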