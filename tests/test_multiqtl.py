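import numpy as np
import pandas as pd
import pytest

from poolgwas.config import AnalysisConfig
from poolgwas.multiqtl import (
    MultiQTLModel,
    QTL,
    consolidate_across_locations,
    explained_variance,
    forward_select,
    pca_marker_profiles,
)

from conftest import make_genotype_matrix


def sig_records(marker_ids, walds=None, trait="FL_Begin", loc="CRA"):
    walds = walds if walds is not None else np.linspace(30, 20, len(marker_ids))
    return pd.DataFrame(
        {
            "marker_id": marker_ids,
            "trait": trait,
            "location_id": loc,
            "wald": walds,
            "neg_log10_p": walds / 4.0,
            "significant": True,
        }
    )


def block_panel(seed=0, n=120, blocks=3, per_block=4, within_sd=0.05):
    """Panel of `blocks` LD blocks (one scaffold each), tight within-block
    correlation, independent across blocks."""
    rng = np.random.default_rng(seed)
    cols, scaffolds = [], []
    for b in range(blocks):
        base = rng.uniform(0.2, 0.8, size=n)
        for _ in range(per_block):
            cols.append(np.clip(base + rng.normal(0, within_sd, n), 0, 1))
            scaffolds.append(f"s{b + 1}")
    return make_genotype_matrix(np.column_stack(cols), scaffolds=scaffolds), rng


class TestForwardSelect:
    def test_single_marker_model(self):
        g, rng = block_panel(seed=1, blocks=1, per_block=1)
        y = pd.Series(2.0 * g.values[:, 0] + rng.normal(0, 0.1, g.n_accessions),
                      index=g.accessions)
        model = forward_select(sig_records(g.marker_ids[:1]), g, y)
        assert len(model.qtls) == 1
        marginal = np.corrcoef(g.values[:, 0], y)[0, 1] ** 2
        assert model.full_r2 == pytest.approx(marginal, abs=1e-10)
        assert model.qtls[0].incremental_r2 == pytest.approx(marginal, abs=1e-10)

    def test_perfectly_collinear_pair_collapses(self):
        g, rng = block_panel(seed=2, blocks=1, per_block=1)
        x = g.values[:, 0]
        g2 = make_genotype_matrix(np.column_stack([x, x]), scaffolds=["s1", "s1"])
        y = pd.Series(x + rng.normal(0, 0.1, len(x)), index=g2.accessions)
        model = forward_select(sig_records(g2.marker_ids), g2, y)
        assert len(model.qtls) == 1
        assert model.qtls[0].members == [g2.marker_ids[1]]

    def test_recovers_causal_blocks(self):
        """3 LD blocks, causal markers in blocks 1 and 2: exactly two QTLs,
        representatives in the causal blocks, memberships equal the blocks."""
        g, rng = block_panel(seed=3)
        y_raw = 1.5 * g.values[:, 0] - 1.2 * g.values[:, 4] + rng.normal(
            0, 0.05, g.n_accessions
        )
        y = pd.Series(y_raw, index=g.accessions)
        model = forward_select(sig_records(g.marker_ids[:8]), g, y)
        assert len(model.qtls) == 2
        rep_scaffolds = {r.rsplit("_", 1)[0] for r in model.representatives}
        assert rep_scaffolds == {"s1", "s2"}
        for q in model.qtls:
            block = q.representative.rsplit("_", 1)[0]
            expected = {
                m for m in g.marker_ids[:8] if m.rsplit("_", 1)[0] == block
            } - {q.representative}
            assert set(q.members) == expected

    def test_first_pick_is_max_marginal_r2(self):
        g, rng = block_panel(seed=4, blocks=4, per_block=1)
        y = pd.Series(g.values[:, 2] + rng.normal(0, 0.3, g.n_accessions),
                      index=g.accessions)
        model = forward_select(sig_records(g.marker_ids), g, y)
        marginals = [
            np.corrcoef(g.values[:, j], y)[0, 1] ** 2 for j in range(4)
        ]
        assert model.qtls[0].representative == g.marker_ids[int(np.argmax(marginals))]

    def test_partition_property_and_monotone_r2(self):
        g, rng = block_panel(seed=5, blocks=5, per_block=3, within_sd=0.08)
        y = pd.Series(
            g.values[:, 0] - 0.8 * g.values[:, 6] + 0.5 * g.values[:, 12]
            + rng.normal(0, 0.2, g.n_accessions),
            index=g.accessions,
        )
        sig = sig_records(g.marker_ids)
        model = forward_select(sig, g, y)
        reps = model.representatives
        members = [m for q in model.qtls for m in q.members]
        assert sorted(reps + members) == sorted(sig["marker_id"])
        assert len(set(reps) & set(members)) == 0
        # representatives pairwise below the collinearity threshold
        sub = g.subset_markers(reps)
        corr = np.corrcoef(sub.values, rowvar=False)
        off = np.abs(corr[np.triu_indices_from(corr, 1)])
        assert (off < 0.3).all()
        # cumulative explained variance non-decreasing, sums to full model
        incs = [q.incremental_r2 for q in model.qtls]
        assert all(v >= -1e-10 for v in incs)
        assert np.cumsum(incs)[-1] == pytest.approx(model.full_r2, abs=1e-8)

    def test_empty_significant_list(self):
        g, _ = block_panel(seed=6, blocks=1)
        y = pd.Series(np.random.default_rng(0).normal(size=g.n_accessions),
                      index=g.accessions)
        model = forward_select(sig_records([])[:0], g, y)
        assert model.qtls == []
        assert np.isnan(model.full_r2)


class TestExplainedVariance:
    def test_perfect_fit_is_one(self):
        g, _ = block_panel(seed=7, blocks=2, per_block=1)
        y = pd.Series(3.0 + 2.0 * g.values[:, 0] - g.values[:, 1],
                      index=g.accessions)
        assert explained_variance(g.marker_ids, g, y) == pytest.approx(1.0, abs=1e-12)

    def test_unrelated_markers_explain_nothing(self):
        g, rng = block_panel(seed=8, blocks=2, per_block=1)
        y = pd.Series(rng.normal(size=g.n_accessions), index=g.accessions)
        assert explained_variance(g.marker_ids, g, y) < 0.1

    def test_matches_multiple_regression_oracle(self):
        """r2 equals an independently coded regression R^2 (fitted vs
        observed squared correlation) to 1e-10."""
        g, rng = block_panel(seed=9, blocks=4, per_block=1)
        y_raw = g.values[:, 0] + 0.5 * g.values[:, 2] + rng.normal(
            0, 0.5, g.n_accessions
        )
        y = pd.Series(y_raw, index=g.accessions)
        r2 = explained_variance(g.marker_ids, g, y)
        X = np.column_stack([np.ones(g.n_accessions), g.values])
        beta, *_ = np.linalg.lstsq(X, y_raw, rcond=None)
        fitted = X @ beta
        oracle = np.corrcoef(fitted, y_raw)[0, 1] ** 2
        assert r2 == pytest.approx(oracle, abs=1e-10)

    def test_collinear_representatives_rejected(self):
        g, rng = block_panel(seed=10, blocks=1, per_block=1)
        x = g.values[:, 0]
        g2 = make_genotype_matrix(np.column_stack([x, x]), scaffolds=["s1", "s2"])
        y = pd.Series(rng.normal(size=len(x)), index=g2.accessions)
        with pytest.raises(ValueError, match="collinear"):
            explained_variance(g2.marker_ids, g2, y)


class TestPCAMarkerProfiles:
    def _records(self, g, n_sig):
        return pd.DataFrame(
            {
                "marker_id": g.marker_ids,
                "neg_log10_p": np.linspace(8, 4, g.n_markers),
                "significant": [True] * n_sig + [False] * (g.n_markers - n_sig),
            }
        )

    def test_duplicated_markers_get_identical_scores(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.1, 0.9, size=30)
        z = rng.uniform(0.1, 0.9, size=30)
        g = make_genotype_matrix(np.column_stack([x, x, z]))
        out, _ = pca_marker_profiles(g, self._records(g, 3))
        np.testing.assert_allclose(
            out.loc[0, ["PC1", "PC2"]].to_numpy(dtype=float),
            out.loc[1, ["PC1", "PC2"]].to_numpy(dtype=float),
            atol=1e-10,
        )

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(12)
        g = make_genotype_matrix(rng.beta(2, 2, size=(25, 10)))
        out, var_frac = pca_marker_profiles(g, self._records(g, 10))
        M = g.values.T - g.values.T.mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(M @ M.T))[::-1]
        lam = lam[lam > 1e-12]
        np.testing.assert_allclose(var_frac[: len(lam)], lam / lam.sum(), atol=1e-10)

    def test_centering_invariance_to_accession_shift(self):
        rng = np.random.default_rng(13)
        vals = rng.beta(2, 2, size=(20, 8)) * 0.5
        g1 = make_genotype_matrix(vals)
        shifted = vals.copy()
        shifted[3, :] += 0.3  # constant shift of one accession's profile
        g2 = make_genotype_matrix(shifted)
        out1, _ = pca_marker_profiles(g1, self._records(g1, 8))
        out2, _ = pca_marker_profiles(g2, self._records(g2, 8))
        np.testing.assert_allclose(out1[["PC1", "PC2"]], out2[["PC1", "PC2"]],
                                   atol=1e-10)

    def test_needs_three_significant_markers(self):
        rng = np.random.default_rng(14)
        g = make_genotype_matrix(rng.beta(2, 2, size=(10, 5)))
        with pytest.raises(ValueError):
            pca_marker_profiles(g, self._records(g, 2))


def model_with(reps, trait="FL_Begin", loc="CRA"):
    m = MultiQTLModel(trait=trait, location_id=loc, full_r2=0.5)
    for i, r in enumerate(reps):
        m.qtls.append(QTL(representative=r, members=[], trait=trait,
                          location_id=loc, incremental_r2=0.1, order=i + 1))
    return m


class TestConsolidateAcrossLocations:
    def test_identical_representative_spans_all_locations(self):
        g, _ = block_panel(seed=15, blocks=3, per_block=1)
        mid = g.marker_ids[0]
        models = [model_with([mid], loc=loc) for loc in ("CRA", "FNPC", "VDS")]
        out = consolidate_across_locations(models, g)
        assert len(out) == 1
        assert out[0].n_locations == 3
        assert all(v == [mid] for v in out[0].members.values())

    def test_uncorrelated_markers_give_empty_output(self):
        g, _ = block_panel(seed=16, blocks=3, per_block=1)
        models = [
            model_with([g.marker_ids[i]], loc=loc)
            for i, loc in enumerate(("CRA", "FNPC", "VDS"))
        ]
        assert consolidate_across_locations(models, g) == []

    def test_correlated_blocks_link_across_locations(self):
        g, _ = block_panel(seed=17, blocks=2, per_block=3)
        # block 1 markers in two locations, block 2 only in the third
        models = [
            model_with([g.marker_ids[0]], loc="CRA"),
            model_with([g.marker_ids[1]], loc="FNPC"),
            model_with([g.marker_ids[3]], loc="VDS"),
        ]
        out = consolidate_across_locations(models, g)
        assert len(out) == 1
        assert set(out[0].members) == {"CRA", "FNPC"}

    def test_invariant_to_model_order(self):
        g, _ = block_panel(seed=18, blocks=3, per_block=2)
        models = [
            model_with([g.marker_ids[0], g.marker_ids[2]], loc="CRA"),
            model_with([g.marker_ids[1]], loc="FNPC"),
            model_with([g.marker_ids[3], g.marker_ids[4]], loc="VDS"),
        ]
        out1 = consolidate_across_locations(models, g)
        out2 = consolidate_across_locations(models[::-1], g)
        assert [(q.name, q.members) for q in out1] == [
            (q.name, q.members) for q in out2
        ]

    def test_mixed_traits_rejected(self):
        g, _ = block_panel(seed=19, blocks=1, per_block=2)
        models = [model_with([g.marker_ids[0]], trait="FL_Begin", loc="CRA"),
                  model_with([g.marker_ids[1]], trait="VEG", loc="FNPC")]
        with pytest.raises(ValueError):
            consolidate_across_locations(models, g)
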