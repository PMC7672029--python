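import numpy as np
import pandas as pd
import pytest

from poolgwas.config import QCThresholds
from poolgwas.qc import (
    compute_kinship,
    effective_marker_number,
    filter_snps,
    parse_marker_id,
    score_major_allele,
    _li_ji,
)

from conftest import make_genotype_matrix


def random_freq_table(rng, n_acc=5, n_markers=4):
    rows = []
    for j in range(n_markers):
        for i in range(n_acc):
            x = rng.dirichlet([2.0, 2.0, 0.3, 0.3])
            rows.append(
                {
                    "accession_id": f"acc{i}",
                    "marker_id": f"scaffold{j + 1}_{50 + j}",
                    "A": x[0], "C": x[1], "G": x[2], "T": x[3],
                }
            )
    return pd.DataFrame(rows)


class TestScoreMajorAllele:
    def test_extracts_major_allele_frequencies(self):
        tab = pd.DataFrame(
            [
                {"accession_id": "a1", "marker_id": "s1_10",
                 "A": 0.1, "C": 0.0, "G": 0.9, "T": 0.0},
                {"accession_id": "a2", "marker_id": "s1_10",
                 "A": 0.3, "C": 0.0, "G": 0.7, "T": 0.0},
            ]
        )
        g = score_major_allele(tab)
        assert g.markers.loc[0, "major"] == "G"
        np.testing.assert_allclose(g.values[:, 0], [0.9, 0.7])

    def test_tie_broken_by_allele_order(self):
        tab = pd.DataFrame(
            [
                {"accession_id": "a1", "marker_id": "s1_10",
                 "A": 0.5, "C": 0.0, "G": 0.5, "T": 0.0},
                {"accession_id": "a2", "marker_id": "s1_10",
                 "A": 0.5, "C": 0.0, "G": 0.5, "T": 0.0},
            ]
        )
        g = score_major_allele(tab)
        assert g.markers.loc[0, "major"] == "A"

    def test_bad_frequency_sum_rejected(self):
        tab = pd.DataFrame(
            [{"accession_id": "a1", "marker_id": "s1_10",
              "A": 0.5, "C": 0.6, "G": 0.0, "T": 0.0}]
        )
        with pytest.raises(ValueError, match="s1_10"):
            score_major_allele(tab)

    def test_matches_argmax_oracle(self):
        """Random table equals a brute-force argmax-and-extract oracle."""
        rng = np.random.default_rng(5)
        tab = random_freq_table(rng)
        g = score_major_allele(tab)
        for j, mid in enumerate(g.marker_ids):
            sub = tab[tab.marker_id == mid].set_index("accession_id")
            means = sub[["A", "C", "G", "T"]].mean()
            major = means.idxmax()
            assert g.markers.loc[j, "major"] == major
            np.testing.assert_allclose(
                g.values[:, j], sub.loc[g.accessions, major].to_numpy()
            )
            top2 = np.sort(means.to_numpy())[-2:].sum()
            assert g.markers.loc[j, "top2_sum"] == pytest.approx(top2)


class TestFilterSnps:
    def test_each_rule_removes_its_marker(self):
        rng = np.random.default_rng(0)
        base = np.clip(rng.uniform(0.3, 0.9, size=(10, 5)), 0, 1)
        base[0, 0] = np.nan          # call-rate failure
        base[:, 1] = 0.99            # MAF failure (mean major > 0.98)
        base[:, 2] = 0.5             # SD failure (constant)
        g = make_genotype_matrix(base)
        g.markers["top2_sum"] = [1.0, 1.0, 1.0, 0.90, 1.0]  # biallelic failure
        filtered, report = filter_snps(g, QCThresholds())
        kept = set(filtered.marker_ids)
        assert g.marker_ids[0] not in kept
        assert g.marker_ids[1] not in kept
        assert g.marker_ids[2] not in kept
        assert g.marker_ids[3] not in kept
        counts = dict(zip(report["rule"], report["removed_count"]))
        assert counts["call_rate"] == 1
        assert counts["biallelic"] == 1
        assert counts["maf"] == 1
        assert counts["major_freq_sd"] >= 1

    def test_matches_bruteforce_predicates_and_idempotent(self):
        """Seeded 50 x 500 panel: surviving set equals marker-wise predicate
        evaluation; filtering its own output removes nothing."""
        rng = np.random.default_rng(11)
        vals = rng.beta(2, 1.2, size=(50, 500))
        vals[rng.uniform(size=vals.shape) < 0.01] = np.nan
        g = make_genotype_matrix(vals, scaffolds=[f"s{j % 40}" for j in range(500)])
        g.markers["top2_sum"] = rng.uniform(0.9, 1.0, size=500)
        t = QCThresholds()
        filtered, _ = filter_snps(g, t)

        expected = []
        for j, mid in enumerate(g.marker_ids):
            col = vals[:, j]
            ok = (
                not np.isnan(col).any()
                and g.markers.loc[j, "top2_sum"] >= t.biallelic_sum_min
                and np.mean(col) <= 1 - t.maf_min
                and np.std(col, ddof=1) >= t.major_freq_sd_min
            )
            if ok:
                expected.append(mid)
        assert filtered.marker_ids == expected

        refiltered, report2 = filter_snps(filtered, t)
        assert refiltered.marker_ids == filtered.marker_ids
        assert report2["removed_count"].sum() == 0


class TestKinship:
    def test_identical_rows_have_maximal_off_diagonal(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.2, 0.9, size=(5, 30))
        vals[1] = vals[0]
        K = compute_kinship(make_genotype_matrix(vals))
        off = K.values - np.diag(np.diag(K.values))
        assert np.unravel_index(np.argmax(off), off.shape) in {(0, 1), (1, 0)}
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], rel=1e-9)

    def test_matches_hand_computed_vanraden(self):
        """4 x 6 toy matrix equals the direct VanRaden formula to 1e-12."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 0.9, size=(4, 6))
        K = compute_kinship(make_genotype_matrix(vals))
        dosage = 2 * vals
        p = vals.mean(axis=0)
        Z = dosage - dosage.mean(axis=0)
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_fixed_markers_excluded(self):
        vals = np.array([[0.2, 1.0], [0.8, 1.0], [0.5, 1.0]])
        K = compute_kinship(make_genotype_matrix(vals))
        K1 = compute_kinship(make_genotype_matrix(vals[:, :1]))
        np.testing.assert_allclose(K.values, K1.values, atol=1e-12)

    def test_diagonal_near_one_for_individual_like_panel(self):
        """VanRaden scaling: mean diagonal ~ 1 when values are individual
        diploid frequencies (0/0.5/1) on an unstructured panel."""
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, size=2000)
        vals = rng.binomial(2, p, size=(120, 2000)) / 2.0
        K = compute_kinship(make_genotype_matrix(
            vals, scaffolds=[f"s{j}" for j in range(2000)]
        ))
        assert K.values.diagonal().mean() == pytest.approx(1.0, abs=0.1)

    def test_invariant_to_accession_permutation(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0.1, 0.9, size=(8, 20))
        g = make_genotype_matrix(vals)
        K = compute_kinship(g)
        perm = rng.permutation(8)
        g2 = g.subset_accessions([g.accessions[i] for i in perm])
        K2 = compute_kinship(g2)
        np.testing.assert_allclose(
            K2.values, K.values[np.ix_(perm, perm)], atol=1e-12
        )


class TestEffectiveMarkerNumber:
    def test_duplicated_marker_counts_once(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 0.9, size=50)
        g = make_genotype_matrix(np.column_stack([x, x]), scaffolds=["s1", "s1"])
        assert effective_marker_number(g) == pytest.approx(1.0, abs=1e-8)

    def test_independent_markers_give_meff_near_m(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 1, size=(500, 20))
        g = make_genotype_matrix(vals, scaffolds=["s1"] * 20)
        assert effective_marker_number(g) == pytest.approx(20.0, abs=0.5)

    def test_three_perfect_blocks_give_meff_three(self):
        """Three blocks of perfectly collinear markers count as three
        independent tests, matching full-matrix Li-Ji as oracle."""
        rng = np.random.default_rng(9)
        cols, scaffolds = [], []
        for b in range(3):
            base = rng.uniform(0.2, 0.8, size=200)
            for _ in range(5):
                cols.append(base)
                scaffolds.append(f"s{b + 1}")
        vals = np.column_stack(cols)
        g = make_genotype_matrix(vals, scaffolds=scaffolds)
        meff = effective_marker_number(g)
        assert meff == pytest.approx(3.0, abs=1e-6)
        # oracle: direct Li-Ji on the full correlation matrix with the
        # cross-block entries at their design value of zero (the sampled
        # cross-block noise otherwise shifts eigenvalues across the
        # integer boundaries where the Li-Ji count is discontinuous)
        corr = np.corrcoef(vals, rowvar=False)
        mask = np.equal.outer(scaffolds, scaffolds)
        oracle = _li_ji(np.where(mask, corr, 0.0))
        assert meff == pytest.approx(oracle, abs=1e-6)

    def test_blockwise_tracks_full_matrix_oracle_under_noise(self):
        """Moderately collinear blocks: per-scaffold blocking stays close to
        the full-correlation-matrix Li-Ji value (blocks are uncorrelated)."""
        rng = np.random.default_rng(9)
        cols, scaffolds = [], []
        for b in range(3):
            base = rng.uniform(0.2, 0.8, size=200)
            for _ in range(5):
                cols.append(np.clip(base + rng.normal(0, 0.15, 200), 0, 1))
                scaffolds.append(f"s{b + 1}")
        vals = np.column_stack(cols)
        g = make_genotype_matrix(vals, scaffolds=scaffolds)
        corr = np.corrcoef(vals, rowvar=False)
        mask = np.equal.outer(scaffolds, scaffolds)
        oracle = _li_ji(np.where(mask, corr, 0.0))
        assert effective_marker_number(g) == pytest.approx(oracle, abs=0.2)

    def test_windowed_equals_full_li_ji_at_window_m(self):
        """With window >= M on one scaffold, the blockwise result equals
        Li-Ji applied to the full correlation matrix."""
        rng = np.random.default_rng(10)
        vals = rng.beta(2, 2, size=(80, 40))
        g = make_genotype_matrix(vals, scaffolds=["s1"] * 40)
        full = _li_ji(np.corrcoef(vals, rowvar=False))
        assert effective_marker_number(g, window=40) == pytest.approx(full, abs=1e-9)
        assert effective_marker_number(g, window=400) == pytest.approx(full, abs=1e-9)

    def test_bounds_and_bad_window(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 1, size=(30, 25))
        g = make_genotype_matrix(vals, scaffolds=[f"s{j % 5}" for j in range(25)])
        meff = effective_marker_number(g, window=3)
        assert 1.0 <= meff <= 25.0
        with pytest.raises(ValueError):
            effective_marker_number(g, window=0)


def test_parse_marker_id_roundtrip():
    assert parse_marker_id("scaffold82158_8091") == ("scaffold82158", 8091)
    assert parse_marker_id("C32110397_2120") == ("C32110397", 2120)
    with pytest.raises(ValueError):
        parse_marker_id("nounderscore")
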