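import itertools

import numpy as np
import pandas as pd
import pytest

from depthcline import structure_stats as st
from depthcline.io_formats import GenotypeTable
from depthcline.synthetic_data import SynthConfig, simulate_genotypes


def brute_force_theta(gt: GenotypeTable, grouping) -> float:
    """Independent loop-by-loop evaluation of the variance-component
    Fst estimator (sum of a over sum of a+b+c, per locus and allele)."""
    labels = sorted(set(grouping))
    A = ABC = 0.0
    for j in range(gt.n_loci):
        col = gt.calls[:, j, :]
        alleles = sorted({a for pair in col for a in pair if a > 0})
        group_rows = {
            g: [i for i, lab in enumerate(grouping)
                if lab == g and col[i, 0] > 0]
            for g in labels
        }
        live = [g for g in labels if len(group_rows[g]) >= 1]
        r = len(live)
        if r < 2:
            continue
        n = {g: len(group_rows[g]) for g in live}
        nbar = sum(n.values()) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(v**2 for v in n.values()) / (r * nbar)) / (r - 1)
        for a in alleles:
            p = {
                g: sum((col[i] == a).sum() for i in group_rows[g]) / (2 * n[g])
                for g in live
            }
            h = {
                g: sum(
                    1 for i in group_rows[g]
                    if (col[i] == a).sum() == 1
                ) / n[g]
                for g in live
            }
            pbar = sum(n[g] * p[g] for g in live) / (r * nbar)
            s2 = sum(n[g] * (p[g] - pbar) ** 2 for g in live) / ((r - 1) * nbar)
            hbar = sum(n[g] * h[g] for g in live) / (r * nbar)
            va = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            vb = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            vc = hbar / 2
            A += va
            ABC += va + vb + vc
    return A / ABC


def brute_force_dest(gt: GenotypeTable, grouping) -> float:
    """Direct evaluation of the two-group Dest formula from tallied
    frequencies, combined across loci by the delta-method harmonic mean."""
    labels = sorted(set(grouping))
    d_loci = []
    for j in range(gt.n_loci):
        col = gt.calls[:, j, :]
        tallies, ns = [], []
        for g in labels:
            rows = [i for i, lab in enumerate(grouping)
                    if lab == g and col[i, 0] > 0]
            tally: dict[int, int] = {}
            for i in rows:
                for a in col[i]:
                    tally[a] = tally.get(a, 0) + 1
            tallies.append(tally)
            ns.append(len(rows))
        alleles = sorted(set().union(*tallies))
        p = np.array(
            [[t.get(a, 0) / (2 * n) for a in alleles]
             for t, n in zip(tallies, ns)]
        )
        r = len(labels)
        hs = 1 - float((p**2).sum(axis=1).mean())
        ht = 1 - float((p.mean(axis=0) ** 2).sum())
        nh = r / sum(1 / n for n in ns)
        hs_est = (2 * nh / (2 * nh - 1)) * hs
        ht_est = ht + hs_est / (2 * nh * r)
        d_loci.append(((ht_est - hs_est) / (1 - hs_est)) * r / (r - 1))
    d = np.array(d_loci)
    mu, var = d.mean(), d.var(ddof=1)
    return 1 / (1 / mu + var / mu**3) if mu > 0 else mu


class TestTheta:
    def test_hand_set_matches_brute_force_components(self, hand_gt, hand_groups):
        got = st.weir_cockerham_theta(hand_gt, hand_groups)
        assert got == pytest.approx(
            brute_force_theta(hand_gt, hand_groups), abs=1e-12
        )

    def test_brute_force_agreement_with_missing_data(self):
        cfg = SynthConfig(group_sizes=(40, 40, 40), n_loci=6,
                          target_fst=0.03, missing_rate=0.15, seed=9)
        gt, frame = simulate_genotypes(cfg)
        grouping = frame["group"].tolist()
        assert st.weir_cockerham_theta(gt, grouping) == pytest.approx(
            brute_force_theta(gt, grouping), abs=1e-12
        )

    def test_null_pair_theta_near_zero(self, null_pair):
        gt, grouping = null_pair
        assert abs(st.weir_cockerham_theta(gt, grouping)) < 0.01

    def test_invariant_to_allele_relabeling_and_order(self, hand_gt, hand_groups):
        base = st.weir_cockerham_theta(hand_gt, hand_groups)
        relabeled = hand_gt.calls.copy()
        relabeled[relabeled > 0] = 10 - relabeled[relabeled > 0]  # 1..3 -> 9..7
        gt2 = GenotypeTable(
            hand_gt.individual_ids, hand_gt.locus_names, relabeled
        )
        assert st.weir_cockerham_theta(gt2, hand_groups) == pytest.approx(
            base, abs=1e-12
        )
        perm = np.array([3, 1, 5, 0, 4, 2])
        gt3 = GenotypeTable(
            [hand_gt.individual_ids[i] for i in perm],
            hand_gt.locus_names,
            hand_gt.calls[perm],
        )
        assert st.weir_cockerham_theta(
            gt3, [hand_groups[i] for i in perm]
        ) == pytest.approx(base, abs=1e-12)

    def test_pairwise_p_uniformish_under_null(self, null_pair):
        gt, grouping = null_pair
        res = st.pairwise_fst(gt, grouping, n_perm=99, rng=0)
        p = res.fst_p.iloc[0, 1]
        assert 0.01 <= p <= 1.0

    def test_negative_theta_not_truncated(self):
        # tiny balanced sample engineered to give a negative estimate
        calls = np.array([[[1, 1]], [[2, 2]], [[1, 2]], [[1, 2]]])
        gt = GenotypeTable(["a", "b", "c", "d"], ["L1"], calls)
        theta = st.weir_cockerham_theta(gt, ["A", "A", "B", "B"])
        assert theta < 0


class TestBootstrapCI:
    def test_ci_to_se_formula(self):
        assert st.ci_to_se(0.10, 0.30) == pytest.approx(0.05102, abs=1e-5)
        assert st.ci_to_se(0.2, 0.2) == 0.0

    def test_ci_width_over_se_is_392(self):
        theta, (lo, hi), se = st.fst_bootstrap_ci(
            *_sim_pair(), n_boot=200, rng=3
        )
        assert (hi - lo) / se == pytest.approx(3.92)
        assert lo <= theta <= hi

    def test_single_locus_errors(self):
        cfg = SynthConfig(group_sizes=(10, 10), n_groups=2, n_loci=1,
                          depth_per_group=(40.0, 120.0), seed=0)
        gt, frame = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="loci"):
            st.fst_bootstrap_ci(gt, frame["group"], n_boot=10, rng=0)


def _sim_pair():
    cfg = SynthConfig(group_sizes=(60, 60), n_groups=2, n_loci=8,
                      target_fst=0.05, depth_per_group=(40.0, 120.0), seed=21)
    gt, frame = simulate_genotypes(cfg)
    return gt, frame["group"].to_numpy()


class TestJostD:
    def test_identical_frequencies_give_near_zero(self, null_pair):
        gt, grouping = null_pair
        d, _ = st.jost_d(gt, grouping, n_boot=0, rng=0)
        assert abs(d) < 0.02

    def test_disjoint_alleles_approach_one(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 6, size=(150, 3, 2))
        b = rng.integers(6, 11, size=(150, 3, 2))
        gt = GenotypeTable(
            [f"i{k}" for k in range(300)],
            ["L1", "L2", "L3"],
            np.concatenate([a, b]),
        )
        d, _ = st.jost_d(gt, ["A"] * 150 + ["B"] * 150, n_boot=0)
        assert d > 0.95

    def test_hand_set_matches_formula_oracle(self, hand_gt, hand_groups):
        d, _ = st.jost_d(hand_gt, hand_groups, n_boot=0)
        assert d == pytest.approx(
            brute_force_dest(hand_gt, hand_groups), abs=1e-12
        )

    def test_structured_pair_significant(self):
        gt, grouping = _sim_pair()
        res = st.pairwise_jost_d(gt, grouping, n_boot=99, rng=5)
        assert res.d.iloc[0, 1] > 0
        assert res.d_p.iloc[0, 1] < 0.05


class TestAmova:
    def test_component_conservation(self):
        gt, grouping = _sim_pair()
        res = st.amova(gt, grouping, n_perm=49, rng=0)
        # among + within SS recompose the total SS of the distance matrix
        d2 = st.genotype_distance_matrix(gt)
        n = d2.shape[0]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        assert res.ss_among + res.ss_within == pytest.approx(ss_total, rel=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)
        assert res.df_among == 1

    def test_structured_simulation_detected(self):
        gt, grouping = _sim_pair()
        res = st.amova(gt, grouping, n_perm=99, rng=1)
        assert res.fct > 0
        assert res.p_value <= 0.05

    def test_single_group_source_rejected(self):
        gt, _ = _sim_pair()
        with pytest.raises(ValueError, match="fewer than two groups"):
            st.amova(gt, ["only"] * gt.n_individuals, n_perm=9)

    def test_ranking_puts_structured_factor_first(self):
        cfg = SynthConfig(group_sizes=(60, 60, 60), n_loci=10,
                          target_fst=0.02, seed=13)
        gt, frame = simulate_genotypes(cfg)
        frame = frame.rename(columns={"group": "stratum_true"})
        frame["stratum"] = frame["stratum_true"]
        table = st.amova_rank(
            gt, frame, factors=("ecotype", "zone", "stratum"),
            crossings=False, n_perm=99, rng=2,
        )
        assert table.iloc[0]["source"] == "stratum"
        assert table.iloc[0]["significant"]
        eco = table[table["source"] == "ecotype"].iloc[0]
        assert not eco["significant"]

    def test_crossing_degrees_of_freedom_drop_empty_cells(self):
        gt, _ = _sim_pair()
        # crossing with an empty cell: 2 x 2 design missing one combination
        labels = ["a|x"] * 40 + ["a|y"] * 40 + ["b|x"] * 40
        res = st.amova(gt, labels, n_perm=9, rng=0)
        assert res.df_among == 2  # 3 non-empty cells - 1


class TestMantel:
    def test_self_correlation_is_one(self):
        d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        res = st.mantel(d, d, n_perm=99)
        assert res.r_m == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.random((4, 4))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        B = rng.random((4, 4))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        res = st.mantel(A, B)
        assert res.exact and res.n_perm == 24
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
        hits = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            r_p = np.corrcoef(A[iu], B[np.ix_(p, p)][iu])[0, 1]
            if r_p >= r_obs - 1e-15:
                hits += 1
        assert res.p_value == pytest.approx(hits / 24, abs=1e-12)

    def test_matches_skbio_r_statistic(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(3)
        X = rng.random((8, 2))
        A = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        Y = X + rng.normal(0, 0.2, X.shape)
        B = np.sqrt(((Y[:, None] - Y[None, :]) ** 2).sum(-1))
        ours = st.mantel(A, B, n_perm=499, rng=0)
        r_sk = sk_mantel(
            DistanceMatrix(A), DistanceMatrix(B), permutations=0
        )[0]
        assert ours.r_m == pytest.approx(float(r_sk), abs=1e-10)

    def test_outlier_interpolation_replaces_named_point(self):
        # a cline with one wrecked point: interpolating it restores the
        # correlation; the switch changes nothing unless a point is named
        x = np.arange(5.0)
        A = np.abs(np.subtract.outer(x, x))
        B = A.copy()
        B[2, :] = B[:, 2] = [3.0, 3.0, 0.0, 3.0, 3.0]
        raw = st.mantel(A, B, n_perm=99, rng=0)
        fixed = st.mantel(A, B, n_perm=99, rng=0, interpolate_index=2)
        assert fixed.r_m > raw.r_m
        default = st.mantel(A, B, n_perm=99, rng=0, interpolate_index=None)
        assert default.r_m == raw.r_m

    def test_too_few_points_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="three points"):
            st.mantel(d, d)

    def test_depth_cline_detected(self):
        cfg = SynthConfig(
            n_groups=6,
            group_sizes=(50,) * 6,
            n_loci=12,
            target_fst=0.03,
            structure_model="cline",
            depth_per_group=(40.0, 50.0, 80.0, 90.0, 100.0, 125.0),
            seed=17,
        )
        gt, frame = simulate_genotypes(cfg)
        theta = st.pairwise_fst(gt, frame["group"], n_perm=0).fst
        gen = st.linearized(theta.to_numpy())
        depths = np.array([40.0, 50.0, 80.0, 90.0, 100.0, 125.0])
        depth_d = np.abs(depths[:, None] - depths[None, :])
        res = st.mantel(depth_d, gen)
        assert res.r_m > 0
        assert res.p_value < 0.05


class TestPcoa:
    def test_identical_individuals_flagged_degenerate(self):
        calls = np.tile(np.array([[1, 2], [3, 3]]), (5, 1, 1)).reshape(5, 2, 2)
        gt = GenotypeTable([f"i{k}" for k in range(5)], ["L1", "L2"], calls)
        res = st.pcoa_individuals(gt)
        assert res.degenerate

    def test_distances_reconstructed_from_coordinates(self):
        gt, _ = _sim_pair()
        sub = gt.subset_individuals(np.arange(gt.n_individuals) < 25)
        res = st.pcoa_individuals(sub)
        d2 = st.genotype_distance_matrix(sub)
        C = res.coordinates
        recon = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1)
        assert np.allclose(recon, d2, atol=1e-8)

    def test_unstructured_axes_explain_little(self):
        cfg = SynthConfig(group_sizes=(100, 100, 100), target_fst=0.0, seed=23)
        gt, _ = simulate_genotypes(cfg)
        res = st.pcoa_individuals(gt)
        assert res.prop_explained[0] < 0.10
        assert res.prop_explained[1] < 0.10
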