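"""Scoring-family unit tests with independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

import icbbench as ib
from icbbench.cohort_io import Cohort, validate_clinical_table
from icbbench.scoring_engine import gsva_kernel_cdf, score_gsva_set
from icbbench.signature_registry import SignatureDefinition


def _cohort_from(expr, external=None):
    clin = validate_clinical_table(pd.DataFrame({
        "sample_id": list(expr.columns), "dataset_id": "d", "recist": "PR",
        "os_time": 1.0, "os_event": 1, "pfs_time": 1.0, "pfs_event": 1,
    }))
    return Cohort(expression=expr, clinical=clin, external_scores=external)


def _mean_sig(genes, sid="sig"):
    return SignatureDefinition(sid, "effector", "mean", 1, genes=list(genes))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ssgsea_oracle(values, genes, gene_set, alpha):
    """Step-by-step ssGSEA walk, written independently of the engine."""
    n = len(genes)
    ranks = rankdata(values, method="average")  # top-expressed gene gets rank n
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    in_set = [genes[i] in gene_set for i in order]
    n_out = n - sum(in_set)
    w = [ranks[i] ** alpha for i in order]
    w_sum = sum(wi for wi, hit in zip(w, in_set) if hit)
    walk, total = 0.0, 0.0
    for wi, hit in zip(w, in_set):
        walk += wi / w_sum if hit else -1.0 / n_out
        total += walk
    return total


def gsva_oracle(expr, gene_set):
    """Kernel-CDF statistic + max-deviation walk, computed by explicit loops."""
    genes = list(expr.index)
    vals = expr.to_numpy(float)
    n_genes, n_samp = vals.shape
    stat = np.zeros_like(vals)
    for i in range(n_genes):
        row = vals[i]
        nn = len(row)
        sd = row.std(ddof=1)
        iqr = np.percentile(row, 75) - np.percentile(row, 25)
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = 0.9 * spread * nn ** (-0.2)
        h = h if h > 0 else 1e-8
        for j in range(n_samp):
            stat[i, j] = np.mean([norm.cdf((row[j] - xk) / h) for xk in row])
    out = []
    for j in range(n_samp):
        ranks = rankdata(stat[:, j], method="average")
        order = sorted(range(n_genes), key=lambda i: (-ranks[i], i))
        in_set = [genes[i] in gene_set for i in order]
        n_out = n_genes - sum(in_set)
        w_sum = sum(ranks[i] for i, hit in zip(order, in_set) if hit)
        walk, best = 0.0, 0.0
        for i, hit in zip(order, in_set):
            walk += ranks[i] / w_sum if hit else -1.0 / n_out
            if abs(walk) > abs(best):
                best = walk
        out.append(best)
    return np.array(out)


# ---------------------------------------------------------------------------
# simple families
# ---------------------------------------------------------------------------

class TestSimpleFamilies:
    def test_single_gene_identity(self, small_expr):
        out = ib.score_single_gene(small_expr, "G3")
        assert (out == small_expr.loc["G3"]).all()

    def test_mean_trivial_and_reduction(self):
        expr = pd.DataFrame([[2.0], [4.0]], index=["A", "B"], columns=["s"])
        assert ib.score_mean_signature(expr, _mean_sig(["A", "B"]))["s"] == 3.0
        single = ib.score_mean_signature(expr, _mean_sig(["A"]))
        assert (single == ib.score_single_gene(expr, "A")).all()

    def test_mean_matches_brute_force(self, small_expr, rng):
        genes = list(rng.choice(small_expr.index, 6, replace=False))
        out = ib.score_mean_signature(small_expr, _mean_sig(genes))
        for s in small_expr.columns:
            manual = sum(small_expr.loc[g, s] for g in genes) / len(genes)
            assert abs(out[s] - manual) < 1e-12

    def test_weighted_sum(self, small_expr, rng):
        genes = ["G0", "G1"]
        expr = pd.DataFrame([[2.0], [4.0]], index=genes, columns=["s"])
        sig = SignatureDefinition("w", "effector", "weighted_sum", 1,
                                  genes=genes, weights=[1.0, 1.0])
        assert ib.score_weighted_sum(expr, sig)["s"] == 6.0
        sig.weights = [0.0, 0.0]
        assert (ib.score_weighted_sum(expr, sig) == 0).all()
        w = rng.normal(size=5)
        genes5 = list(small_expr.index[:5])
        sig5 = SignatureDefinition("w5", "effector", "weighted_sum", 1,
                                   genes=genes5, weights=list(w))
        out = ib.score_weighted_sum(small_expr, sig5)
        manual = small_expr.loc[genes5].T @ w
        assert np.abs(out - manual).max() < 1e-12

    def test_up_down(self, small_expr):
        sig = SignatureDefinition("ud", "immune_resistance", "up_down", -1,
                                  gene_sets={"up": ["G0", "G1"], "down": ["G2"]})
        centered = small_expr.sub(small_expr.mean(axis=1), axis=0)
        manual = centered.loc[["G0", "G1"]].mean() - centered.loc["G2"]
        out = ib.score_up_down(small_expr, sig)
        assert np.abs(out - manual).max() < 1e-12
        same = SignatureDefinition("ud2", "immune_resistance", "up_down", -1,
                                   gene_sets={"up": ["G0"], "down": ["G0"]})
        assert np.abs(ib.score_up_down(small_expr, same)).max() == 0.0

    def test_mcp_marker_means(self):
        expr = pd.DataFrame([[1.0], [3.0]], index=["M1", "M2"], columns=["s"])
        out = ib.score_mcp(expr, {"pop": ["M1", "M2"]})
        assert out.loc["pop", "s"] == 2.0
        # duplicated marker weighs 2/(k+1)
        dup = ib.score_mcp(expr, {"pop": ["M1", "M1", "M2"]})
        assert dup.loc["pop", "s"] == pytest.approx((2 * 1.0 + 3.0) / 3)

    def test_mcp_ten_populations(self, registry, planted_cohort):
        markers = {s.id: s.genes for s in registry.values() if s.method == "mcp"}
        out = ib.score_mcp(planted_cohort.expression, markers)
        assert out.shape[0] == 10


class TestImpres:
    def test_bounds_and_tie_rule(self):
        pairs = [("A", "B"), ("C", "D")]
        expr = pd.DataFrame({"s1": [5, 1, 2, 2], "s2": [1, 5, 1, 2]},
                            index=["A", "B", "C", "D"], dtype=float)
        out = ib.score_impres(expr, pairs)
        assert out["s1"] == 1  # A>B yes, C=D tie contributes 0
        assert out["s2"] == 0

    def test_all_pairs_satisfied_hits_max(self, registry):
        sig = registry["IMPRES"]
        genes = sig.all_genes
        # order expression so every (g1, g2) pair satisfies g1 > g2
        rank = {}
        for g1, g2 in sig.pairs:
            rank.setdefault(g1, 0)
            rank.setdefault(g2, 0)
        for _ in range(len(genes)):
            for g1, g2 in sig.pairs:
                rank[g1] = max(rank[g1], rank[g2] + 1)
        expr = pd.DataFrame({"s": [float(rank[g]) for g in genes]}, index=genes)
        out = ib.score_impres(expr, sig.pairs)
        assert out["s"] == len(sig.pairs) == 15

    def test_matches_loop_oracle_and_rank_invariance(self, registry, rng):
        sig = registry["IMPRES"]
        genes = sig.all_genes
        for _ in range(20):
            expr = pd.DataFrame(rng.uniform(0, 8, size=(len(genes), 5)),
                                index=genes, columns=list("abcde"))
            out = ib.score_impres(expr, sig.pairs)
            for s in expr.columns:
                manual = sum(expr.loc[g1, s] > expr.loc[g2, s] for g1, g2 in sig.pairs)
                assert out[s] == manual
            assert ((out >= 0) & (out <= 15)).all()
            transformed = expr**3 + 2.0  # strictly increasing on positives
            assert (ib.score_impres(transformed, sig.pairs) == out).all()


class TestSsgsea:
    def test_singleton_rank_monotonicity(self, small_expr):
        col = small_expr.iloc[:, [0]]
        top = col.iloc[:, 0].idxmax()
        bottom = col.iloc[:, 0].idxmin()
        es_top = ib.score_ssgsea(col, [top]).iloc[0]
        es_bottom = ib.score_ssgsea(col, [bottom]).iloc[0]
        assert es_top > es_bottom

    def test_matches_hand_walk(self, rng):
        genes = ["A", "B", "C", "D"]
        params = ib.EnrichmentParams()
        for _ in range(30):
            expr = pd.DataFrame(rng.uniform(0, 6, size=(4, 3)), index=genes,
                                columns=["s1", "s2", "s3"])
            out = ib.score_ssgsea(expr, ["A", "C"], params)
            for j, s in enumerate(expr.columns):
                expected = ssgsea_oracle(expr[s].to_numpy(), genes, {"A", "C"},
                                         params.rank_weight_exponent)
                assert out[s] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, small_expr):
        base = ib.score_ssgsea(small_expr, ["G1", "G4", "G7"])
        cubed = ib.score_ssgsea(small_expr**3, ["G1", "G4", "G7"])
        assert np.abs(base - cubed).max() < 1e-12

    def test_set_equal_to_universe_rejected(self, small_expr):
        with pytest.raises(ValueError):
            ib.score_ssgsea(small_expr, list(small_expr.index))


class TestTis:
    def test_identical_samples_identical_scores(self, small_expr):
        expr = pd.concat([small_expr.iloc[:, [0]]] * 2, axis=1)
        expr.columns = ["a", "b"]
        expr["c"] = small_expr.iloc[:, 1].to_numpy()
        out = ib.score_tis(expr, {"s1": ["G0", "G1"], "s2": ["G2"]})
        assert out["a"] == pytest.approx(out["b"], abs=1e-12)

    def test_sample_mean_zero(self, small_expr):
        out = ib.score_tis(small_expr, {"s1": ["G0", "G1"], "s2": ["G2", "G5"]})
        assert abs(out.mean()) < 1e-12

    def test_matches_manual_composition(self, small_expr):
        subsets = {"s1": ["G0", "G1"], "s2": ["G2", "G5"], "s3": ["G7"]}
        es = pd.DataFrame({k: ib.score_ssgsea(small_expr, v) for k, v in subsets.items()}).T
        z, _ = ib.z_score_genes(es)
        manual = z.mean(axis=0)
        out = ib.score_tis(small_expr, subsets)
        assert np.abs(out - manual).max() < 1e-12

    def test_incomplete_subset_gives_missing(self, small_expr):
        out = ib.score_tis(small_expr, {"s1": ["G0"], "s2": ["NOT_THERE"]})
        assert out.isna().all()


class TestGsva:
    def test_matches_hand_computation(self, rng):
        genes = [f"g{i}" for i in range(5)]
        expr = pd.DataFrame(rng.uniform(1, 7, size=(5, 3)), index=genes,
                            columns=["s1", "s2", "s3"])
        gene_set = {"g0", "g2"}
        expected = gsva_oracle(expr, gene_set)
        out = score_gsva_set(gsva_kernel_cdf(expr), list(gene_set))
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-10)

    def test_high_expressing_sample_scores_highest(self, rng):
        genes = [f"g{i}" for i in range(12)]
        expr = pd.DataFrame(rng.normal(4, 1, size=(12, 5)), index=genes)
        expr.iloc[:4, 2] += 5.0  # sample 2 maximal in the set genes
        out = ib.score_gsva_mean(expr, {"set": genes[:4]})
        assert out.idxmax() == expr.columns[2]

    def test_location_shift_of_one_gene_invariant(self, small_expr):
        collection = {"set": ["G1", "G4"]}
        base = ib.score_gsva_mean(small_expr, collection)
        shifted = small_expr.copy()
        shifted.loc["G7"] += 100.0
        out = ib.score_gsva_mean(shifted, collection)
        np.testing.assert_allclose(out.to_numpy(), base.to_numpy(), atol=1e-9)

    def test_single_sample_rejected(self, small_expr):
        with pytest.raises(ValueError):
            ib.score_gsva_mean(small_expr.iloc[:, [0]], {"set": ["G1"]})


class TestPc1:
    def _sig(self, genes):
        return SignatureDefinition("pc", "immune_resistance", "pc1", -1, genes=genes)

    def test_rank_one_case_positively_oriented(self, rng):
        profile = rng.uniform(1, 5, size=8)
        expr = pd.DataFrame([profile, 2 * profile + 1], index=["A", "B"],
                            columns=[f"s{i}" for i in range(8)])
        out = ib.score_pc1(expr, self._sig(["A", "B"]))
        r = np.corrcoef(out, profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_scores_centered(self, small_expr):
        out = ib.score_pc1(small_expr, self._sig(list(small_expr.index[:5])))
        assert abs(out.mean()) < 1e-10

    def test_pc1_variance_dominates_random_projections(self, small_expr, rng):
        genes = list(small_expr.index[:6])
        out = ib.score_pc1(small_expr, self._sig(genes))
        z, _ = ib.z_score_genes(small_expr.loc[genes])
        data = z.to_numpy().T
        var_pc1 = out.var(ddof=0)
        for _ in range(1000):
            u = rng.normal(size=len(genes))
            u /= np.linalg.norm(u)
            assert var_pc1 >= (data @ u).var(ddof=0) - 1e-10

    def test_all_constant_rejected(self):
        expr = pd.DataFrame(np.ones((2, 4)), index=["A", "B"])
        with pytest.raises(ValueError):
            ib.score_pc1(expr, self._sig(["A", "B"]))


class TestIps:
    COMPONENTS = [
        {"name": "mhc", "category": "MHC", "weight": 1, "genes": ["A"]},
        {"name": "ec", "category": "EC", "weight": 1, "genes": ["B"]},
        {"name": "sc", "category": "SC", "weight": -1, "genes": ["C"]},
        {"name": "cp", "category": "CP", "weight": 1, "genes": ["D"]},
    ]

    def _expr(self, col1, col2):
        return pd.DataFrame(np.column_stack([col1, col2]),
                            index=["A", "B", "C", "D"], columns=["s1", "s2"])

    def test_clamps(self):
        # two samples: z-scores are +-1; s1 gets aggregate +1, s2 gets -1 -> 0
        expr = self._expr([2, 2, 0, 2], [0, 0, 2, 0])
        out = ib.score_ips(expr, self.COMPONENTS)
        assert out["s2"] == 0.0

    def test_affine_map_mid_range(self):
        # aggregate for s1: mean(+1, +1, -(-1), +1) = 1 -> 10/3
        expr = self._expr([2, 2, 0, 2], [0, 0, 2, 0])
        out = ib.score_ips(expr, self.COMPONENTS)
        assert out["s1"] == pytest.approx(10.0 / 3.0, abs=1e-12)

    def test_range_on_random_data(self, rng, registry):
        sig = registry["IPS"]
        genes = sig.all_genes
        expr = pd.DataFrame(rng.uniform(0, 8, size=(len(genes), 20)), index=genes)
        out = ib.score_ips(expr, sig.components)
        assert ((out >= 0) & (out <= 10)).all()

    def test_missing_category_rejected(self, small_expr):
        with pytest.raises(Exception):
            ib.score_ips(small_expr, self.COMPONENTS[:3])


class TestScoreAll:
    def test_full_coverage_only_external_missing(self, registry, planted_cohort):
        scores, coverage = ib.score_all(planted_cohort, registry)
        missing = set(scores.index[scores.isna().all(axis=1)])
        assert missing == {"CIBERSORT.CD8", "TIDE"}
        assert all(coverage[s]["evaluable"] for s in registry if s not in missing)

    def test_external_columns_passed_through(self, registry, planted_cohort):
        ext = pd.DataFrame(
            {"cibersort_cd8": 0.1, "tide": -0.3},
            index=planted_cohort.expression.columns)
        cohort = Cohort(planted_cohort.expression, planted_cohort.clinical, ext)
        scores, _ = ib.score_all(cohort, registry)
        assert (scores.loc["CIBERSORT.CD8"] == 0.1).all()
        assert (scores.loc["TIDE"] == -0.3).all()

    def test_missing_gene_blocks_signature(self, registry, planted_cohort):
        expr = planted_cohort.expression.drop(index="CD8B")
        cohort = Cohort(expr, planted_cohort.clinical)
        scores, coverage = ib.score_all(cohort, registry)
        assert scores.loc["gene.CD8"].isna().all()
        assert not coverage["gene.CD8"]["evaluable"]

    def test_deterministic_rerun(self, registry, planted_cohort):
        s1, _ = ib.score_all(planted_cohort, registry)
        s2, _ = ib.score_all(planted_cohort, registry)
        assert s1.equals(s2)

    def test_permutation_equivariance_all_families(self, registry, planted_cohort, rng):
        scores, _ = ib.score_all(planted_cohort, registry)
        perm = rng.permutation(planted_cohort.expression.shape[1])
        cols = planted_cohort.expression.columns[perm]
        shuffled = Cohort(planted_cohort.expression[cols],
                          planted_cohort.clinical.loc[cols])
        scores_p, _ = ib.score_all(shuffled, registry)
        pd.testing.assert_frame_equal(scores[cols], scores_p)

    def test_mean_families_not_rank_invariant(self, small_expr):
        sig = _mean_sig(["G0", "G1", "G2"])
        base = ib.score_mean_signature(small_expr, sig)
        cubed = ib.score_mean_signature(small_expr**3, sig)
        assert np.abs(base - cubed).max() > 1e-6


def test_score_matrix_round_trip(registry, planted_cohort, tmp_path):
    scores, coverage = ib.score_all(planted_cohort, registry)
    path = tmp_path / "scores.tsv"
    ib.write_score_matrix(scores, path, coverage)
    back = ib.read_score_matrix(path)
    pd.testing.assert_frame_equal(back, scores, check_exact=True)
    assert "NA" in path.read_text()
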