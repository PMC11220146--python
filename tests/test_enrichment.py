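"""Preranked enrichment, gene-list correlations, fraction comparisons."""

import numpy as np
import pandas as pd
import pytest

from pathoscore.enrichment import (
    GeneSet,
    compare_fractions,
    genelist_correlations,
    gsea_es,
    gsea_permutation,
    rank_genes,
    read_gmt,
    write_gmt,
)
from pathoscore.synthetic import CohortConfig, generate_cohort


def running_sum_oracle(genes, metrics, members, p):
    """Step-by-step enumeration of the weighted KS running sum."""
    hits = [g in members for g in genes]
    n, n_hit = len(genes), sum(hits)
    denom = sum(abs(m) ** p for g, m in zip(genes, metrics) if g in members)
    total, path = 0.0, []
    for g, m, h in zip(genes, metrics, hits):
        if h:
            total += (abs(m) ** p) / denom if denom else 1 / n_hit
        else:
            total -= 1 / (n - n_hit)
        path.append(total)
    es = max(path, key=abs)
    return es, path


def ranked_frame(genes, metrics):
    return pd.DataFrame({"gene": genes, "metric": metrics})


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("A", "first", ["g1", "g2"]),
                GeneSet("B", "second", ["g3", "g4", "g5"])]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.name, s.members) for s in back] == \
            [(s.name, s.members) for s in sets]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("bad", "", [])


class TestRankGenes:
    def _expr(self, rng, n_pat=20):
        ps = pd.Series(rng.random(n_pat),
                       index=[f"P{i}" for i in range(n_pat)])
        expr = pd.DataFrame(rng.normal(size=(5, n_pat)),
                            index=[f"G{i}" for i in range(5)],
                            columns=ps.index)
        return expr, ps

    def test_score_copy_ranked_first_negation_last(self, rng):
        expr, ps = self._expr(rng)
        expr.loc["G0"] = ps.to_numpy()
        expr.loc["G4"] = -ps.to_numpy()
        ranked = rank_genes(expr, ps)
        assert ranked["gene"].iloc[0] == "G0"
        assert ranked["metric"].iloc[0] == pytest.approx(1.0)
        assert ranked["gene"].iloc[-1] == "G4"
        assert ranked["metric"].iloc[-1] == pytest.approx(-1.0)

    def test_matches_scipy_per_gene(self, rng):
        from scipy import stats

        expr, ps = self._expr(rng)
        ranked = rank_genes(expr, ps).set_index("gene")
        for g in expr.index:
            rho = stats.spearmanr(expr.loc[g], ps).statistic
            assert ranked.loc[g, "metric"] == pytest.approx(rho)

    def test_duplicate_symbols_keep_highest_variance(self, rng):
        expr, ps = self._expr(rng)
        dup = pd.DataFrame([np.zeros(20) + 0.001 * rng.normal(size=20)],
                           index=["G0"], columns=ps.index)
        stacked = pd.concat([expr, dup])
        ranked = rank_genes(stacked, ps)
        assert (ranked["gene"] == "G0").sum() == 1

    def test_too_few_shared_patients(self, rng):
        expr, ps = self._expr(rng)
        with pytest.raises(ValueError):
            rank_genes(expr[expr.columns[:2]], ps[ps.index[:2]])


class TestEnrichmentScore:
    def test_whole_universe_set_scores_one(self, rng):
        genes = [f"G{i}" for i in range(20)]
        ranked = ranked_frame(genes, np.linspace(2, -2, 20))
        es, running = gsea_es(ranked, GeneSet("all", "", genes))
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_matches_running_sum_enumeration(self, p, rng):
        genes = [f"G{i}" for i in range(50)]
        metrics = np.sort(rng.normal(size=50))[::-1]
        ranked = ranked_frame(genes, metrics)
        for seed in range(5):
            members = list(np.random.default_rng(seed).choice(genes, 8,
                                                              replace=False))
            es, running = gsea_es(ranked, GeneSet("s", "", members), p=p)
            es_o, path_o = running_sum_oracle(genes, metrics, set(members), p)
            assert es == pytest.approx(es_o)
            assert np.allclose(running, path_o)
            assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_top_k_set_unweighted_hand_value(self):
        genes = [f"G{i}" for i in range(10)]
        ranked = ranked_frame(genes, np.linspace(1, 0.1, 10))
        es, _ = gsea_es(ranked, GeneSet("top", "", genes[:3]), p=0.0)
        assert es == pytest.approx(1 - 0 / 7)  # peak right after the 3rd hit

    def test_reversal_antisymmetry_unweighted(self, rng):
        genes = [f"G{i}" for i in range(30)]
        metrics = np.linspace(3, -3, 30)
        members = list(rng.choice(genes, 6, replace=False))
        es_f, _ = gsea_es(ranked_frame(genes, metrics),
                          GeneSet("s", "", members), p=0.0)
        es_r, _ = gsea_es(ranked_frame(genes[::-1], metrics[::-1]),
                          GeneSet("s", "", members), p=0.0)
        assert es_f == pytest.approx(-es_r)

    def test_no_overlap_raises(self):
        ranked = ranked_frame(["G1"], [1.0])
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("s", "", ["ZZZ"]))


class TestPermutation:
    def _cohort_ranked(self, seed):
        cfg = CohortConfig(n_patients=60, seed=seed)
        cohort = generate_cohort(cfg)
        clin = cohort.clinical_table().set_index("patient_id")
        ps = clin["marker"]  # score surrogate correlated with the planted set
        ranked = rank_genes(cohort.expression, ps)
        return ranked, cohort.gene_sets

    def test_planted_set_detected_decoys_null(self):
        ranked, sets = self._cohort_ranked(seed=1)
        res = gsea_permutation(ranked, sets, n_perm=500, seed=0)
        planted = res[res["set"] == "PLANTED_SIGNAL"].iloc[0]
        assert planted["NES"] > 0 and planted["p"] < 0.05
        decoys = res[res["set"] != "PLANTED_SIGNAL"]
        assert decoys["p"].min() > 0.01
        assert planted["significant"]

    def test_planted_set_wins_across_seeds(self):
        wins = 0
        for seed in range(10):
            ranked, sets = self._cohort_ranked(seed=seed)
            res = gsea_permutation(ranked, sets, n_perm=200, seed=seed)
            best = res.sort_values(["p", "set"]).iloc[0]
            wins += best["set"] == "PLANTED_SIGNAL"
        assert wins >= 9

    def test_reproducible_and_order_invariant(self):
        ranked, sets = self._cohort_ranked(seed=2)
        r1 = gsea_permutation(ranked, sets, n_perm=100, seed=9)
        r2 = gsea_permutation(ranked, list(reversed(sets)), n_perm=100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)


class TestGenelistCorrelations:
    def test_score_copy_and_exact_small_sample_p(self, rng):
        pats = [f"P{i}" for i in range(5)]
        ps = pd.Series([0.1, 0.3, 0.5, 0.7, 0.9], index=pats)
        expr = pd.DataFrame({p: [ps[p], rng.normal()] for p in pats},
                            index=["COPY", "RAND"])
        out = genelist_correlations(ps, expr, ["COPY", "RAND", "MISSING"])
        assert list(out["gene"]) == ["COPY", "RAND"]
        copy = out.set_index("gene").loc["COPY"]
        assert copy["rho"] == pytest.approx(1.0)
        # of 120 rank permutations only identity and reversal reach |rho| = 1
        assert copy["p"] == pytest.approx(2 / 120)

    def test_bh_adjustment_contract(self, rng):
        pats = [f"P{i}" for i in range(30)]
        ps = pd.Series(rng.random(30), index=pats)
        expr = pd.DataFrame(rng.normal(size=(6, 30)),
                            index=[f"G{i}" for i in range(6)], columns=pats)
        out = genelist_correlations(ps, expr, list(expr.index))
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        merged = out.sort_values("p")
        assert merged["p_adj"].cummax().equals(merged["p_adj"])


class TestCompareFractions:
    def _table(self, rng, n=40, k=4):
        raw = rng.random((n, k))
        frac = raw / raw.sum(axis=1, keepdims=True)
        return pd.DataFrame(frac, columns=[f"cell_{i}" for i in range(k)])

    def test_identical_groups_null(self, rng):
        frac = self._table(rng)
        doubled = pd.concat([frac, frac], ignore_index=True)
        groups = np.r_[np.zeros(40), np.ones(40)]
        out = compare_fractions(doubled, groups)
        assert (out["p"] > 0.9).all()

    def test_planted_shift_has_minimal_p(self, rng):
        frac = self._table(rng, n=60)
        groups = np.r_[np.zeros(30), np.ones(30)]
        shifted = frac.copy()
        shifted.loc[groups == 1, "cell_0"] += 0.2
        shifted = shifted.div(shifted.sum(axis=1), axis=0)
        out = compare_fractions(shifted, groups).set_index("cell_type")
        assert out["p"].idxmin() == "cell_0"

    def test_row_sum_validation(self, rng):
        frac = self._table(rng) * 0.5
        with pytest.raises(ValueError, match="sum"):
            compare_fractions(frac, np.r_[np.zeros(20), np.ones(20)])
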