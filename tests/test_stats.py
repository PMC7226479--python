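"""Nonparametric tests checked against exhaustive enumeration oracles,
plus the correlation, fold-change and enrichment utilities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import fetoquant as fq
from fetoquant import stats as gs
from fetoquant.errors import ValidationError


def _kw_h(groups):
    """Independent rank-sum formula H = 12/(N(N+1)) sum R_g^2/n_g - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    ties = pd.Series(pooled).value_counts().to_numpy()
    correction = 1 - (np.sum(ties ** 3 - ties)
                      / (n_total ** 3 - n_total))
    return h / correction if correction > 0 else 0.0


class TestKruskalWallis:
    def test_perfectly_separated_triples(self):
        res = fq.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6],
                                 "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(
            float(sps.chi2.sf(7.2, 2)), rel=1e-12)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 10)) for _ in range(4)]
            res = fq.kruskal_wallis({f"g{i}": g
                                     for i, g in enumerate(groups)})
            assert res.statistic == pytest.approx(_kw_h(groups), abs=1e-10)

    def test_all_equal_values_give_h_zero_p_one(self):
        res = fq.kruskal_wallis({"a": [5, 5], "b": [5, 5, 5]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi2_close_to_exhaustive_permutation_small_n(self):
        groups = [[1.0, 2.0, 7.0], [3.0, 8.0], [4.0, 9.0, 10.0]]
        res = fq.kruskal_wallis({"a": groups[0], "b": groups[1],
                                 "c": groups[2]})
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = total = 0
        for perm in itertools.permutations(pooled):
            regrouped, start = [], 0
            for s in sizes:
                regrouped.append(np.array(perm[start:start + s]))
                start += s
            total += 1
            if _kw_h(regrouped) >= res.statistic - 1e-9:
                count += 1
        p_exact = count / total
        assert abs(res.p_value - p_exact) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            fq.kruskal_wallis({"a": [1.0], "b": []})


def _mw_exact_p(a, b):
    """Two-sided exact p by enumerating all C(n, |a|) rank assignments."""
    pooled = sorted(a) + sorted(b)
    n = len(pooled)
    obs_u = _mw_u(a, b)
    n_a = len(a)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(n) if i not in idx]
        u = _mw_u(aa, bb)
        total += 1
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-9:
            count += 1
    return count / total


def _mw_u(a, b):
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        res = fq.mann_whitney([1, 2, 3], [4, 5, 6])
        assert min(res.statistic, 9 - res.statistic) == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_multisets_p_one(self):
        res = fq.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a n_b / 2
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.permutation(20)[: rng.integers(3, 6)].astype(float))
        b = list(rng.permutation(40)[: rng.integers(3, 6)].astype(float)
                 + 100.5 * rng.integers(0, 2))
        if set(a) & set(b):
            b = [x + 0.25 for x in b]
        res = fq.mann_whitney(a, b)
        assert res.p_value == pytest.approx(_mw_exact_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            fq.mann_whitney([], [1.0])


def _fisher_two_sided(table):
    """Enumerate all tables with the observed margins; sum probabilities
    no larger than the observed table's hypergeometric probability."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = sps.hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisherExact:
    def test_diagonal_three_three(self):
        res = fq.fisher_exact_2x2([[3, 0], [0, 3]])
        assert res.p_value == pytest.approx(0.1)  # 2 x 1/20

    def test_flat_table_no_association(self):
        assert fq.fisher_exact_2x2([[1, 1], [1, 1]]).p_value == 1.0

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            table = rng.integers(0, 7, size=(2, 2))
            res = fq.fisher_exact_2x2(table.tolist())
            assert res.p_value == pytest.approx(
                _fisher_two_sided(table), abs=1e-10)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fq.fisher_exact_2x2([[1, -1], [0, 2]])


def _kendall_pairs(x, y):
    """O(n^2) concordant/discordant pair counting, tau-b tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


class TestRankCorrelations:
    def test_strictly_increasing(self):
        rho, tau = fq.rank_correlations([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert tau == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        rho, tau = fq.rank_correlations([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert tau == pytest.approx(-1.0)

    def test_tau_b_matches_pair_counting_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        _, tau = fq.rank_correlations(x, y)
        assert tau == pytest.approx(_kendall_pairs(x, y), abs=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            fq.rank_correlations([1, 2], [3, 4])


class TestFoldChange:
    def test_published_crp_elevation(self):
        # fetopathy-group CRP mean over control mean
        assert fq.fold_change(5.29, 1.97) == pytest.approx(5.29 / 1.97)
        assert fq.fold_change(5.29, 1.97) >= 2.0

    def test_equal_means_give_unity(self):
        assert fq.fold_change(3.3, 3.3) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            fq.fold_change(1.0, 0.0)


class TestOverrepresentation:
    def test_term_annotating_everything_is_unenriched(self):
        study = {f"P{i}" for i in range(10)}
        ref = {f"P{i}" for i in range(100)}
        res = fq.overrepresentation_test(study, ref, {"T1": ref})
        assert res[0].enrichment == pytest.approx(1.0)
        assert res[0].p_raw == pytest.approx(1.0)

    def test_p_matches_hypergeometric_tail_oracle(self):
        study = {f"P{i}" for i in range(10)}          # n = 10
        ref = {f"P{i}" for i in range(100)}           # N = 100
        term = {f"P{i}" for i in range(5)} | {f"P{i}" for i in range(50, 55)}
        res = fq.overrepresentation_test(study, ref, {"T1": term})
        # k=5 of K=10 in a study of 10 from 100: direct tail sum
        oracle = sum(sps.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert res[0].k_study == 5 and res[0].K_ref == 10
        assert res[0].p_raw == pytest.approx(oracle, rel=1e-12)

    def test_bonferroni_is_m_times_raw_capped(self):
        study = {"P0", "P1"}
        ref = {f"P{i}" for i in range(20)}
        annotation = {f"T{j}": {"P0", "P1", f"P{j + 5}"} for j in range(4)}
        res = fq.overrepresentation_test(study, ref, annotation)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 4 * r.p_raw))


class TestCompareGroups:
    def test_report_means_within_sampling_error(self, quant_table, manifest):
        report = fq.compare_groups(quant_table, manifest,
                                   ["CEACAM1", "CNDP1"])
        # G05 CEACAM1 configured at 515.6 +/- 72.14, n=36 -> 3 SE ~ 36
        g05 = report["CEACAM1"]["per_group"]["G05"]
        assert abs(g05["mean"] - 515.6) < 3 * 72.14 / np.sqrt(36) + 520 * 0.03
        assert report["CEACAM1"]["kruskal_wallis"]["p"] < 0.001

    def test_fold_change_against_control_direction(self, quant_table,
                                                   manifest):
        report = fq.compare_groups(quant_table, manifest, ["CNDP1"])
        folds = report["CNDP1"]["fold_change_vs_control"]
        assert folds["G02"] > 2.0          # 49.3 / 17.1
        assert folds["G03"] > 1.0

    def test_empty_group_contrast_skipped(self):
        quant = pd.DataFrame({
            "sample_id": ["A1", "A2", "B1"],
            "protein_id": ["CRP"] * 3,
            "conc_ng_ml": [1.0, 2.0, 3.0],
            "flags": [""] * 3,
        })
        manifest = pd.DataFrame({
            "sample_id": ["A1", "A2", "B1", "C1"],
            "group": ["G01", "G01", "G05", "G02"],
            "dm_type": ["GDM", "GDM", "none", "GDM"],
            "df_status": [False, False, False, True],
            "treatment": ["diet", "diet", "none", "insulin"],
        })
        report = fq.compare_groups(quant, manifest, ["CRP"])
        # G02 has no measured values: its DF contrast must be absent
        assert "G02_vs_nonDF" not in report["CRP"]["contrasts"]

    def test_label_permutation_permutes_output(self):
        rng = np.random.default_rng(6)
        values = {g: rng.normal(size=5) for g in ("G01", "G02", "G05")}
        res = fq.kruskal_wallis(values)
        shuffled = {"G05": values["G05"], "G01": values["G01"],
                    "G02": values["G02"]}
        res2 = fq.kruskal_wallis(shuffled)
        assert res.statistic == res2.statistic
        assert res.p_value == res2.p_value


class TestTypeIError:
    def test_kruskal_wallis_null_rejection_rate(self):
        # five groups at the published sizes drawn from one distribution
        sizes = [43, 37, 34, 29, 36]
        rng = np.random.default_rng(99)
        n_sims, rejections = 2000, 0
        for _ in range(n_sims):
            groups = {f"g{i}": rng.normal(size=s)
                      for i, s in enumerate(sizes)}
            if fq.kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert 0.035 <= rate <= 0.065
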