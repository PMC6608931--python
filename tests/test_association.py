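"""Association statistics against independent oracles, and the cascade.

The Fisher oracle enumerates all 2x2 tables with the observed margins via
the hypergeometric pmf; the trend-test oracle is a separate textbook
implementation (T = sum w_i (r_i s - s_i r), variance from the margins)
plus a label-permutation oracle.  Both stay independent of the package
code paths they check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from resistseq.association import (CarrierTable, associate, build_dataset2,
                                   build_dataset3, carrier_table, catt,
                                   fisher_exact, genotype_counts,
                                   population_frequencies,
                                   sens_spec_auc, shared_snp_summary,
                                   snps_per_gene)
from resistseq.containers import GenotypeMatrix
from resistseq.synthetic_data import (PopulationSpec, SimulationConfig,
                                      simulate_cohort)


# ---------------------------------------------------------------------------
# oracles

def fisher_enumeration_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher p by exhaustive enumeration over the margin-fixed
    table family, summing probabilities <= that of the observed table."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def catt_closed_form_oracle(counts: np.ndarray) -> tuple[float, float]:
    """Textbook trend statistic: T = sum w_i (r_i s - s_i r),
    Var(T) = (r s / n) [n sum w_i^2 n_i - (sum w_i n_i)^2]."""
    counts = np.asarray(counts, dtype=float)
    w = np.arange(counts.shape[0], dtype=float)
    r_i, s_i = counts[:, 0], counts[:, 1]
    r, s = r_i.sum(), s_i.sum()
    n_i = r_i + s_i
    n = r + s
    t = np.sum(w * (r_i * s - s_i * r))
    var = (r * s / n) * (n * np.sum(w**2 * n_i) - np.sum(w * n_i) ** 2)
    stat = t * t / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def catt_permutation_oracle(counts: np.ndarray, n_perm: int,
                            seed: int) -> float:
    """Permutation p-value: shuffle phenotype labels, recompute the trend
    statistic."""
    counts = np.asarray(counts, dtype=int)
    dosages = np.repeat([0, 1, 2], counts.sum(axis=1))
    labels = np.concatenate([
        np.repeat(["resistant", "susceptible"], counts[d])
        for d in range(3)
    ])
    obs = catt(counts)[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        stat = catt(genotype_counts(dosages, perm))[0]
        if stat >= obs - 1e-12:
            hits += 1
    return hits / n_perm


# ---------------------------------------------------------------------------
# carrier table and metrics

class TestCarrierTable:
    def test_basic_counts(self):
        t = carrier_table([2, 1, 0, 0],
                          ["resistant", "resistant", "susceptible",
                           "susceptible"])
        assert t.as_array().tolist() == [[2, 0], [0, 2]]
        assert t.n_missing == 0

    def test_missing_excluded_and_counted(self):
        t = carrier_table([2, 1, np.nan, 0, 0],
                          ["resistant", "resistant", "resistant",
                           "susceptible", "susceptible"])
        assert t.as_array().sum() == 4
        assert t.n_missing == 1

    def test_perfect_association(self):
        dosages = [1] * 10 + [0] * 10
        labels = ["resistant"] * 10 + ["susceptible"] * 10
        assert carrier_table(dosages, labels).as_array().tolist() == \
            [[10, 0], [0, 10]]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            carrier_table([np.nan, np.nan], ["resistant", "susceptible"])


class TestFisher:
    def test_no_carriers_gives_one_flagged(self):
        p, flag = fisher_exact(np.array([[0, 10], [0, 10]]))
        assert (p, flag) == (1.0, True)

    def test_five_vs_five_diagonal(self):
        # direct hypergeometric: C(5,5)C(5,0)/C(10,5) doubled by symmetry
        p, flag = fisher_exact(np.array([[5, 0], [0, 5]]))
        assert not flag
        assert p == pytest.approx(2 / 252, rel=1e-9)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_matches_enumeration_oracle(self, cells):
        table = np.array(cells).reshape(2, 2)
        p, flag = fisher_exact(table)
        if flag:
            assert (table.sum(axis=0) == 0).any() or \
                (table.sum(axis=1) == 0).any()
        else:
            assert p == pytest.approx(fisher_enumeration_oracle(table),
                                      rel=1e-7)


class TestSensSpecAuc:
    @pytest.mark.parametrize("table,expected", [
        (CarrierTable(10, 0, 0, 10), (1.0, 1.0, 1.0)),
        (CarrierTable(0, 10, 0, 10), (0.0, 1.0, 0.5)),  # no carriers
        (CarrierTable(60, 30, 7, 28), (2 / 3, 0.8, 11 / 15)),
    ])
    def test_formula(self, table, expected):
        sens, spec, auc = sens_spec_auc(table)
        assert (sens, spec, auc) == pytest.approx(expected, abs=1e-12)
        assert auc == pytest.approx((sens + spec) / 2)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            sens_spec_auc(CarrierTable(5, 5, 0, 0))


class TestCatt:
    def test_perfect_trend_highly_significant(self):
        counts = np.array([[0, 10], [0, 0], [10, 0]])
        stat, p, flag = catt(counts)
        assert not flag
        assert p < 1e-4

    def test_equal_distributions_give_zero(self):
        counts = np.array([[5, 5], [3, 3], [2, 2]])
        stat, p, flag = catt(counts)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_monomorphic_flagged(self):
        stat, p, flag = catt(np.array([[10, 5], [0, 0], [0, 0]]))
        assert (stat, p, flag) == (0.0, 1.0, True)

    @given(st.lists(st.integers(0, 15), min_size=6, max_size=6))
    def test_matches_closed_form_oracle(self, cells):
        counts = np.array(cells).reshape(3, 2)
        if (counts.sum(axis=0) == 0).any():
            return
        stat, p, flag = catt(counts)
        if flag:
            return
        o_stat, o_p = catt_closed_form_oracle(counts)
        assert stat == pytest.approx(o_stat, rel=1e-6)
        assert p == pytest.approx(o_p, rel=1e-6, abs=1e-12)

    def test_matches_permutation_oracle(self):
        # cohort-scale table, where the chi-squared reference is accurate
        counts = np.array([[40, 30], [35, 15], [45, 10]])
        _, p, _ = catt(counts)
        p_perm = catt_permutation_oracle(counts, n_perm=10_000, seed=0)
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / 10_000)
        assert abs(p - p_perm) < 4 * se + 0.005


# ---------------------------------------------------------------------------
# cascade

def _results_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["supercontig"] = df.get("supercontig", "sc1")
    df["position"] = range(1, len(df) + 1)
    return df.set_index("site_id")


class TestCascade:
    def test_dataset2_boundary_inclusive_and_regions(self):
        rows = [
            {"site_id": "a", "region": "exon", "fisher_p": 0.10, "auc": 0.9,
             "catt_p": 0.01},
            {"site_id": "b", "region": "intron", "fisher_p": 0.05,
             "auc": 0.8, "catt_p": 0.01},
            {"site_id": "c", "region": "exon", "fisher_p": 0.11, "auc": 0.7,
             "catt_p": 0.01},
            {"site_id": "d", "region": "flank", "fisher_p": 0.01, "auc": 0.6,
             "catt_p": 0.01},
        ]
        ds2 = build_dataset2(_results_frame(rows))
        assert list(ds2.index) == ["a"]  # p=0.10 kept; intron/flank dropped

    def test_dataset2_sorted_by_auc_descending(self):
        rows = [
            {"site_id": s, "region": "exon", "fisher_p": 0.01, "auc": a,
             "catt_p": 0.2}
            for s, a in [("x", 0.6), ("y", 0.9), ("z", 0.75)]
        ]
        ds2 = build_dataset2(_results_frame(rows))
        assert list(ds2.index) == ["y", "z", "x"]

    def test_dataset3_boundary(self):
        rows = [
            {"site_id": "a", "region": "exon", "fisher_p": 0.01, "auc": 0.9,
             "catt_p": 0.05},
            {"site_id": "b", "region": "exon", "fisher_p": 0.01, "auc": 0.8,
             "catt_p": 0.051},
        ]
        ds3 = build_dataset3(build_dataset2(_results_frame(rows)))
        assert list(ds3.index) == ["a"]

    def test_all_filtered_gives_empty(self):
        rows = [{"site_id": "a", "region": "exon", "fisher_p": 0.5,
                 "auc": 0.9, "catt_p": 0.01}]
        assert build_dataset2(_results_frame(rows)).empty

    @given(st.floats(0.0, 0.10), st.floats(0.0, 0.05))
    def test_tightening_thresholds_never_adds_snps(self, fa, ca):
        rng = np.random.default_rng(99)
        rows = [
            {"site_id": f"s{i}", "region": "exon",
             "fisher_p": float(rng.random()), "auc": float(rng.random()),
             "catt_p": float(rng.random())}
            for i in range(40)
        ]
        frame = _results_frame(rows)
        full = set(build_dataset3(build_dataset2(frame)).index)
        tight = set(build_dataset3(build_dataset2(frame, fa), ca).index)
        assert tight <= full

    def test_shared_snp_summary_percentage(self):
        malathion = {f"m{i}" for i in range(144)}
        permethrin = {f"p{i}" for i in range(62)} | {f"m{i}" for i in range(22)}
        shared, total, pct = shared_snp_summary(
            {"malathion": malathion, "permethrin": permethrin})
        assert len(shared) == 22
        assert total == 144 + 62
        assert pct == round(100 * 22 / 206)

    def test_snps_per_gene_counts(self):
        rows = [
            {"site_id": "a", "region": "exon", "fisher_p": 0.01, "auc": 0.9,
             "catt_p": 0.01, "gene_id": "G1"},
            {"site_id": "b", "region": "exon", "fisher_p": 0.01, "auc": 0.8,
             "catt_p": 0.01, "gene_id": "G1"},
            {"site_id": "c", "region": "exon", "fisher_p": 0.01, "auc": 0.7,
             "catt_p": 0.01, "gene_id": "G2"},
        ]
        counts = snps_per_gene(_results_frame(rows))
        assert counts.to_dict() == {"G1": 2, "G2": 1}


class TestPopulationFrequencies:
    def _cohort_frames(self):
        sites = pd.DataFrame({
            "supercontig": ["sc1"], "position": [100], "ref": ["A"],
            "alt": ["T"]}, index=pd.Index(["sc1:100"], name="site_id"))
        samples = [f"i{k}" for k in range(19)]
        dosage = pd.DataFrame(
            [[1.0] * 7 + [0.0] * 12], index=sites.index, columns=samples)
        geno = GenotypeMatrix(sites=sites, dosage=dosage)
        pheno = pd.DataFrame({
            "population": ["TXU"] * 19,
            "permethrin": ["resistant"] * 10 + ["susceptible"] * 9,
        }, index=pd.Index(samples, name="sample"))
        return geno, pheno

    def test_seven_of_nineteen_reports_037(self):
        geno, pheno = self._cohort_frames()
        freqs = population_frequencies(geno, pheno, "permethrin")
        assert freqs.loc["sc1:100", "freq_TXU"] == 0.37

    def test_difference_of_reported_frequencies(self):
        sites = pd.DataFrame({
            "supercontig": ["sc1"], "position": [1], "ref": ["A"],
            "alt": ["T"]}, index=pd.Index(["sc1:1"], name="site_id"))
        samples = [f"i{k}" for k in range(200)]
        # 81 of 100 resistant carry; 32 of 100 susceptible carry
        dosage = pd.DataFrame(
            [[1.0] * 81 + [0.0] * 19 + [1.0] * 32 + [0.0] * 68],
            index=sites.index, columns=samples)
        pheno = pd.DataFrame({
            "population": ["P"] * 200,
            "permethrin": ["resistant"] * 100 + ["susceptible"] * 100,
        }, index=pd.Index(samples, name="sample"))
        geno = GenotypeMatrix(sites=sites, dosage=dosage)
        freqs = population_frequencies(geno, pheno, "permethrin")
        row = freqs.loc["sc1:1"]
        assert (row["freq_resistant"], row["freq_susceptible"]) == (0.81, 0.32)
        assert row["difference"] == 0.49

    def test_all_carriers_everywhere(self):
        geno, pheno = self._cohort_frames()
        geno.dosage.iloc[0, :] = 2.0
        freqs = population_frequencies(geno, pheno, "permethrin")
        row = freqs.loc["sc1:100"]
        assert row["freq_TXU"] == 1.0 and row["difference"] == 0.0


# ---------------------------------------------------------------------------
# statistical behaviour on simulated cohorts

@pytest.fixture(scope="module")
def null_results():
    cfg = SimulationConfig(
        populations=(PopulationSpec("P1", 60, False),
                     PopulationSpec("P2", 65, False)),
        n_genes=40, n_neutral_snps=500, causal_snps=(),
        duplications=(), missing_rate=0.0)
    cohort = simulate_cohort(cfg, seed=21)
    ann = cohort.sites.reset_index()[["site_id", "gene_id", "region"]]
    ann["effect"] = None
    return associate(cohort.genotypes, cohort.phenotypes, "permethrin", ann)


class TestNullBehaviour:
    def test_fisher_type_i_error_within_alpha(self, null_results):
        rate = (null_results["fisher_p"] <= 0.10).mean()
        mc = 3 * np.sqrt(0.1 * 0.9 / len(null_results))
        assert rate <= 0.10 + mc

    def test_catt_pvalues_approximately_uniform(self, null_results):
        informative = null_results.loc[~null_results["catt_flag"], "catt_p"]
        stat = stats.kstest(informative, "uniform")
        # discrete genotypes make the chi-squared p slightly conservative;
        # require no gross departure from uniformity
        assert stat.statistic < 0.10

    def test_auc_centered_at_half(self, null_results):
        assert abs(null_results["auc"].mean() - 0.5) < 0.03


class TestRecovery:
    def test_planted_snp_ranks_high_by_auc(self, default_cohort):
        cohort = default_cohort
        ann = cohort.sites.reset_index()[["site_id", "gene_id", "region"]]
        ann["effect"] = None
        results = associate(cohort.genotypes, cohort.phenotypes,
                            "permethrin", ann)
        causal = cohort.truth["causal_snps"][0]["site_id"]
        neutral = results.drop(index=causal)
        assert results.loc[causal, "auc"] > neutral["auc"].quantile(0.9)
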