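import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicqtl.scan import (GenotypeData, call_qtls, genome_scan,
                           longitudinal_scan, marker_effect_regression,
                           parameter_scan, permutation_test,
                           single_marker_anova)
from magicqtl.simulate import (QTLEffect, SimulationConfig,
                               simulate_trait_series)


def brute_force_anova(groups):
    """Sums-of-squares ANOVA table, written out longhand."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - np.mean(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, float(stats.f.sf(F, dfb, dfw))


class TestSingleMarkerAnova:
    def test_hand_worked_example(self):
        # groups {1,2,3} and {4,5,6}: SSB = 13.5, SSW = 4, df (1, 4)
        F, p = single_marker_anova([[1, 2, 3], [4, 5, 6]])
        assert F == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)

    def test_null_symmetric_groups(self):
        F, p = single_marker_anova([[1.0, 3.0], [0.0, 4.0]])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_f_increases_with_effect_size(self):
        base = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        fs = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            shifted = [base[0], [v + delta for v in base[1]]]
            fs.append(single_marker_anova(shifted)[0])
        assert all(a < b for a, b in zip(fs, fs[1:]))

    def test_matches_brute_force_on_random_configs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            k = rng.integers(2, 6)
            groups = [rng.normal(rng.normal(), 1.0, rng.integers(2, 9))
                      for _ in range(k)]
            F, p = single_marker_anova(groups)
            F2, p2 = brute_force_anova(groups)
            assert F == pytest.approx(F2, rel=1e-10)
            assert p == pytest.approx(p2, rel=1e-10)
            sp = stats.f_oneway(*groups)
            assert F == pytest.approx(sp.statistic, rel=1e-10)

    def test_degrees_of_freedom_contracts(self):
        with pytest.raises(ValueError):
            single_marker_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            single_marker_anova([[1.0], [2.0]])


@pytest.fixture(scope="module")
def gdata(population):
    _, pop = population
    return GenotypeData.from_population(pop)


class TestGenomeScan:
    def test_scan_table_invariants(self, gdata):
        rng = np.random.default_rng(0)
        y = rng.normal(size=gdata.n_lines)
        scan = genome_scan(gdata, y)
        tab = scan.table.dropna(subset=["p"])
        assert len(tab) > 100
        assert ((tab["p"] > 0) & (tab["p"] <= 1)).all()
        assert np.allclose(tab["neg_log10_p"], -np.log10(tab["p"]))
        assert ((tab["marker_h2"] >= 0) & (tab["marker_h2"] <= 1)).all()

    def test_type_i_rate_near_nominal(self, gdata):
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(5):
            y = rng.normal(size=gdata.n_lines)
            tab = genome_scan(gdata, y).table.dropna(subset=["p"])
            rates.append((tab["p"] < 0.05).mean())
        # linked markers correlate, but the mean rate should stay near 5%
        assert abs(np.mean(rates) - 0.05) < 0.05

    def test_founder_grouping_gives_eight_means(self, gdata):
        rng = np.random.default_rng(2)
        y = rng.normal(size=gdata.n_lines)
        scan = genome_scan(gdata, y, grouping="founder")
        mean_cols = [c for c in scan.table.columns if c.startswith("mean_")]
        assert len(mean_cols) == 8

    def test_phenotype_alignment_by_series(self, gdata):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=gdata.n_lines),
                      index=gdata.line_names)
        a = genome_scan(gdata, y).table
        b = genome_scan(gdata, y.to_numpy()).table
        pd.testing.assert_frame_equal(a, b)


class TestPermutation:
    def test_deterministic_under_seed(self, gdata):
        rng = np.random.default_rng(4)
        y = rng.normal(size=gdata.n_lines)
        p1 = permutation_test(gdata, y, B=50, seed=9)
        p2 = permutation_test(gdata, y, B=50, seed=9)
        assert np.array_equal(p1.null_max_stats, p2.null_max_stats)
        assert p1.empirical_p == p2.empirical_p

    def test_strong_signal_gives_zero_k(self, gdata):
        perm = permutation_test(gdata, np.random.default_rng(5).normal(
            size=gdata.n_lines), B=50, seed=1, observed_max=50.0)
        assert perm.K == 0
        assert perm.empirical_p == 0.0

    def test_invalid_observed_stat_rejected(self, gdata):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            permutation_test(gdata, rng.normal(size=gdata.n_lines), B=10,
                             seed=0, observed_max=-np.inf)

    def test_empirical_p_near_uniform_under_null(self, gdata):
        rng = np.random.default_rng(7)
        ps = [permutation_test(gdata, rng.normal(size=gdata.n_lines),
                               B=40, seed=i).empirical_p
              for i in range(15)]
        assert 0.2 < np.mean(ps) < 0.8


class TestCalls:
    def test_no_signal_no_calls(self, gdata):
        rng = np.random.default_rng(8)
        y = rng.normal(size=gdata.n_lines)
        scan = genome_scan(gdata, y)
        perm = permutation_test(gdata, y, B=50, seed=2,
                                observed_max=scan.max_neg_log10_p)
        if scan.max_neg_log10_p <= 4:
            assert call_qtls(scan, perm) == []

    def test_two_unlinked_qtls_two_calls(self, population):
        panel, pop = population
        gdata = GenotypeData.from_population(pop)
        rng = np.random.default_rng(9)
        j1 = 20   # chr1A
        j2 = 100  # chr4D (40 markers per chromosome)
        y = (1.5 * gdata.genotypes[:, j1]
             + 1.5 * gdata.genotypes[:, j2]
             + rng.normal(0, 1.0, gdata.n_lines))
        scan = genome_scan(gdata, y)
        perm = permutation_test(gdata, y, B=100, seed=3,
                                observed_max=scan.max_neg_log10_p)
        calls = call_qtls(scan, perm)
        chroms = {c.chrom for c in calls}
        assert {"chr1A", "chr4D"} <= chroms
        for c in calls:
            assert c.interval_lower <= c.bp <= c.interval_upper
            assert c.neg_log10_p > 4 and c.empirical_p < 0.05


class TestDerivedScans:
    def test_parameter_scan_hits_planted_qtl(self, population, qtl_config):
        _, pop = population
        cfg, marker = qtl_config
        _, truth = simulate_trait_series(pop, cfg, "Area")
        gdata = GenotypeData.from_population(pop)
        truth = truth.rename(columns={"trait": "model"})
        scans = parameter_scan(truth, gdata, trait="Area")
        peak = scans["D"].peak
        target_cm = float(gdata.markers.loc[
            gdata.markers["marker"] == marker, "cM"].iloc[0])
        assert peak["chrom"] == "chr4D"
        assert abs(peak["cM"] - target_cm) < 15.0
        # specificity: parameter A carries no planted signal
        assert scans["A"].max_neg_log10_p < scans["D"].max_neg_log10_p

    def test_longitudinal_scan_reduces_to_genome_scan(self, population):
        _, pop = population
        cfg = SimulationConfig(seed=21, n_lines=pop.n_lines,
                               timepoints=(150,))
        series, _ = simulate_trait_series(pop, cfg, "Area")
        gdata = GenotypeData.from_population(pop)
        scans, traj = longitudinal_scan(series, gdata, "Area")
        assert list(scans) == [150]
        pheno = series.groupby("line")["value"].mean()
        direct = genome_scan(gdata, pheno.reindex(gdata.line_names))
        assert np.allclose(scans[150].table["F"], direct.table["F"],
                           equal_nan=True)

    def test_marker_effect_regression_recovers_slope(self, population,
                                                     qtl_config):
        _, pop = population
        cfg, marker = qtl_config
        series, _ = simulate_trait_series(pop, cfg, "Area")
        gdata = GenotypeData.from_population(pop)
        traj = marker_effect_regression(series, gdata, marker, "Area")
        late = traj[traj["DAS"] >= 170]
        # planted +9000 on D for B-allele carriers: per-allele slope ~ 4500
        assert late["slope"].mean() == pytest.approx(4500.0, rel=0.25)
        early = traj[traj["DAS"] <= 100]
        assert early["slope"].abs().mean() < late["slope"].abs().mean()

    def test_monomorphic_marker_rejected(self, population):
        _, pop = population
        gdata = GenotypeData.from_population(pop)
        mono = GenotypeData(
            markers=gdata.markers, line_names=gdata.line_names,
            genotypes=np.zeros_like(gdata.genotypes),
        )
        series = pd.DataFrame({"line": gdata.line_names, "rep": 1,
                               "DAS": 100, "trait": "Area", "value": 1.0})
        with pytest.raises(ValueError):
            marker_effect_regression(series, mono,
                                     gdata.markers["marker"].iloc[0], "Area")
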