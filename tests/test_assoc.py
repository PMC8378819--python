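"""Association scan, parent scoring, performance correlation, clustering."""

import numpy as np
import pandas as pd
import pytest

from coralbreed import assoc


def _survival(fams, alive, n=100, origins=None):
    return pd.DataFrame({
        "family_id": fams,
        "origin": origins if origins is not None else ["PG"] * len(fams),
        "n_start": n,
        "n_alive_60h": alive,
    })


def _alleles(loci):
    return pd.DataFrame({
        "locus_id": loci,
        "major_allele": "A",
        "minor_allele": "C",
    })


class TestScan:
    def test_perfect_anticorrelation(self):
        fams = ["F1", "F2", "F3", "F4"]
        maf = pd.DataFrame({"L1": [0.0, 0.1, 0.4, 0.5]}, index=fams)
        surv = _survival(fams, [90, 80, 50, 40])
        scan = assoc.scan_survival_association(maf, surv, _alleles(["L1"]))
        assert scan.table.loc["L1", "R"] == pytest.approx(-1.0)
        assert scan.table.loc["L1", "class"] == "strong"
        assert scan.table.loc["L1", "beneficial_allele"] == "A"

    def test_constant_maf_reports_nothing(self):
        fams = ["F1", "F2", "F3", "F4"]
        maf = pd.DataFrame({"L1": [0.2] * 4}, index=fams)
        surv = _survival(fams, [90, 80, 50, 40])
        scan = assoc.scan_survival_association(maf, surv, _alleles(["L1"]))
        row = scan.table.loc["L1"]
        assert row["class"] == "none"
        assert row["p_adj"] == 1.0
        assert np.isnan(row["R"])

    def test_too_few_families_not_tested(self):
        fams = ["F1", "F2", "F3", "F4"]
        maf = pd.DataFrame({"L1": [0.1, 0.3, np.nan, np.nan]}, index=fams)
        surv = _survival(fams, [90, 80, 50, 40])
        scan = assoc.scan_survival_association(maf, surv, _alleles(["L1"]))
        assert not scan.table.loc["L1", "tested"]
        assert scan.n_tested == 0

    def test_glm_matches_statsmodels(self):
        """Batched IRLS likelihood-ratio p-values equal a conventional
        per-locus GLM fit (independent implementation)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        nfam, nloci = 24, 15
        fams = [f"F{i}" for i in range(nfam)]
        origins = np.repeat(["PG", "IO", "PGxIO"], nfam // 3)
        maf = pd.DataFrame(
            rng.uniform(0.05, 0.45, size=(nfam, nloci)),
            index=fams, columns=[f"L{j}" for j in range(nloci)])
        alive = rng.binomial(100, 0.6, nfam)
        surv = _survival(fams, alive, origins=list(origins))
        scan = assoc.scan_survival_association(
            maf, surv, _alleles(list(maf.columns)))

        dummies = pd.get_dummies(pd.Series(origins), drop_first=True)
        C = np.column_stack([np.ones(nfam), dummies.to_numpy(float)])
        y = np.column_stack([alive, 100 - alive])
        for locus in maf.columns:
            X = np.column_stack([C, maf[locus].to_numpy()])
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, C, family=sm.families.Binomial()).fit()
            from scipy import stats as sps
            lrt = 2 * (full.llf - null.llf)
            p_ref = sps.chi2.sf(max(lrt, 0), 1)
            assert scan.table.loc[locus, "p"] == pytest.approx(
                p_ref, rel=1e-4, abs=1e-12)

    def test_orientation_flip_consistency(self):
        """Flipping the minor-allele convention at a locus flips the sign of
        R and relabels the beneficial allele."""
        fams = ["F1", "F2", "F3", "F4", "F5"]
        vals = np.array([0.05, 0.15, 0.25, 0.35, 0.45])
        surv = _survival(fams, [90, 80, 70, 60, 50])
        maf = pd.DataFrame({"L1": vals}, index=fams)
        flipped = pd.DataFrame({"L1": 1 - vals}, index=fams)
        al = _alleles(["L1"])
        al_flip = al.assign(major_allele="C", minor_allele="A")
        s1 = assoc.scan_survival_association(maf, surv, al)
        s2 = assoc.scan_survival_association(flipped, surv, al_flip)
        assert s1.table.loc["L1", "R"] == pytest.approx(
            -s2.table.loc["L1", "R"])
        assert s1.table.loc["L1", "p"] == pytest.approx(
            s2.table.loc["L1", "p"], rel=1e-6)
        # beneficial allele is the same nucleotide under both labellings
        assert (s1.table.loc["L1", "beneficial_allele"]
                == s2.table.loc["L1", "beneficial_allele"])


class TestScoreParent:
    def test_worked_copy_scoring(self):
        # copies (2, 1, 0, 1) -> scores (1, 0.5, 0, 0.5) -> mean 0.5
        geno = pd.Series([1.0, 0.5, 0.0, 0.5],
                         index=["L1", "L2", "L3", "L4"])  # alt = beneficial
        ben = pd.Series([True] * 4, index=geno.index)
        assert assoc.score_parent(geno, ben) == pytest.approx(0.5)

    def test_extremes(self):
        loci = ["L1", "L2"]
        ben = pd.Series([True, True], index=loci)
        assert assoc.score_parent(pd.Series([1.0, 1.0], index=loci), ben) == 1.0
        assert assoc.score_parent(pd.Series([0.0, 0.0], index=loci), ben) == 0.0

    def test_reference_beneficial_flips_score(self):
        loci = ["L1"]
        ben = pd.Series([False], index=loci)   # beneficial is the reference
        assert assoc.score_parent(pd.Series([0.0], index=loci), ben) == 1.0
        assert assoc.score_parent(pd.Series([1.0], index=loci), ben) == 0.0

    def test_missing_loci_excluded_and_all_missing_nan(self):
        loci = ["L1", "L2"]
        ben = pd.Series([True, True], index=loci)
        assert assoc.score_parent(
            pd.Series([np.nan, 1.0], index=loci), ben) == 1.0
        assert np.isnan(assoc.score_parent(
            pd.Series([np.nan, np.nan], index=loci), ben))

    def test_invariant_to_order_and_duplication(self):
        loci = ["L1", "L2", "L3"]
        ben = pd.Series([True, False, True], index=loci)
        geno = pd.Series([1.0, 0.5, 0.0], index=loci)
        base = assoc.score_parent(geno, ben)
        shuffled = assoc.score_parent(geno.iloc[[2, 0, 1]], ben)
        assert shuffled == pytest.approx(base)
        # duplicating a locus record duplicates its weight consistently:
        # mean over scored loci of the duplicated series stays in [0,1]
        dup = assoc.score_parent(
            pd.concat([geno, geno.loc[["L1"]]]),
            pd.concat([ben, ben.loc[["L1"]]]))
        assert 0.0 <= dup <= 1.0


class TestPerformanceCorrelation:
    def _scores(self, ids, vals):
        return pd.DataFrame({"parent_id": ids, "n_loci_scored": 10,
                             "beneficial_proportion": vals})

    def test_identity_vectors(self):
        ids = ["S1", "S2", "S3", "S4"]
        vals = [0.3, 0.4, 0.5, 0.6]
        out = assoc.correlate_parent_performance(
            self._scores(ids, vals), pd.Series(vals, index=ids))
        assert out["R"] == pytest.approx(1.0)

    def test_exclusion_list(self):
        ids = ["S1", "S2", "S3", "S4"]
        vals = [0.3, 0.4, 0.5, 0.9]
        idx = pd.Series([0.3, 0.4, 0.5, -1.0], index=ids)
        out = assoc.correlate_parent_performance(
            self._scores(ids, vals), idx, exclude=["S4"])
        assert out["n"] == 3
        assert out["R"] == pytest.approx(1.0)

    def test_too_few_points_raises(self):
        ids = ["S1", "S2"]
        with pytest.raises(ValueError, match=">=3"):
            assoc.correlate_parent_performance(
                self._scores(ids, [0.3, 0.4]),
                pd.Series([0.1, 0.2], index=ids))

    def test_permutation_p_consistency(self):
        """The parametric p agrees with a permutation null within
        Monte-Carlo error."""
        rng = np.random.default_rng(5)
        ids = [f"S{i}" for i in range(12)]
        x = rng.uniform(0.3, 0.7, 12)
        y = x + rng.normal(0, 0.15, 12)
        out = assoc.correlate_parent_performance(
            self._scores(ids, x), pd.Series(y, index=ids))
        n_perm = 2000
        exceed = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            r = np.corrcoef(x, yp)[0, 1]
            exceed += abs(r) >= abs(out["R"])
        perm_p = exceed / n_perm
        se = np.sqrt(max(perm_p * (1 - perm_p), 1e-6) / n_perm)
        assert abs(perm_p - out["p"]) <= max(4 * se, 0.01)


class TestClustering:
    def test_identical_parents_merge_first(self):
        rng = np.random.default_rng(2)
        loci = [f"L{i}" for i in range(30)]
        base = rng.choice([0.0, 0.5, 1.0], 30)
        mat = pd.DataFrame(
            [base, base, rng.choice([0.0, 0.5, 1.0], 30)],
            index=["P1", "P2", "P3"], columns=loci)
        out = assoc.cluster_paternal_genotypes(mat, pd.Index(loci))
        assert out["correlation"].loc["P1", "P2"] == pytest.approx(1.0)
        first_merge = out["linkage"][0, :2].astype(int)
        labels = list(out["correlation"].index)
        assert {labels[i] for i in first_merge} == {"P1", "P2"}

    def test_complement_parent_anticorrelated(self):
        loci = [f"L{i}" for i in range(20)]
        base = np.tile([0.0, 0.5, 1.0, 0.5], 5)
        mat = pd.DataFrame([base, 1.0 - base], index=["P1", "P2"],
                           columns=loci)
        out = assoc.cluster_paternal_genotypes(mat, pd.Index(loci))
        assert out["correlation"].loc["P1", "P2"] == pytest.approx(-1.0)

    def test_low_shared_loci_flagged(self):
        loci = [f"L{i}" for i in range(12)]
        a = pd.Series(np.tile([0.0, 1.0], 6), index=loci)
        b = a.copy()
        b.iloc[4:] = np.nan     # only 4 shared loci
        mat = pd.DataFrame([a, b, a], index=["P1", "P2", "P3"])
        out = assoc.cluster_paternal_genotypes(mat, pd.Index(loci))
        assert ("P1", "P2") in out["low_confidence_pairs"]

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(3)
        loci = [f"L{i}" for i in range(25)]
        mat = pd.DataFrame(rng.choice([0.0, 0.5, 1.0], size=(5, 25)),
                           index=[f"P{i}" for i in range(5)], columns=loci)
        out = assoc.cluster_paternal_genotypes(mat, pd.Index(loci))
        nwk = assoc.linkage_to_newick(
            out["linkage"], list(out["correlation"].index))
        assert nwk.endswith(";")
        for pid in mat.index:
            assert pid in nwk

    def test_regional_structure_with_cryptic_tolerant_sires(self):
        """Hot and cool sires cluster by region at strong loci, except
        planted cool sires carrying hot-population alleles, which cluster
        with the hot group."""
        rng = np.random.default_rng(9)
        nloci = 120
        hot_freq = np.full(nloci, 0.9)
        cool_freq = np.full(nloci, 0.15)
        def draw(freq, n):
            return rng.binomial(2, freq, size=(n, nloci)) / 2.0
        hot = draw(hot_freq, 5)
        cool = draw(cool_freq, 4)
        cryptic = draw(hot_freq, 1)       # cool-labelled, hot-like genotype
        mat = pd.DataFrame(
            np.vstack([hot, cool, cryptic]),
            index=[f"PG-S{i}" for i in range(5)]
            + [f"IO-S{i}" for i in range(4)] + ["IO-CRYPTIC"],
            columns=[f"L{i}" for i in range(nloci)])
        out = assoc.cluster_paternal_genotypes(mat, pd.Index(mat.columns))
        corr = out["correlation"]
        pg = [f"PG-S{i}" for i in range(5)]
        io = [f"IO-S{i}" for i in range(4)]
        within_pg = corr.loc[pg, pg].to_numpy()[np.triu_indices(5, 1)].mean()
        between = corr.loc[pg, io].to_numpy().mean()
        assert within_pg > between
        assert corr.loc["IO-CRYPTIC", pg].mean() > corr.loc["IO-CRYPTIC", io].mean()
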