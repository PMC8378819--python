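"""Survival statistics: standardisation, models, index, heritability, field rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coralbreed import phenostats as ph


def _table(rows):
    return pd.DataFrame(rows, columns=[
        "family_id", "dam_id", "sire_id", "origin", "temperature", "plate",
        "n_start", "n_alive_60h"])


class TestRelativeSurvival:
    def test_ratio_and_cap(self):
        table = _table([
            ("F1", "D1", "S1", "PG", 27.0, 1, 100, 90),
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 60),
            ("F2", "D1", "S2", "PG", 27.0, 1, 100, 90),
            ("F2", "D1", "S2", "PG", 36.0, 1, 100, 95),
        ])
        rel = ph.relative_survival(table).set_index("family_id")
        assert rel.loc["F1", "relative_survival"] == pytest.approx(60 / 90)
        assert rel.loc["F2", "relative_survival"] == 1.0  # capped

    def test_zero_ambient_is_missing(self):
        table = _table([
            ("F1", "D1", "S1", "PG", 27.0, 1, 100, 0),
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 10),
        ])
        rel = ph.relative_survival(table)
        assert rel["relative_survival"].isna().all()

    def test_missing_ambient_row_raises(self):
        table = _table([("F1", "D1", "S1", "PG", 36.0, 1, 100, 10)])
        with pytest.raises(ValueError, match="ambient"):
            ph.relative_survival(table)


def _rel_frame(origins, temps, values, families=None):
    rows = []
    i = 0
    for o_idx, origin in enumerate(origins):
        for t in temps:
            for v in values[(o_idx, t)]:
                fam = families[i] if families else f"{origin}-F{i}"
                rows.append({"family_id": fam, "origin": origin,
                             "temperature": t, "relative_survival": v})
                i += 1
    return pd.DataFrame(rows)


class TestOriginEffectModel:
    def _simulate_null(self, rng, n_per=12):
        rows = []
        for origin in ("PG", "IO", "PGxIO"):
            for t in (33.0, 36.0):
                for k in range(n_per):
                    rows.append({
                        "family_id": f"{origin}{k}", "origin": origin,
                        "temperature": t,
                        "relative_survival": np.clip(
                            rng.normal(0.7, 0.12), 0, 1)})
        return pd.DataFrame(rows)

    def test_type_one_error_calibrated(self):
        """Identical survival distributions: the origin term is significant
        in roughly 5% of null replicates."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            res = ph.origin_effect_model(self._simulate_null(rng))
            hits += res.anova.loc["C(origin)", "PR(>F)"] < 0.05
        rate = hits / n_rep
        # binomial 3-sigma band around 0.05
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_power_detects_planted_io_deficit(self):
        """A 0.3 survival deficit for IO at 36 degC is found by the IO-PG
        Tukey comparison in nearly every replicate."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            df = self._simulate_null(rng)
            sel = (df["origin"] == "IO") & (df["temperature"] == 36.0)
            df.loc[sel, "relative_survival"] -= 0.3
            df["relative_survival"] = df["relative_survival"].clip(0, 1)
            res = ph.origin_effect_model(df)
            t36 = res.tukey[res.tukey["temperature"] == 36.0]
            row = t36[(t36["group1"] == "IO") & (t36["group2"] == "PG")]
            hits += bool(row["reject"].iloc[0])
        assert hits / n_rep >= 0.9

    def test_single_origin_degenerates_with_warning(self):
        df = self._simulate_null(np.random.default_rng(0))
        res = ph.origin_effect_model(df[df["origin"] == "PG"])
        assert res.single_origin
        assert "C(temperature)" in res.anova.index


class TestFamilyDeclineTests:
    def _frame(self, fam_values):
        rows = []
        for fam, vals in fam_values.items():
            for v in vals:
                rows.append({"family_id": fam, "temperature": 36.0,
                             "relative_survival": v})
        return pd.DataFrame(rows)

    def test_no_decline_not_significant(self):
        out = ph.family_decline_tests(self._frame({"F1": [1.0, 1.0, 1.0],
                                                   "F2": [0.9, 0.8, 0.85]}))
        f1 = out.set_index("family_id").loc["F1"]
        assert not f1["significant_decline"]
        assert f1["p"] == 1.0

    def test_declining_family_found_among_nulls(self):
        """(0.2, 0.25, 0.3) is significant after FDR among 50 null families;
        expected p matches the closed-form one-sample t tail."""
        rng = np.random.default_rng(7)
        fams = {f"N{i}": np.clip(rng.normal(1.0, 0.05, 3), 0, 1.2)
                for i in range(49)}
        fams["DEC"] = [0.2, 0.25, 0.3]
        out = ph.family_decline_tests(self._frame(fams)).set_index("family_id")
        vals = np.array([0.2, 0.25, 0.3])
        tstat = (vals.mean() - 1.0) / (vals.std(ddof=1) / np.sqrt(3))
        expected_p = stats.t.cdf(tstat, df=2)
        assert out.loc["DEC", "p"] == pytest.approx(expected_p, rel=1e-10)
        assert out.loc["DEC", "p_adj"] < 0.05

    def test_fdr_calibration_under_global_null(self):
        """With all families null, the realised false-discovery proportion
        stays near or below the nominal 5%."""
        rng = np.random.default_rng(11)
        discoveries = 0
        tested = 0
        for _ in range(20):
            fams = {f"N{i}": 1.0 + rng.normal(0, 0.05, 3) for i in range(50)}
            out = ph.family_decline_tests(self._frame(fams))
            discoveries += out["significant_decline"].sum()
            tested += 1
        assert discoveries / (tested * 50) <= 0.05

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError, match="replicate"):
            ph.family_decline_tests(self._frame({"F1": [0.5]}))


class TestVarianceExplained:
    def test_two_group_hand_anova(self):
        df = pd.DataFrame({
            "relative_survival": [1, 2, 3, 4, 5, 6],
            "grp": ["A", "A", "A", "B", "B", "B"],
        })
        out = ph.variance_explained(df, ["grp"])
        assert out.loc[0, "eta_p_squared"] == pytest.approx(13.5 / 17.5)

    def test_matches_classical_one_way_eta(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "relative_survival": rng.normal(size=60),
            "grp": np.repeat(list("ABCDE"), 12),
        })
        out = ph.variance_explained(df, ["grp"])
        # independent oracle: direct sums of squares
        y = df["relative_survival"]
        grand = y.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2
                   for _, g in y.groupby(df["grp"]))
        ss_w = sum(((g - g.mean()) ** 2).sum()
                   for _, g in y.groupby(df["grp"]))
        assert out.loc[0, "eta_p_squared"] == pytest.approx(
            ss_b / (ss_b + ss_w), rel=1e-10)

    def test_orthogonal_factor_near_zero(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "relative_survival": rng.normal(size=2000),
            "grp": rng.permutation(np.repeat(["A", "B"], 1000)),
        })
        out = ph.variance_explained(df, ["grp"])
        assert out.loc[0, "eta_p_squared"] < 0.01

    def test_factor_explaining_everything(self):
        df = pd.DataFrame({
            "relative_survival": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            "grp": ["A", "A", "B", "B", "C", "C"],
        })
        out = ph.variance_explained(df, ["grp"])
        assert out.loc[0, "eta_p_squared"] == pytest.approx(1.0)

    def test_saturated_model_raises(self):
        df = pd.DataFrame({
            "relative_survival": [1.0, 2.0],
            "grp": ["A", "B"],
        })
        with pytest.raises(ValueError, match="saturated"):
            ph.variance_explained(df, ["grp"])


class TestSurvivalIndex:
    def _table(self):
        return _table([
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 72),
            ("F2", "D1", "S2", "PG", 36.0, 1, 100, 34),
            ("F3", "D2", "S1", "PG", 36.0, 1, 100, 60),
            ("F4", "D2", "S2", "PG", 36.0, 1, 100, 40),
        ])

    def test_formula_arithmetic(self):
        h, m = 0.72, 0.53
        table = _table([
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 72),
            ("F2", "D1", "S2", "PG", 36.0, 1, 100, 34),
        ])
        out = ph.survival_index(table).set_index("family_id")
        assert out.loc["F1", "m"] == pytest.approx(m)
        assert out.loc["F1", "index"] == pytest.approx(h / m - 1)

    def test_identity_when_h_equals_maternal_mean(self):
        table = _table([
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 50),
            ("F2", "D1", "S2", "PG", 36.0, 1, 100, 50),
        ])
        out = ph.survival_index(table)
        assert (out["index"] == 0).all()

    def test_sire_mean(self):
        idx = pd.DataFrame({
            "sire_id": ["S1", "S1"], "dam_id": ["D1", "D2"],
            "family_id": ["F1", "F3"], "h": [0.6, 0.7], "m": [0.5, 0.5],
            "index": [0.2, 0.4]})
        assert ph.sire_mean_index(idx).loc["S1"] == pytest.approx(0.3)

    def test_scale_free_within_dam_groups(self):
        base = ph.survival_index(self._table())
        scaled_table = self._table()
        scaled_table["n_alive_60h"] = (
            scaled_table["n_alive_60h"] * 0.5).astype(int)
        scaled = ph.survival_index(scaled_table)
        np.testing.assert_allclose(
            base["index"].to_numpy(), scaled["index"].to_numpy(), atol=1e-12)

    def test_zero_maternal_mean_missing(self):
        table = _table([
            ("F1", "D1", "S1", "PG", 36.0, 1, 100, 0),
            ("F2", "D1", "S2", "PG", 36.0, 1, 100, 0),
        ])
        out = ph.survival_index(table)
        assert out["index"].isna().all()


def _vc_data(seed, vs, vd, ve, n_rep=3):
    """Draw plate-level data from the sire-dam variance component model at
    the realised study design (17 sires, 4 dams, 50 families)."""
    from coralbreed import simdata
    fams = simdata.make_cross_design().to_frame()
    rng = np.random.default_rng(seed)
    sires = sorted(fams["sire_id"].unique())
    dams = sorted(fams["dam_id"].unique())
    se = dict(zip(sires, rng.normal(0, np.sqrt(vs), len(sires))))
    de = dict(zip(dams, rng.normal(0, np.sqrt(vd), len(dams))))
    rows = []
    for _, r in fams.iterrows():
        for _ in range(n_rep):
            rows.append({
                "sire_id": r["sire_id"], "dam_id": r["dam_id"],
                "relative_survival": 0.6 + se[r["sire_id"]] + de[r["dam_id"]]
                + rng.normal(0, np.sqrt(ve))})
    return pd.DataFrame(rows)


SHORT_CHAIN = ph.ChainConfig(iterations=20_000, burn_in=4_000, thin=8)


class TestHeritability:
    def test_null_variance_components_recovered(self):
        """No sire or dam variance: posterior h2 concentrates near zero."""
        means = []
        for seed in range(3):
            df = _vc_data(seed, 0.0, 0.0, 1.0)
            est = ph.estimate_heritability(df, SHORT_CHAIN, seed=seed)
            means.append(est.samples["h2_maternal"].mean())
        assert np.mean(means) < 0.1

    def test_posterior_variance_matches_conjugate_toy(self):
        """On data with negligible group effects and many observations, the
        residual-variance posterior matches the closed-form scaled-inverse-
        chi-squared update within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({
            "sire_id": np.tile(["S1", "S2"], n // 2),
            "dam_id": np.tile(["D1", "D2"], n // 2),
            "relative_survival": rng.normal(0.0, 1.0, n),
        })
        est = ph.estimate_heritability(df, SHORT_CHAIN, seed=1)
        y = df["relative_survival"].to_numpy()
        # conjugate posterior given ~zero effects: IG((nu+n)/2, (nuV+SS)/2)
        nu, V = 0.002, 1.0
        ss = ((y - y.mean()) ** 2).sum()
        expected_mean = (nu * V + ss) / (nu + n - 2)
        got = est.samples["V_resid"].mean()
        assert got == pytest.approx(expected_mean, rel=0.05)

    def test_h2_bounded_and_components_positive(self):
        df = _vc_data(1, 0.1, 0.2, 0.8)
        est = ph.estimate_heritability(df, SHORT_CHAIN, seed=2)
        s = est.samples
        assert (s[["V_sire", "V_dam", "V_resid"]] > 0).all().all()
        assert s["h2_narrow"].between(0, 1).all()
        assert s["h2_maternal"].between(0, 1).all()

    def test_ambient_like_data_h2_interval_includes_zero(self):
        """With no genetic signal (ambient temperature behaviour), the h2
        credible interval includes ~0."""
        df = _vc_data(5, 0.0, 0.0, 0.05)
        est = ph.estimate_heritability(df, SHORT_CHAIN, seed=3)
        lo = np.percentile(est.samples["h2_maternal"], 2.5)
        assert lo < 0.05

    def test_requires_two_sires_and_dams(self):
        df = pd.DataFrame({
            "sire_id": ["S1"] * 6, "dam_id": ["D1", "D2"] * 3,
            "relative_survival": np.arange(6.0)})
        with pytest.raises(ValueError, match="sires"):
            ph.estimate_heritability(df, SHORT_CHAIN, seed=0)


class TestFieldSurvival:
    def test_reported_rates_and_ratio(self, field_table):
        out = ph.field_survival_summary(field_table)
        assert out.loc["PGxIO", "rate"] == pytest.approx(20 / 1031)
        assert out.loc["PG", "rate"] == pytest.approx(3 / 1068)
        assert out.attrs["hybrid_pg_ratio"] >= 6.0
        assert out.loc["PGxIO", "families_with_survivors"] == pytest.approx(5 / 8)
        assert out.loc["IO", "families_with_survivors"] == pytest.approx(0.5)

    def test_all_zero_survivors_ratio_missing(self):
        df = pd.DataFrame({
            "family_id": ["F1", "F2"], "origin": ["PG", "PGxIO"],
            "n_deployed": [100, 100], "n_survivors": [0, 0]})
        out = ph.field_survival_summary(df)
        assert (out["rate"] == 0).all()
        assert np.isnan(out.attrs["hybrid_pg_ratio"])

    def test_fraction_of_families_with_survivors(self):
        df = pd.DataFrame({
            "family_id": ["F1", "F2"], "origin": ["PG", "PG"],
            "n_deployed": [10, 10], "n_survivors": [1, 0]})
        out = ph.field_survival_summary(df)
        assert out.loc["PG", "families_with_survivors"] == 0.5
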