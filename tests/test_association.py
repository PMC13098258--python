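"""CLR transform, filters, both MWAS layers, accumulation curve."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magpop.association import (
    accumulation_curve,
    bonferroni_threshold,
    clr_transform,
    filter_diseases,
    filter_species,
    species_mwas,
    unit_presence_matrix,
    within_species_mwas,
)
from magpop.simulate import simulate_phenotype_covariates


def _pheno(n, rng, diseases=None):
    df = simulate_phenotype_covariates(n, rng)
    for name, col in (diseases or {}).items():
        df[name] = col
    return df


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        x = pd.DataFrame([[0.25] * 4], index=["s1"])
        assert np.allclose(clr_transform(x).to_numpy(), 0.0)

    def test_two_part_hand_computation(self):
        # geometric mean of (0.8, 0.2) is 0.4 -> (ln 2, -ln 2)
        x = pd.DataFrame([[0.8, 0.2]], index=["s1"])
        assert np.allclose(clr_transform(x).to_numpy(), [[math.log(2), -math.log(2)]])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.dirichlet(np.ones(10), size=30))
        assert np.allclose(clr_transform(x).sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.random((5, 8)) + 0.1
        a = clr_transform(pd.DataFrame(raw))
        b = clr_transform(pd.DataFrame(raw * 37.0))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_matches_skbio_on_zero_free_table(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(6), size=10)
        ours = clr_transform(pd.DataFrame(x)).to_numpy()
        assert np.allclose(ours, skbio_clr(x), atol=1e-10)

    def test_zero_replacement_keeps_finite(self):
        x = pd.DataFrame([[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]])
        y = clr_transform(x)
        assert np.isfinite(y.to_numpy()).all()
        assert np.allclose(y.sum(axis=1), 0.0, atol=1e-9)

    def test_all_zero_row_errors(self):
        x = pd.DataFrame([[0.5, 0.5], [0.0, 0.0]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            clr_transform(x)


class TestFilters:
    def test_prevalence_inclusive_boundary(self):
        x = pd.DataFrame(0.0, index=range(100), columns=["rare", "common", "absent"])
        x.loc[0, "rare"] = 0.5          # exactly 1% of samples
        x.loc[:, "common"] = 0.5
        kept = filter_species(x, min_prevalence=0.01)
        assert kept == ["rare", "common"]

    def test_species_recount_oracle(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.random((200, 30)) * (rng.random((200, 30)) < 0.3))
        kept = filter_species(x, 0.05)
        manual = [c for c in x.columns if (x[c] > 0).sum() >= 0.05 * len(x)]
        assert kept == manual

    @pytest.mark.parametrize("n_cases,expected", [(99, []), (100, ["d"])])
    def test_disease_case_boundary(self, n_cases, expected):
        ph = pd.DataFrame({"d": [1] * n_cases + [0] * (200 - n_cases)})
        assert filter_diseases(ph, ["d"], min_cases=100) == expected


class TestBonferroni:
    def test_species_level_threshold(self):
        assert f"{bonferroni_threshold(0.05, 1842):.3g}" == "2.71e-05"

    def test_within_species_threshold(self):
        assert f"{bonferroni_threshold(0.05, 33):.2g}" == "0.0015"

    def test_single_test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestSpeciesMwas:
    def test_noiseless_planted_effect_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n = 60
        disease = (rng.random(n) < 0.5).astype(int)
        ph = _pheno(n, rng, {"dz": disease})
        y = 2.0 * disease + 0.1 * ph["bmi"].to_numpy()
        clr = pd.DataFrame({"spX": y}, index=ph.index)
        res = species_mwas(clr, ph, ["dz"])[0]
        assert res.effect == pytest.approx(2.0, abs=1e-8)
        assert res.status == "ok" and res.odds_ratio is None

    def test_constant_disease_flagged(self):
        rng = np.random.default_rng(5)
        ph = _pheno(40, rng, {"dz": np.zeros(40, dtype=int)})
        clr = pd.DataFrame({"spX": rng.normal(size=40)}, index=ph.index)
        res = species_mwas(clr, ph, ["dz"])[0]
        assert res.status == "degenerate" and math.isnan(res.p_value)
        assert not res.significant

    def test_misaligned_samples_rejected(self):
        rng = np.random.default_rng(6)
        ph = _pheno(10, rng, {"dz": np.ones(10, dtype=int)})
        clr = pd.DataFrame({"spX": np.zeros(11)},
                           index=[f"S{i:04d}" for i in range(11)])
        with pytest.raises(ValueError, match="missing"):
            species_mwas(clr, ph, ["dz"])

    def test_power_increases_with_effect_size(self):
        """Rejection fraction grows monotonically over planted effect sizes."""
        rng = np.random.default_rng(7)
        n, reps = 150, 40
        rates = []
        for beta in (0.0, 0.5, 1.0):
            hits = 0
            for _ in range(reps):
                disease = (rng.random(n) < 0.4).astype(int)
                ph = _pheno(n, rng, {"dz": disease})
                y = beta * disease + rng.normal(size=n)
                clr = pd.DataFrame({"sp": y}, index=ph.index)
                hits += species_mwas(clr, ph, ["dz"], alpha=0.05)[0].p_value < 0.05
            rates.append(hits / reps)
        assert rates[0] < rates[1] < rates[2]

    def test_bonferroni_recount_invariant(self):
        rng = np.random.default_rng(8)
        n = 120
        ph = _pheno(n, rng, {"dz": (rng.random(n) < 0.5).astype(int)})
        clr = pd.DataFrame(rng.normal(size=(n, 12)), index=ph.index,
                           columns=[f"sp{i}" for i in range(12)])
        res = species_mwas(clr, ph, ["dz"])
        alpha_c = 0.05 / 12
        assert sum(r.significant for r in res) == sum(
            1 for r in res if r.p_value < alpha_c
        )


class TestUnitPresence:
    @staticmethod
    def _fixture():
        recovery = pd.DataFrame({
            "sample_id": ["s1", "s1", "s2", "s3"],
            "mag_id": ["m1", "m2", "m3", "m4"],
        })
        unit_of = {"m1": "S1_U1", "m2": "S1_U2", "m3": "S1_U1", "m4": "S1_U1"}
        return recovery, unit_of

    def test_planted_carriers_recovered(self):
        recovery, unit_of = self._fixture()
        mat = unit_presence_matrix(recovery, unit_of, ["s1", "s2", "s3", "s4"])
        assert mat.loc["s1", "S1_U1"] == 1 and mat.loc["s1", "S1_U2"] == 1
        assert mat.loc["s4"].sum() == 0  # no MAG at all -> all-zero row

    def test_column_sums_equal_carrier_counts(self):
        recovery, unit_of = self._fixture()
        mat = unit_presence_matrix(recovery, unit_of, ["s1", "s2", "s3", "s4"])
        assert mat["S1_U1"].sum() == 3 and mat["S1_U2"].sum() == 1


class TestWithinSpeciesMwas:
    def test_no_covariate_or_equals_cross_product_ratio(self):
        """Saturated logistic fit reproduces OR = ad/bc on a 2x2 table."""
        a, b, c, d = 30, 20, 10, 40  # carriers: a cases, b controls; etc.
        carrier = np.array([1] * (a + b) + [0] * (c + d))
        disease = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        idx = [f"s{i}" for i in range(carrier.size)]
        presence = pd.DataFrame({"u1": carrier}, index=idx)
        ph = pd.DataFrame({"dz": disease}, index=idx)
        res = within_species_mwas(presence, ph, ["dz"], covariates=(),
                                  min_carriers=10)[0]
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_unit_in_every_sample_flagged(self):
        rng = np.random.default_rng(9)
        n = 50
        ph = _pheno(n, rng, {"dz": (rng.random(n) < 0.5).astype(int)})
        presence = pd.DataFrame({"u1": np.ones(n, dtype=int)}, index=ph.index)
        res = within_species_mwas(presence, ph, ["dz"], min_carriers=10)[0]
        assert res.status == "degenerate"

    def test_min_carriers_excludes_rare_units(self):
        rng = np.random.default_rng(10)
        n = 200
        ph = _pheno(n, rng, {"dz": (rng.random(n) < 0.5).astype(int)})
        presence = pd.DataFrame({
            "common": (rng.random(n) < 0.5).astype(int),
            "rare": np.array([1] * 5 + [0] * (n - 5)),
        }, index=ph.index)
        res = within_species_mwas(presence, ph, ["dz"], min_carriers=100)
        assert {r.feature_id for r in res} == {"common"}

    def test_perfect_separation_flagged_not_crash(self):
        n = 60
        carrier = np.array([1] * 30 + [0] * 30)
        idx = [f"s{i}" for i in range(n)]
        presence = pd.DataFrame({"u1": carrier}, index=idx)
        ph = pd.DataFrame({"dz": carrier}, index=idx)  # disease == carrier
        res = within_species_mwas(presence, ph, ["dz"], covariates=(),
                                  min_carriers=10)[0]
        assert res.status in {"separation", "nonconverged"}
        assert not res.significant


class TestAccumulationCurve:
    def test_perfectly_linear_discovery(self):
        novel = {f"s{i:03d}": {f"n{i}"} for i in range(40)}
        curve, slope500, r2 = accumulation_curve(novel, n_permutations=5, seed=0)
        assert slope500 == pytest.approx(500.0)
        assert r2 == pytest.approx(1.0)
        assert curve[-1] == 40

    def test_no_novel_species_flat(self):
        novel = {f"s{i}": set() for i in range(20)}
        _, slope500, _ = accumulation_curve(novel, n_permutations=3, seed=0)
        assert slope500 == 0.0

    def test_zero_permutations_error(self):
        with pytest.raises(ValueError):
            accumulation_curve({"s1": set()}, n_permutations=0)

    def test_linear_regime_high_r2(self):
        """Many rare novel species: discovery stays near-linear (R² > 0.95)."""
        rng = np.random.default_rng(11)
        novel = {
            f"s{i:03d}": {f"n{rng.integers(0, 10_000)}" for _ in range(3)}
            for i in range(100)
        }
        _, slope500, r2 = accumulation_curve(novel, n_permutations=10, seed=1)
        assert r2 > 0.95
        assert slope500 > 0


@given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=8))
@settings(max_examples=50, derandomize=True)
def test_clr_row_sums_zero_property(parts):
    x = pd.DataFrame([parts])
    assert abs(clr_transform(x).to_numpy().sum()) < 1e-9
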