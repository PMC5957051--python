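import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicemod.model import (
    CATEGORY_CONSTRAINTS,
    MODULATION_CATEGORIES,
    ModelConfig,
    ModulationFit,
    StratificationError,
    bh_fdr,
    classify,
    classify_pattern,
    fit_triplet,
    infer_triplets,
    permutation_p_gamma,
    sign_pattern,
    stratify_by_psi,
    unmodulated_activity,
)
from splicemod.simulate import SimConfig, PlantedTriplet, generate_dataset

SAMPLES30 = [f"s{i:02d}" for i in range(30)]


def series(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i:02d}" for i in range(len(values))]
    return pd.Series(values, index=samples)


def monotone_strata(n_per_stratum=30):
    """Strata over 2n samples: first half low, second half high."""
    labels = ["low"] * n_per_stratum + ["high"] * n_per_stratum
    idx = [f"s{i:03d}" for i in range(2 * n_per_stratum)]
    from splicemod.model import StratumLabels

    return StratumLabels(pd.Series(labels, index=idx, dtype=object), frac=0.5)


class TestStratify:
    def test_distinct_values_split_cleanly(self):
        psi = series(np.linspace(0.1, 0.9, 9))
        strata = stratify_by_psi(psi, frac=1 / 3, min_stratum_n=3)
        assert strata.low_samples == ["s00", "s01", "s02"]
        assert strata.high_samples == ["s06", "s07", "s08"]

    def test_thirty_percent_of_ten(self):
        psi = series(np.linspace(0, 1, 10))
        strata = stratify_by_psi(psi, frac=0.3, min_stratum_n=3)
        assert strata.n_low == 3 and strata.n_high == 3
        assert (strata.labels == "excluded").sum() == 4

    def test_ties_broken_by_stable_order(self):
        psi = series(np.full(12, 0.5))
        strata = stratify_by_psi(psi, frac=1 / 3, min_stratum_n=4)
        assert strata.low_samples == ["s00", "s01", "s02", "s03"]
        assert strata.high_samples == ["s08", "s09", "s10", "s11"]

    def test_missing_values_are_excluded(self):
        vals = np.linspace(0.1, 0.9, 9).tolist() + [np.nan] * 3
        strata = stratify_by_psi(series(vals), frac=1 / 3, min_stratum_n=3)
        assert strata.n_low == 3 and strata.n_high == 3
        assert all(strata.labels[f"s{i:02d}"] == "excluded" for i in (9, 10, 11))

    def test_too_few_samples_reports_counts(self):
        with pytest.raises(StratificationError) as err:
            stratify_by_psi(series(np.linspace(0, 1, 10)), frac=1 / 3, min_stratum_n=8)
        assert err.value.available == 10
        assert err.value.required >= 16


class TestFitTriplet:
    def test_no_modulation_when_target_equals_tf(self, rng):
        strata = monotone_strata(30)
        f = series(rng.normal(size=60), strata.labels.index.tolist())
        fit = fit_triplet(f, f.copy(), strata)
        assert fit.rho_low == pytest.approx(1.0)
        assert fit.rho_high == pytest.approx(1.0)
        assert fit.gamma == pytest.approx(0.0)
        assert fit.beta_m == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_inversion_is_exact(self, rng):
        strata = monotone_strata(30)
        f = series(rng.normal(size=60), strata.labels.index.tolist())
        m = np.array([0.0] * 30 + [1.0] * 30)
        t = series(f.to_numpy() * (1 - 2 * m), f.index.tolist())
        fit = fit_triplet(f, t, strata)
        assert fit.rho_low == pytest.approx(1.0)
        assert fit.rho_high == pytest.approx(-1.0)
        assert fit.gamma == pytest.approx(-2.0)
        assert fit.alpha_f > 0
        assert fit.mod_effect < 0

    def test_independent_target_gives_small_gamma(self, rng):
        strata = monotone_strata(30)
        f = series(rng.normal(size=60), strata.labels.index.tolist())
        t = series(rng.normal(size=60), f.index.tolist())
        fit = fit_triplet(f, t, strata)
        assert abs(fit.gamma) < 0.7
        p = permutation_p_gamma(f, t, strata, n_perm=199, seed=5)
        assert p > 0.01

    def test_constant_stratum_flags_degenerate(self):
        strata = monotone_strata(8)
        f = series([1.0] * 8 + list(range(8)), strata.labels.index.tolist())
        t = series(np.arange(16.0), strata.labels.index.tolist())
        fit = fit_triplet(f, t, strata)
        assert fit.degenerate
        assert "constant" in fit.reason

    def test_gamma_antisymmetric_under_stratum_swap(self, rng):
        strata = monotone_strata(15)
        f = series(rng.normal(size=30), strata.labels.index.tolist())
        t = series(rng.normal(size=30), f.index.tolist())
        fit = fit_triplet(f, t, strata)
        fit_sw = fit_triplet(f, t, strata.swapped())
        assert fit_sw.gamma == pytest.approx(-fit.gamma)
        assert fit_sw.beta_m == pytest.approx(-fit.beta_m)


class TestPermutation:
    def test_planted_inversion_has_tiny_p(self, rng):
        strata = monotone_strata(30)
        f = series(rng.normal(size=60), strata.labels.index.tolist())
        m = np.array([0.0] * 30 + [1.0] * 30)
        t = series(
            f.to_numpy() * (1 - 2 * m) + rng.normal(0, 0.1, 60), f.index.tolist()
        )
        p = permutation_p_gamma(f, t, strata, n_perm=999, seed=1)
        assert p <= 0.01

    def test_null_pvalues_roughly_uniform(self, rng):
        strata = monotone_strata(15)
        idx = strata.labels.index.tolist()
        pvals = []
        for rep in range(200):
            f = series(rng.normal(size=30), idx)
            t = series(rng.normal(size=30), idx)
            pvals.append(permutation_p_gamma(f, t, strata, n_perm=199, seed=rep))
        pvals = np.asarray(pvals)
        # mean of U(0,1) within Monte-Carlo tolerance and sensible tail mass
        assert abs(pvals.mean() - 0.5) < 0.08
        assert 0.005 < (pvals <= 0.1).mean() < 0.25

    def test_deterministic_given_seed_and_column_order(self, rng):
        strata = monotone_strata(12)
        idx = strata.labels.index.tolist()
        f = series(rng.normal(size=24), idx)
        t = series(rng.normal(size=24), idx)
        p1 = permutation_p_gamma(f, t, strata, n_perm=199, seed=42)
        p2 = permutation_p_gamma(f, t, strata, n_perm=199, seed=42)
        # reversing the sample (column) order must not change the p-value
        rev = idx[::-1]
        from splicemod.model import StratumLabels

        strata_rev = StratumLabels(strata.labels[rev], strata.frac)
        p3 = permutation_p_gamma(f[rev], t[rev], strata_rev, n_perm=199, seed=42)
        assert p1 == p2 == p3

    def test_too_few_permutations_rejected(self, rng):
        strata = monotone_strata(10)
        f = series(rng.normal(size=20), strata.labels.index.tolist())
        with pytest.raises(ValueError, match="n_perm"):
            permutation_p_gamma(f, f + 1, strata, n_perm=0, seed=1)


class TestBH:
    def test_hand_computed_example(self):
        # min over j >= i of p_(j) * m / j: all four collapse to 0.04
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_order_preserving_under_permutation(self, rng):
        p = rng.uniform(0.001, 1.0, size=17)
        q = bh_fdr(p)
        perm = rng.permutation(17)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])
        assert bh_fdr([]).size == 0


class TestClassify:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            # table rows, all columns significant
            ({"gamma": "+", "alpha_f": "-", "beta_f": "+", "beta_m": "+", "mod_effect": "+"},
             "inverts_inhibition"),
            ({"gamma": "-", "alpha_f": "+", "beta_f": "-", "beta_m": "-", "mod_effect": "-"},
             "inverts_activation"),
            # blank cells: only the constrained columns need to be significant
            ({"gamma": "+", "alpha_f": "-", "beta_f": "0", "beta_m": "0", "mod_effect": "0"},
             "attenuates_inhibition"),
            ({"gamma": "-", "alpha_f": "+", "beta_f": "0", "beta_m": "0", "mod_effect": "0"},
             "attenuates_activation"),
            ({"gamma": "-", "alpha_f": "0", "beta_f": "-", "beta_m": "-", "mod_effect": "-"},
             "enhances_inhibition"),
            ({"gamma": "+", "alpha_f": "0", "beta_f": "+", "beta_m": "+", "mod_effect": "+"},
             "enhances_activation"),
            # nothing significant
            ({"gamma": "0", "alpha_f": "0", "beta_f": "0", "beta_m": "0", "mod_effect": "0"},
             "unclassified"),
        ],
    )
    def test_table_rows(self, pattern, expected):
        assert classify_pattern(pattern) == expected

    def test_inversion_beats_attenuation_on_full_pattern(self):
        pattern = {"gamma": "+", "alpha_f": "-", "beta_f": "+", "beta_m": "+", "mod_effect": "+"}
        # both attenuates_inhibition and inverts_inhibition match; the more
        # specific inversion wins
        assert classify_pattern(pattern) == "inverts_inhibition"

    def test_relaxed_beta_f_column(self):
        pattern = {"gamma": "+", "alpha_f": "-", "beta_f": "0", "beta_m": "+", "mod_effect": "+"}
        assert classify_pattern(pattern, strict_all_columns=True) == "attenuates_inhibition"
        assert classify_pattern(pattern, strict_all_columns=False) == "inverts_inhibition"

    def test_classify_uses_significance_not_just_sign(self):
        # gamma significantly +, alpha_f significantly -, everything else n.s.
        fit = ModulationFit(
            gamma=0.9, alpha_f=-1.0, beta_f=0.1, beta_m=1.0,
            p_gamma=0.001, p_alpha_f=0.001, p_beta_f=0.6, p_beta_m=0.001,
            p_mod_effect=0.9, n_low=30, n_high=30,
        )
        assert sign_pattern(fit) == {
            "gamma": "+", "alpha_f": "-", "beta_f": "0", "beta_m": "+", "mod_effect": "0",
        }
        assert classify(fit) == "attenuates_inhibition"
        fit.p_gamma = 0.5  # gamma loses significance -> no category matches
        assert classify(fit) == "unclassified"

    def test_unmodulated_activity_labels(self):
        fit = ModulationFit(alpha_f=0.8, p_alpha_f=0.001)
        assert unmodulated_activity(fit) == "activation"
        fit = ModulationFit(alpha_f=-0.8, p_alpha_f=0.001)
        assert unmodulated_activity(fit) == "inhibition"
        fit = ModulationFit(alpha_f=-0.8, p_alpha_f=0.4)
        assert unmodulated_activity(fit) == "inactive"

    def test_exactly_six_categories(self):
        assert len(MODULATION_CATEGORIES) == 6
        assert set(CATEGORY_CONSTRAINTS) == set(MODULATION_CATEGORIES)


class TestInferTriplets:
    def _small_dataset(self, seed=3):
        cfg = SimConfig(
            seed=seed,
            n_samples=90,
            n_events=3,
            n_tfs=2,
            n_targets_per_tf=3,
            planted=(
                PlantedTriplet.with_default_effects(
                    "inverts_inhibition", event_index=0, tf="TF1", target="TG001"
                ),
            ),
        )
        return generate_dataset(cfg)

    def test_planted_inversion_recovered_among_nulls(self):
        expr, psi, tf_map, truth = self._small_dataset()
        from splicemod.qc import FilterConfig, run_qc

        expr, psi, _ = run_qc(expr, psi, FilterConfig())
        # with 18 candidates the smallest attainable BH q is n_cand/(n_perm+1),
        # so the permutation count must comfortably resolve the 5% FDR call
        trips = infer_triplets(expr, psi, tf_map, ModelConfig(seed=7, n_perm=999))
        called = [t for t in trips if t.called]
        assert len(called) == 1
        t = called[0]
        assert (t.modulator.canonical, t.tf, t.target) == (
            truth.at[0, "modulator_id"], "TF1", "TG001",
        )
        assert t.category == "inverts_inhibition"

    def test_missing_tf_skipped_without_crash(self):
        expr, psi, tf_map, _ = self._small_dataset()
        from splicemod.profiles import TFTargetMap

        bigger = TFTargetMap(tf_map.pairs | {("GHOST", "TG001")})
        trips = infer_triplets(expr, psi, bigger, ModelConfig(seed=7, n_perm=199))
        assert all(t.tf != "GHOST" for t in trips)

    def test_output_sorted_by_tf_then_q(self):
        expr, psi, tf_map, _ = self._small_dataset()
        trips = infer_triplets(expr, psi, tf_map, ModelConfig(seed=7, n_perm=199))
        keys = [(t.tf, t.fit.q_gamma) for t in trips]
        assert keys == sorted(keys)

    def test_seed_required(self):
        expr, psi, tf_map, _ = self._small_dataset()
        with pytest.raises(ValueError, match="seed"):
            infer_triplets(expr, psi, tf_map, ModelConfig())
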