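"""Differential-expression statistics: CPM, fold change, exact NB test,
dispersion estimation, BH adjustment and class-specific gates."""

import numpy as np
import pandas as pd
import pytest

import cernet
from cernet.errors import ConfigurationError, DegenerateSampleError

from .conftest import make_matrix
from .oracles import binomial_split_pvalue


class TestNormalizeCpm:
    def test_single_feature_columns_normalize_to_1e6(self):
        m = make_matrix([[5, 10, 3, 8, 1, 2]])
        cpm = cernet.normalize_cpm(m)
        assert np.allclose(cpm.to_numpy(), 1e6)

    def test_equal_split(self):
        m = make_matrix([[1] * 6, [1] * 6])
        cpm = cernet.normalize_cpm(m)
        assert np.allclose(cpm.to_numpy(), 5e5)

    def test_column_sums_equal_1e6(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(50, (40, 6)))
        cpm = cernet.normalize_cpm(m)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_names_sample(self):
        counts = np.ones((3, 6), dtype=int)
        counts[:, 2] = 0
        m = make_matrix(counts)
        with pytest.raises(DegenerateSampleError, match="NHS_H3"):
            cernet.normalize_cpm(m)


class TestLog2FoldChange:
    def test_identical_group_means_give_zero(self, design_3v3):
        m = make_matrix([[7, 7, 7, 7, 7, 7]], design_3v3)
        lfc = cernet.log2_fold_change(m, design_3v3)
        assert lfc.iloc[0] == pytest.approx(0.0)

    def test_doubling_gives_one_without_pseudocount(self, design_3v3):
        # two features keep CPM finite; second feature balances the library
        m = make_matrix([[10, 10, 10, 20, 20, 20], [20, 20, 20, 10, 10, 10]], design_3v3)
        lfc = cernet.log2_fold_change(m, design_3v3, pseudocount=0.0)
        assert lfc.iloc[0] == pytest.approx(1.0)
        assert lfc.iloc[1] == pytest.approx(-1.0)

    def test_label_swap_negates(self, design_3v3):
        swapped = cernet.generate_design(tissues=("hypothalamus",), conditions=("HS", "NHS"))
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(30, (20, 6)), design_3v3)
        a = cernet.log2_fold_change(m, design_3v3, pseudocount=0.0)
        b = cernet.log2_fold_change(m, swapped, pseudocount=0.0)
        assert np.allclose(a.to_numpy(), -b.to_numpy())


class TestNbExactTest:
    def test_identical_counts_give_p_one(self):
        assert cernet.nb_exact_test([5, 5, 5], [5, 5, 5], 0.2) == pytest.approx(1.0)
        assert cernet.nb_exact_test([0, 0], [0, 0], 0.0) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            cernet.nb_exact_test([1, 2], [3, 4], -0.1)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3)])
    def test_matches_rational_oracle_at_zero_dispersion(self, na, nb):
        """Dispersion 0 reduces to the exact binomial-split test."""
        for t in range(0, 16):
            for sa in range(t + 1):
                a = [sa] + [0] * (na - 1)
                b = [t - sa] + [0] * (nb - 1)
                got = cernet.nb_exact_test(a, b, 0.0)
                expected = float(binomial_split_pvalue(sa, t, na, nb))
                assert got == pytest.approx(expected, abs=1e-12)

    def test_label_swap_leaves_pvalue_unchanged(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.poisson(20, 3)
            b = rng.poisson(35, 3)
            assert cernet.nb_exact_test(a, b, 0.15) == pytest.approx(
                cernet.nb_exact_test(b, a, 0.15), rel=1e-10
            )

    def test_more_extreme_split_gives_smaller_p(self):
        p_mild = cernet.nb_exact_test([10, 10, 10], [14, 14, 14], 0.0)
        p_strong = cernet.nb_exact_test([5, 5, 5], [25, 25, 25], 0.0)
        assert p_strong < p_mild

    def test_power_monotone_in_effect_size(self):
        """Empirical power is nondecreasing in the planted |log2FC|."""
        def power(lfc, seed=9, n_features=500):
            rng = np.random.default_rng(seed)
            lam = np.exp(rng.normal(np.log(100), 1, n_features))
            r = 10.0
            mu_a = np.tile(lam[:, None], (1, 3))
            mu_b = mu_a * 2.0 ** lfc
            a = rng.negative_binomial(r, r / (r + mu_a))
            b = rng.negative_binomial(r, r / (r + mu_b))
            pvals = [cernet.nb_exact_test(a[i], b[i], 0.1) for i in range(n_features)]
            return np.mean(np.asarray(pvals) < 0.05)

        powers = [power(l) for l in (0.5, 1.0, 2.0)]
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.9


class TestDispersionEstimation:
    def test_poisson_counts_give_near_zero_dispersion(self, design_3v3):
        rng = np.random.default_rng(7)
        lam = np.exp(rng.normal(np.log(100), 1, 2000))
        m = make_matrix(rng.poisson(lam[:, None], (2000, 6)), design_3v3)
        assert cernet.estimate_common_dispersion(m, design_3v3) <= 0.01

    def test_feature_order_invariance(self, design_3v3):
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(5, 0.3, (200, 6))
        m = make_matrix(counts, design_3v3)
        shuffled = m.counts.sample(frac=1.0, random_state=1)
        m2 = cernet.ExpressionMatrix(shuffled, "mRNA", "hypothalamus")
        d1 = cernet.estimate_common_dispersion(m, design_3v3)
        d2 = cernet.estimate_common_dispersion(m2, design_3v3)
        assert d1 == pytest.approx(d2, rel=1e-6)


class TestBhAdjust:
    def test_hand_calculated_example(self):
        assert np.allclose(cernet.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_pvalue_unchanged(self):
        assert cernet.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(cernet.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            cernet.bh_adjust([0.5, 1.5])

    def test_output_in_unit_interval_and_bh_order_preserved(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        fdr = cernet.bh_adjust(p)
        assert ((fdr >= 0) & (fdr <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestGates:
    def _table(self, log2fc, pvalue, fdr):
        return pd.DataFrame(
            {"feature_id": ["x"], "log2fc": [log2fc], "pvalue": [pvalue], "fdr": [fdr]}
        )

    def test_fold_change_gate_blocks_small_effects(self):
        out = cernet.classify_significance(self._table(0.5, 0.001, 0.001), "circRNA")
        assert not out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "none"

    def test_mrna_uses_fdr_while_circrna_uses_pvalue(self):
        """The same feature passes as circRNA (p gate) but fails as mRNA (FDR gate)."""
        row = self._table(2.0, 0.01, 0.2)
        as_mrna = cernet.classify_significance(row, "mRNA")
        as_circ = cernet.classify_significance(row, "circRNA")
        assert not as_mrna["significant"].iloc[0]
        assert as_circ["significant"].iloc[0]

    def test_direction_thresholds(self):
        up = cernet.classify_significance(self._table(1.0, 0.2, 0.9), "miRNA")
        down = cernet.classify_significance(self._table(-1.2, 0.2, 0.9), "miRNA")
        assert up["direction"].iloc[0] == "up"
        assert down["direction"].iloc[0] == "down"

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            cernet.classify_significance(self._table(1, 0.5, 0.5), "lncRNA")


class TestCallDe:
    def test_gate_soundness_on_simulated_data(self, design_3v3):
        """Every significant row satisfies its class's printed thresholds."""
        cfg = cernet.SimulationConfig(
            n_features={"circRNA": 150, "miRNA": 100, "mRNA": 150},
            n_planted_triads=10, de_fraction=0.2, seed=4,
        )
        mats, _ = cernet.simulate_counts(design_3v3, cfg)
        for cls in ("circRNA", "miRNA", "mRNA"):
            table = cernet.call_de(mats[(cls, "hypothalamus")], design_3v3)
            sig = table[table["significant"]]
            assert (sig["log2fc"].abs() >= 1.0).all()
            if cls == "mRNA":
                assert (sig["fdr"] < 0.05).all()
            else:
                assert (sig["pvalue"] < 0.05).all()
            assert (sig["direction"] != "none").all()

    def test_planted_effects_are_detected(self, design_3v3):
        cfg = cernet.SimulationConfig(
            n_features={"circRNA": 5, "miRNA": 5, "mRNA": 300},
            de_fraction={"mRNA": 0.1}, n_planted_triads=0, seed=15,
        )
        mats, truth = cernet.simulate_counts(design_3v3, cfg)
        table = cernet.call_de(mats[("mRNA", "hypothalamus")], design_3v3)
        planted = {f for c, f, _ in truth.planted_de if c == "mRNA"}
        found = set(table.loc[table["significant"], "feature_id"])
        # 8-fold planted effects at 3 vs 3: most are recovered
        assert len(found & planted) >= 0.7 * len(planted)
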