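"""ML estimation, likelihood-ratio NCPs and chi-square power."""

import numpy as np
import pytest

from mrdoc.fit import FitResult, fit_ml, free_parameters, lrt_ncp, power_from_ncp
from mrdoc.models import ModelKind, ModelParams, implied_sigma, submodel_sigma
from mrdoc.simulate import exact_mvn_sample


def make_data(kind, params, n=1000, seed=0, check_mask=True):
    tc = implied_sigma(kind, params, check_mask=check_mask)
    mz = exact_mvn_sample(tc.sigma_mz, n, seed, group="MZ", var_order=tc.var_order_mz)
    dz = exact_mvn_sample(tc.sigma_dz, n, seed + 1, group="DZ", var_order=tc.var_order_dz)
    return mz, dz


GEN = {
    ModelKind.DOC: ModelParams(g1=0.04, ra=0.2, rc=0.2),
    ModelKind.MRDOC: ModelParams(g1=0.04, b1=0.05, b2=0.05, ra=0.2, rc=0.2),
    ModelKind.MRDOC2: ModelParams(
        g1=0.04, g2=0.02, b1=0.05, b3=0.025, ra=0.2, rc=0.2, re=0.2, rf=0.2
    ),
}


class TestRecovery:
    @pytest.mark.parametrize("kind", list(ModelKind))
    def test_exact_data_recovers_truth_from_generic_start(self, kind):
        """Fitting the generating model to its own exact data returns the
        generating values (within 1e-4) and a vanishing discrepancy, even
        from the default (non-truth) starting point."""
        gen = GEN[kind]
        mz, dz = make_data(kind, gen)
        fit = fit_ml(kind, mz, dz)  # default generic start
        assert fit.converged
        assert fit.minus2lnL < 1e-8
        est = fit.as_path_params()
        for name in est:
            assert est[name] == pytest.approx(getattr(gen, name), abs=1e-4), name

    def test_variable_count_mismatch_rejected(self):
        mz, dz = make_data(ModelKind.DOC, GEN[ModelKind.DOC])
        with pytest.raises(ValueError, match="marginalize"):
            fit_ml(ModelKind.MRDOC2, mz, dz)

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError, match="non-free"):
            free_parameters(ModelKind.DOC, {"b1": 0.0})


class TestMisspecificationSign:
    """Unmodeled E-confounding pushes the causal estimate in the direction
    of the confounding when re is fixed to zero in MR-DoC."""

    @pytest.mark.parametrize("re,comparison", [(0.3, "over"), (-0.3, "under")])
    def test_re_misspecification_biases_g1(self, re, comparison):
        gen = GEN[ModelKind.MRDOC2].with_(re=re)
        mz8, dz8 = make_data(ModelKind.MRDOC2, gen)
        from mrdoc.models import var_order_for

        mz = mz8.marginal(var_order_for(ModelKind.MRDOC, "MZ"))
        dz = dz8.marginal(var_order_for(ModelKind.MRDOC, "DZ"))
        fit = fit_ml(ModelKind.MRDOC, mz, dz, start=gen)
        assert fit.converged
        g1_hat = fit.param("g1")
        if comparison == "over":
            assert g1_hat > gen.g1
        else:
            assert g1_hat < gen.g1


class TestLRT:
    def test_true_constraint_gives_zero_ncp(self):
        gen = GEN[ModelKind.MRDOC2].with_(g1=0.0)
        mz, dz = make_data(ModelKind.MRDOC2, gen)
        full = fit_ml(ModelKind.MRDOC2, mz, dz, start=gen)
        con = fit_ml(ModelKind.MRDOC2, mz, dz, constraints={"g1": 0.0}, start=gen)
        lrt = lrt_ncp(full, con)
        assert lrt.ncp == 0.0
        assert lrt.df == 1

    def test_false_constraint_gives_positive_ncp_and_df2(self):
        gen = GEN[ModelKind.MRDOC2]
        mz, dz = make_data(ModelKind.MRDOC2, gen)
        full = fit_ml(ModelKind.MRDOC2, mz, dz, start=gen)
        con1 = fit_ml(ModelKind.MRDOC2, mz, dz, constraints={"g1": 0.0}, start=gen)
        con2 = fit_ml(ModelKind.MRDOC2, mz, dz, constraints={"g1": 0.0, "g2": 0.0}, start=gen)
        l1, l2 = lrt_ncp(full, con1), lrt_ncp(full, con2)
        assert l1.ncp > 0
        assert l2.df == 2
        # the fuller model never fits worse than its constrained versions
        assert con1.minus2lnL >= full.minus2lnL - 1e-8
        assert con2.minus2lnL >= con1.minus2lnL - 1e-8

    def test_ncp_invariant_to_seed(self):
        """Exact data fixes the sample moments, so the NCP cannot depend on
        which records realized them."""
        gen = GEN[ModelKind.MRDOC2]
        ncps = []
        for seed in (10, 99):
            mz, dz = make_data(ModelKind.MRDOC2, gen, seed=seed)
            full = fit_ml(ModelKind.MRDOC2, mz, dz, start=gen)
            con = fit_ml(ModelKind.MRDOC2, mz, dz, constraints={"g1": 0.0}, start=gen)
            ncps.append(lrt_ncp(full, con).ncp)
        assert ncps[0] == pytest.approx(ncps[1], abs=1e-6)

    def test_negative_statistic_is_an_error(self):
        a = FitResult(ModelKind.DOC, {}, 10.0, True, 9, 0.0, {})
        b = FitResult(ModelKind.DOC, {}, 9.0, True, 8, 0.0, {"g1": 0.0})
        with pytest.raises(ValueError, match="negative"):
            lrt_ncp(a, b)

    def test_objective_difference_matches_record_level_likelihood(self):
        """The covariance-ML NCP agrees with the raw-record -2lnL difference
        on exact data (an independent likelihood computation)."""
        gen = GEN[ModelKind.MRDOC]
        mz, dz = make_data(ModelKind.MRDOC, gen)
        full = fit_ml(ModelKind.MRDOC, mz, dz, start=gen)
        con = fit_ml(ModelKind.MRDOC, mz, dz, constraints={"g1": 0.0}, start=gen)

        def raw_m2ll(fit):
            p = {**fit.constraints, **fit.estimates}
            kw = {{"CA": "ra", "CC": "rc"}.get(k, k): v for k, v in p.items()}
            tc = implied_sigma(ModelKind.MRDOC, ModelParams(**kw), style="varcomp",
                               check_mask=False)
            total = 0.0
            for gd, sig in ((mz, tc.sigma_mz), (dz, tc.sigma_dz)):
                k = sig.shape[0]
                _, logdet = np.linalg.slogdet(sig)
                quad = np.einsum("ij,jk,ik->", gd.values, np.linalg.inv(sig), gd.values)
                total += gd.n_pairs * (k * np.log(2 * np.pi) + logdet) + quad
            return total

        ncp_cov = con.minus2lnL - full.minus2lnL
        ncp_raw = raw_m2ll(con) - raw_m2ll(full)
        # the conventions differ by O(1/n) in the trace multiplier
        assert ncp_cov == pytest.approx(ncp_raw, rel=0.02)


class TestPower:
    def test_null_power_equals_size(self):
        assert power_from_ncp(0.0, 1, 0.05) == 0.05

    def test_monotone_in_ncp(self):
        grid = np.linspace(0.0, 40.0, 30)
        powers = [power_from_ncp(x, 1, 0.05) for x in grid]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_canonical_80_percent_point(self):
        # df=1, alpha=.05: NCP 7.849 is the classic 80%-power point
        assert power_from_ncp(7.849, 1, 0.05) == pytest.approx(0.80, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_from_ncp(-1.0, 1, 0.05)
        with pytest.raises(ValueError):
            power_from_ncp(1.0, 1, 1.5)
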