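"""Factorial simulation studies: bias under misspecification and NCP power.

Five scenarios over three factorial designs (one per model):

* ``S1_error`` — each model generates its own design's data, phenotype
  measurement error is injected (default reliabilities 0.90 exposure /
  0.70 outcome), and the same model is refit.
* ``S2_re`` — each model's design gains an unshared-environment
  correlation factor re in {-0.3, +0.3} at generation; DoC and MR-DoC are
  refit with their identifying constraint re = 0, MR-DoC2 refits re freely.
* ``S3_error_mrdoc2gen`` — MR-DoC2 (Design 3) generates; measurement error
  is injected; all three models are fit to the (marginalized) data.
* ``S4_re_mrdoc2gen`` — MR-DoC2 generates with re in {-0.3, +0.3}; all
  three models are fit.
* ``S5_power`` — MR-DoC2 generates Design 3 as stated (re = rf = 0.2); for
  each fitted model the likelihood-ratio NCP of the test g1 = 0 is
  extracted and converted to power, and the 64 per-cell NCPs are regressed
  on the six varying factor values.

Every cell uses exact data (sample covariance == population covariance), so
all quantities are deterministic functions of the design, not of the seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fit import FitResult, fit_ml, free_parameters, lrt_ncp, power_from_ncp
from .models import ModelKind, ModelParams, TwinCovariance, implied_sigma, submodel_sigma
from .simulate import ErrorSpec, GroupData, add_measurement_error, exact_mvn_sample

logger = logging.getLogger(__name__)

__all__ = [
    "DesignGrid",
    "RunConfig",
    "PowerRegressionResult",
    "design_grid",
    "cell_params",
    "run_scenario",
    "bias_summary",
    "ncp_regression",
    "SCENARIOS",
]

SCENARIOS = ("S1_error", "S2_re", "S3_error_mrdoc2gen", "S4_re_mrdoc2gen", "S5_power")

# variance components common to all designs; E completes each trait to unit
# residual variance
_FIXED_ACE = {"VA1": 0.10, "VC1": 0.10, "VE1": 0.80, "VA2": 0.10, "VC2": 0.10, "VE2": 0.80}

# Factorial levels of the causal and instrument paths are quoted on the
# variance-fraction (R^2) scale — e.g. instrument levels 0.025/0.05 mean
# path coefficients 0.158/0.224, i.e. instruments explaining 2.5%/5% of
# exposure variance; the generating path is the square root of the level.
# The ra/rc/re/rf levels enter as the raw cross-covariances of the
# variance-component parameterization (this is what reproduces the
# covariance change of 0.300 / 0.085 that re = 0.3 induces in MR-DoC).
PATH_FACTORS = frozenset({"g1", "g2", "b1", "b2", "b3"})
COV_FACTORS = frozenset({"ra", "rc", "re", "rf"})


@dataclass(frozen=True)
class DesignGrid:
    """One factorial design: varying factors (parameter -> levels) and the
    constants, with the model that generates it."""

    design_id: int
    generator_kind: ModelKind
    factors: dict[str, list[float]]
    fixed: dict[str, float]

    @property
    def cells(self) -> list[dict[str, float]]:
        names = list(self.factors)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.factors[n] for n in names))
        ]

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(v) for v in self.factors.values()]))


def design_grid(design_id: int) -> DesignGrid:
    """Designs 1-3: DoC (2^3 = 8 cells), MR-DoC (2^5 = 32), MR-DoC2 (2^6 = 64)."""
    two = {"g1": [0.02, 0.04], "ra": [0.0, 0.2], "rc": [0.0, 0.2]}
    if design_id == 1:
        return DesignGrid(1, ModelKind.DOC, dict(two), dict(_FIXED_ACE))
    if design_id == 2:
        factors = {"b1": [0.025, 0.05], "b2": [0.025, 0.05], **two}
        return DesignGrid(2, ModelKind.MRDOC, factors, dict(_FIXED_ACE))
    if design_id == 3:
        factors = {
            "b1": [0.025, 0.05],
            "b3": [0.025, 0.05],
            "g1": [0.02, 0.04],
            "g2": [0.02, 0.04],
            "ra": [0.0, 0.2],
            "rc": [0.0, 0.2],
        }
        return DesignGrid(3, ModelKind.MRDOC2, factors, {**_FIXED_ACE, "re": 0.2, "rf": 0.2})
    raise ValueError(f"unknown design {design_id}; expected 1, 2 or 3")


def cell_params(grid: DesignGrid, cell: dict[str, float], re_override: float | None = None) -> ModelParams:
    """Generating parameter vector for one design cell, on the
    variance-component scale: the ``ra``/``rc``/``re``/``rf`` fields of the
    returned ``ModelParams`` hold raw cross-covariances, and causal and
    instrument paths are the square roots of the quoted variance-fraction
    levels.  Use with ``implied_sigma(..., style='varcomp')``."""
    vals = {**grid.fixed, **cell}
    if re_override is not None:
        vals["re"] = re_override
    vals = {k: (np.sqrt(v) if k in PATH_FACTORS else v) for k, v in vals.items()}
    return ModelParams(**vals)


def varcomp_truth(gen: ModelParams) -> dict[str, float]:
    """The generating values keyed by the fitter's free-parameter names
    (``CA``/``CC``/``CE``/``CF`` are the raw cross-covariances that sit in
    the correlation-named slots of a varcomp-style ``ModelParams``)."""
    out = {k: getattr(gen, k) for k in (
        "g1", "g2", "b1", "b2", "b3",
        "VA1", "VC1", "VE1", "VA2", "VC2", "VE2", "vP1", "vP2",
    )}
    out.update(CA=gen.ra, CC=gen.rc, CE=gen.re, CF=gen.rf)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything one scenario run depends on."""

    scenario: str = "S5_power"
    n_mz: int = 1000
    n_dz: int = 1000
    alpha: float = 0.05
    rhoX: float = 0.90
    rhoY: float = 0.70
    re_levels: tuple[float, float] = (-0.3, 0.3)
    master_seed: int = 2024
    start_at_truth: bool = True
    include_2df: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_mz <= 8 or self.n_dz <= 8:
            raise ValueError("need more twin pairs than observed variables per group")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        ErrorSpec(self.rhoX, self.rhoY).validate()
        if self.scenario in ("S2_re", "S4_re_mrdoc2gen") and not self.re_levels:
            raise ValueError(f"{self.scenario} requires at least one re level")
        if not 0 <= self.master_seed < 2**31:
            raise ValueError("master_seed must be a non-negative 31-bit integer")


@dataclass(frozen=True)
class PowerRegressionResult:
    """OLS of per-cell NCPs on the varying design-factor values."""

    fitted_kind: ModelKind
    coefficients: dict[str, float]
    standardized: dict[str, float]   # slope * sd(factor) / sd(ncp)
    intercept: float
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "fitted_kind": self.fitted_kind.value,
            "coefficients": dict(self.coefficients),
            "standardized": dict(self.standardized),
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


def _cell_seed(master: int, design_id: int, cell_index: int, stream: int) -> int:
    ss = np.random.SeedSequence([master, design_id, cell_index, stream])
    return int(ss.generate_state(1)[0])


def _simulate_groups(tc: TwinCovariance, cfg: RunConfig, design_id: int, cell_index: int):
    mz = exact_mvn_sample(
        tc.sigma_mz, cfg.n_mz, _cell_seed(cfg.master_seed, design_id, cell_index, 0),
        group="MZ", var_order=tc.var_order_mz,
    )
    dz = exact_mvn_sample(
        tc.sigma_dz, cfg.n_dz, _cell_seed(cfg.master_seed, design_id, cell_index, 1),
        group="DZ", var_order=tc.var_order_dz,
    )
    return mz, dz


def _bias_record(fit: FitResult, gen: ModelParams) -> dict[str, float]:
    """true_/est_/bias_ columns for every free parameter of the fitted
    model, on the variance-component scale."""
    truth = varcomp_truth(gen)
    rec = {}
    for name in free_parameters(fit.kind, fit.constraints):
        rec[f"true_{name}"] = truth[name]
        rec[f"est_{name}"] = fit.estimates[name]
        rec[f"bias_{name}"] = fit.estimates[name] - truth[name]
    return rec


def _fit_with_start(kind, mz, dz, gen, cfg, constraints=None, label=""):
    start = varcomp_truth(gen) if cfg.start_at_truth else None
    return fit_ml(kind, mz, dz, constraints=constraints, start=start, label=label)


def _marginal_data(mz: GroupData, dz: GroupData, kind: ModelKind):
    from .models import var_order_for

    want_mz, want_dz = var_order_for(kind, "MZ"), var_order_for(kind, "DZ")
    if mz.var_order == want_mz and dz.var_order == want_dz:
        return mz, dz
    return mz.marginal(want_mz), dz.marginal(want_dz)


def run_scenario(scenario: str, config: RunConfig | None = None) -> pd.DataFrame:
    """Run one scenario end-to-end; returns one tidy row per design cell x
    (re level x) fitted model.  Deterministic given the configuration."""
    from dataclasses import replace

    cfg = replace(config or RunConfig(), scenario=scenario)
    cfg.validate()

    rows: list[dict] = []
    if scenario in ("S1_error", "S2_re"):
        # own-model generation on each model's design
        for design_id in (1, 2, 3):
            grid = design_grid(design_id)
            kind = grid.generator_kind
            for idx, cell in enumerate(grid.cells):
                re_levels = cfg.re_levels if scenario == "S2_re" else (None,)
                for re_level in re_levels:
                    gen = cell_params(grid, cell, re_override=re_level)
                    # DoC / MR-DoC fix re = 0 when *fitting*; in S2 the
                    # generating process violates that, hence no mask check
                    tc = implied_sigma(kind, gen, style="varcomp", check_mask=False)
                    if scenario == "S1_error":
                        tc = add_measurement_error(tc, ErrorSpec(cfg.rhoX, cfg.rhoY))
                    mz, dz = _simulate_groups(tc, cfg, design_id, idx)
                    fit = _fit_with_start(kind, mz, dz, gen, cfg, label=f"D{design_id}c{idx}")
                    rows.append(
                        {
                            "scenario": scenario,
                            "design_id": design_id,
                            "cell_index": idx,
                            "re_level": np.nan if re_level is None else re_level,
                            "generator_kind": kind.value,
                            "fitted_kind": kind.value,
                            "converged": fit.converged,
                            **{f"factor_{k}": v for k, v in cell.items()},
                            **_bias_record(fit, gen),
                        }
                    )
    elif scenario in ("S3_error_mrdoc2gen", "S4_re_mrdoc2gen", "S5_power"):
        grid = design_grid(3)
        re_levels = cfg.re_levels if scenario == "S4_re_mrdoc2gen" else (None,)
        for idx, cell in enumerate(grid.cells):
            for re_level in re_levels:
                gen = cell_params(grid, cell, re_override=re_level)
                tc = implied_sigma(ModelKind.MRDOC2, gen, style="varcomp")
                if scenario == "S3_error_mrdoc2gen":
                    tc = add_measurement_error(tc, ErrorSpec(cfg.rhoX, cfg.rhoY))
                mz8, dz8 = _simulate_groups(tc, cfg, 3, idx)
                for fitted in (ModelKind.DOC, ModelKind.MRDOC, ModelKind.MRDOC2):
                    mz, dz = _marginal_data(mz8, dz8, fitted)
                    label = f"D3c{idx}-{fitted.value}"
                    fit = _fit_with_start(fitted, mz, dz, gen, cfg, label=label)
                    row = {
                        "scenario": scenario,
                        "design_id": 3,
                        "cell_index": idx,
                        "re_level": np.nan if re_level is None else re_level,
                        "generator_kind": ModelKind.MRDOC2.value,
                        "fitted_kind": fitted.value,
                        "converged": fit.converged,
                        **{f"factor_{k}": v for k, v in cell.items()},
                        **_bias_record(fit, gen),
                    }
                    if scenario == "S5_power":
                        con = _fit_with_start(
                            fitted, mz, dz, gen, cfg,
                            constraints={"g1": 0.0}, label=label + "-g1_0",
                        )
                        lrt = lrt_ncp(fit, con)
                        row.update(
                            ncp=lrt.ncp, df=lrt.df,
                            power=power_from_ncp(lrt.ncp, lrt.df, cfg.alpha),
                            converged=fit.converged and con.converged,
                        )
                        if cfg.include_2df and fitted is ModelKind.MRDOC2:
                            con2 = _fit_with_start(
                                fitted, mz, dz, gen, cfg,
                                constraints={"g1": 0.0, "g2": 0.0}, label=label + "-g1g2_0",
                            )
                            lrt2 = lrt_ncp(fit, con2)
                            row.update(
                                ncp_2df=lrt2.ncp, df_2df=lrt2.df,
                                power_2df=power_from_ncp(lrt2.ncp, lrt2.df, cfg.alpha),
                            )
                    rows.append(row)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    df = pd.DataFrame(rows)
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        logger.warning("%d of %d fits did not converge in %s", n_bad, len(df), scenario)
    return df


def bias_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (estimate - truth) per parameter per fitted model across cells.

    Negative means underestimation.  Non-converged fits are excluded with a
    logged count."""
    if results is None or len(results) == 0:
        raise ValueError("no study results to summarize")
    if results["scenario"].nunique() > 1:
        raise ValueError("bias_summary expects results from a single scenario")
    ok = results[results["converged"]]
    dropped = len(results) - len(ok)
    if dropped:
        logger.warning("bias_summary: excluding %d non-converged fits", dropped)
    if len(ok) == 0:
        raise ValueError("no converged fits to summarize")
    bias_cols = [c for c in ok.columns if c.startswith("bias_")]
    out = (
        ok.groupby("fitted_kind")[bias_cols]
        .mean()
        .rename(columns=lambda c: c.removeprefix("bias_"))
    )
    out.columns.name = "parameter"
    return out


def ncp_regression(results: pd.DataFrame, fitted_kind: ModelKind) -> PowerRegressionResult:
    """OLS of the per-cell g1 = 0 NCPs on the six varying Design-3 factors.

    The R-squared measures how much of the variation in power (via the NCP)
    the parameter values explain for the given fitted model; the constants
    re = rf = 0.2 are absorbed by the intercept."""
    fitted_kind = ModelKind(fitted_kind)
    sub = results[(results["fitted_kind"] == fitted_kind.value) & results["converged"]]
    if len(sub) == 0:
        raise ValueError(f"no converged S5 records for {fitted_kind.value}")
    if "ncp" not in sub.columns or sub["ncp"].isna().any():
        raise ValueError("results lack NCPs; run scenario S5_power first")
    factor_cols = [c for c in sub.columns if c.startswith("factor_")]
    X = sub[factor_cols].rename(columns=lambda c: c.removeprefix("factor_"))
    y = sub["ncp"].to_numpy()
    if np.allclose(y.std(), 0.0):
        raise ValueError("NCP is constant across cells; R-squared is undefined")
    Xmat = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        sds = X.std()
        flat = [c for c in X.columns if sds[c] == 0]
        raise ValueError(f"design matrix is rank deficient; collinear/constant columns: {flat}")
    model = sm.OLS(y, Xmat).fit()
    coefs = dict(zip(X.columns, model.params[1:]))
    y_sd = y.std(ddof=1)
    standardized = {c: coefs[c] * X[c].std(ddof=1) / y_sd for c in X.columns}
    return PowerRegressionResult(
        fitted_kind=fitted_kind,
        coefficients=coefs,
        standardized=standardized,
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
    )
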