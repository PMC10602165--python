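"""Multigroup normal-theory ML estimation, likelihood-ratio NCPs, and power.

Fitting is done in the variance-component parameterization: the free
quantities are the A/C/E variances and cross-trait covariances (``VA1``,
``CA``, ...) rather than factor loadings, alongside the causal and
instrument regression weights.  The discrepancy minimized over the MZ and
DZ groups jointly is

    F(theta) = sum_g N_g * [ ln|Sigma_g(theta)| + tr(S_g Sigma_g(theta)^-1)
                             - ln|S_g| - p ]

with S_g the sample covariance (divisor n-1), means fixed at zero.  F is
zero when the model reproduces both sample matrices exactly, which is the
situation exact-data simulation engineers for the generating model; for a
constrained refit on the same data, the increase in F equals the
likelihood-ratio statistic and hence the non-centrality parameter of the
test of the constraint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2, ncx2

from .models import ModelKind, ModelParams, implied_sigma
from .simulate import GroupData

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "LRTResult", "fit_ml", "lrt_ncp", "power_from_ncp", "free_parameters"]

# Free parameters per model, variance-component style.  CA/CC/CE are the
# cross-trait A/C/E covariances, CF the PS1-PS2 covariance; they ride in the
# ra/rc/re/rf slots of ModelParams under style="varcomp".
_ACE = ("VA1", "VC1", "VE1", "VA2", "VC2", "VE2", "CA", "CC")
_FREE: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.DOC: ("g1",) + _ACE,
    ModelKind.MRDOC: ("g1", "b1", "b2") + _ACE + ("vP1",),
    ModelKind.MRDOC2: ("g1", "g2", "b1", "b3") + _ACE + ("CE", "vP1", "vP2", "CF"),
}
_COV_ALIAS = {"CA": "ra", "CC": "rc", "CE": "re", "CF": "rf"}
_VARIANCES = {"VA1", "VC1", "VE1", "VA2", "VC2", "VE2", "vP1", "vP2"}

_GRAD_TOL = 1e-3      # on the N-scaled objective; see docs for the scaling
_NCP_CLIP = 1e-8


def free_parameters(kind: ModelKind, constraints: dict[str, float] | None = None) -> list[str]:
    """Names of the parameters estimated for ``kind`` after applying
    ``constraints`` ({name: fixed value})."""
    kind = ModelKind(kind)
    cons = constraints or {}
    unknown = set(cons) - set(_FREE[kind])
    if unknown:
        raise ValueError(f"constraints name non-free parameters of {kind.value}: {sorted(unknown)}")
    return [p for p in _FREE[kind] if p not in cons]


@dataclass(frozen=True)
class FitResult:
    kind: ModelKind
    estimates: dict[str, float]        # free parameters only, varcomp style
    minus2lnL: float                   # discrepancy F at the optimum
    converged: bool
    n_free: int
    gradient_norm: float
    constraints: dict[str, float] = field(default_factory=dict)

    def param(self, name: str) -> float:
        if name in self.estimates:
            return self.estimates[name]
        if name in self.constraints:
            return self.constraints[name]
        raise KeyError(name)

    def as_path_params(self) -> dict[str, float]:
        """All parameter values with A/C/E/PGS covariances converted back to
        correlations (ra, rc, re, rf); zero-variance factors yield 0."""
        vals = {**dict.fromkeys(_FREE[self.kind], 0.0), **self.constraints, **self.estimates}
        out = {k: v for k, v in vals.items() if k not in _COV_ALIAS}
        pairs = {"CA": ("VA1", "VA2"), "CC": ("VC1", "VC2"), "CE": ("VE1", "VE2"), "CF": ("vP1", "vP2")}
        for cov, (v1, v2) in pairs.items():
            if cov in vals:
                denom = math.sqrt(max(vals.get(v1, 0.0), 0.0) * max(vals.get(v2, 0.0), 0.0))
                out[_COV_ALIAS[cov]] = vals[cov] / denom if denom > 1e-12 else 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "estimates": dict(self.estimates),
            "constraints": dict(self.constraints),
            "minus2lnL": self.minus2lnL,
            "converged": self.converged,
            "n_free": self.n_free,
            "gradient_norm": self.gradient_norm,
        }


@dataclass(frozen=True)
class LRTResult:
    ncp: float
    df: int
    alpha: float | None = None
    power: float | None = None

    def with_power(self, alpha: float = 0.05) -> "LRTResult":
        return LRTResult(self.ncp, self.df, alpha, power_from_ncp(self.ncp, self.df, alpha))

    def to_dict(self) -> dict:
        return {"ncp": self.ncp, "df": self.df, "alpha": self.alpha, "power": self.power}


def _params_from_vector(kind, names, theta, fixed):
    vals = dict(fixed)
    vals.update(zip(names, theta))
    kwargs = {}
    for name, v in vals.items():
        kwargs[_COV_ALIAS.get(name, name)] = v
    return ModelParams(**kwargs)


def _sigma_pair(kind, names, theta, fixed):
    p = _params_from_vector(kind, names, theta, fixed)
    tc = implied_sigma(kind, p, style="varcomp", check_mask=False)
    return tc.sigma_mz, tc.sigma_dz


def start_vector(
    kind: ModelKind, names: list[str], start: "ModelParams | dict[str, float] | None"
) -> np.ndarray:
    """Starting values: the generating truth when supplied — either a
    path-style ``ModelParams`` (correlations converted to covariances) or a
    ready dict on the variance-component scale — else variances 0.3 and
    paths/covariances 0.01."""
    if start is None:
        return np.array([0.3 if n in _VARIANCES else 0.01 for n in names])
    if isinstance(start, dict):
        return np.array(
            [start.get(n, 0.3 if n in _VARIANCES else 0.01) for n in names]
        )
    conv = {
        "CA": start.ra * math.sqrt(start.VA1 * start.VA2),
        "CC": start.rc * math.sqrt(start.VC1 * start.VC2),
        "CE": start.re * math.sqrt(start.VE1 * start.VE2),
        "CF": start.rf * math.sqrt(start.vP1 * start.vP2),
    }
    return np.array([conv[n] if n in conv else getattr(start, n) for n in names])


def fit_ml(
    kind: ModelKind,
    data_mz: GroupData,
    data_dz: GroupData,
    constraints: dict[str, float] | None = None,
    start: "ModelParams | dict[str, float] | None" = None,
    *,
    label: str = "",
) -> FitResult:
    """Minimize the multigroup ML discrepancy for ``kind`` over its free
    parameters, with ``constraints`` ({name: value}) held fixed.

    Deterministic given the data and the start.  Non-convergence is flagged
    on the result and logged, never silent.
    """
    kind = ModelKind(kind)
    cons = dict(constraints or {})
    names = free_parameters(kind, cons)
    from .models import var_order_for

    for gd, grp in ((data_mz, "MZ"), (data_dz, "DZ")):
        expected = var_order_for(kind, grp)
        if len(gd.var_order) != len(expected):
            raise ValueError(
                f"{kind.value} observes {len(expected)} variables in the {grp} group, "
                f"data has {len(gd.var_order)}; marginalize upstream"
            )

    groups = []
    for gd in (data_mz, data_dz):
        S = gd.sample_cov
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(f"sample covariance of {gd.group} group is not positive definite")
        groups.append((gd.n_pairs, S, logdet_S, S.shape[0]))

    def discrepancy(theta):
        """F and the per-group weight matrices W_g = Sigma^-1 (Sigma - S) Sigma^-1."""
        try:
            sig_mz, sig_dz = _sigma_pair(kind, names, theta, cons)
        except ValueError:
            return None
        F = 0.0
        weights = []
        for (n, S, logdet_S, p), sig in zip(groups, (sig_mz, sig_dz)):
            try:
                c, low = linalg.cho_factor(sig, lower=True)
            except linalg.LinAlgError:
                return None
            logdet = 2.0 * np.log(np.diag(c)).sum()
            inv = linalg.cho_solve((c, low), np.eye(p))
            F += n * (logdet + (inv * S).sum() - logdet_S - p)
            weights.append(n * (inv - inv @ S @ inv))
        # soft guard against the causal-loop unit root |g1*g2| -> 1
        g1 = theta[names.index("g1")] if "g1" in names else cons.get("g1", 0.0)
        g2 = theta[names.index("g2")] if "g2" in names else cons.get("g2", 0.0)
        if abs(g1 * g2) >= 0.99:
            F += 1e6 * (abs(g1 * g2) - 0.99)
        return F, weights

    penalty_count = 0

    def fun(theta):
        out = discrepancy(theta)
        if out is None:
            nonlocal penalty_count
            penalty_count += 1
            return 1e10 * (1.0 + float(theta @ theta))
        return out[0]

    h = 1e-6

    def jac(theta):
        out = discrepancy(theta)
        if out is None:
            return 2e10 * theta
        _, weights = out
        grad = np.empty(len(theta))
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            try:
                sp = _sigma_pair(kind, names, tp, cons)
                sm = _sigma_pair(kind, names, tm, cons)
            except ValueError:
                grad[k] = 0.0
                continue
            grad[k] = sum(
                (W * ((a - b) / (2 * h))).sum() for W, a, b in zip(weights, sp, sm)
            )
        return grad

    # variance components are deliberately unbounded: in the
    # variance-component parameterization a mis-specified model may need
    # negative variance estimates, and boundary solutions would distort the
    # likelihood-ratio statistics; positive definiteness of the implied
    # covariance is enforced by the penalty instead
    theta0 = start_vector(kind, names, start)

    def run(x0):
        return optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B",
            options={"maxiter": 3000, "ftol": 1e-15, "gtol": 1e-8, "maxcor": 30},
        )

    res = run(theta0)
    grad_norm = float(np.linalg.norm(jac(res.x), ord=np.inf))
    if grad_norm > _GRAD_TOL:
        # one restart from a perturbed start, keeping the better optimum
        rng = np.random.default_rng(0)
        res2 = run(res.x + 0.01 * rng.standard_normal(len(names)))
        if res2.fun < res.fun:
            res = res2
        grad_norm = float(np.linalg.norm(jac(res.x), ord=np.inf))

    converged = bool(grad_norm <= _GRAD_TOL and np.isfinite(res.fun))
    if not converged:
        logger.warning(
            "fit of %s%s did not converge (|grad|=%.2e, F=%.4g, %d singular evals)",
            kind.value, f" [{label}]" if label else "", grad_norm, res.fun, penalty_count,
        )
    return FitResult(
        kind=kind,
        estimates=dict(zip(names, (float(v) for v in res.x))),
        minus2lnL=float(res.fun),
        converged=converged,
        n_free=len(names),
        gradient_norm=grad_norm,
        constraints=cons,
    )


def lrt_ncp(full: FitResult, constrained: FitResult) -> LRTResult:
    """Likelihood-ratio statistic of a constrained refit against the fuller
    fit on the same data; under exact data this is the non-centrality
    parameter of the chi-square test of the constraint."""
    if full.kind != constrained.kind:
        raise ValueError("fits are for different models")
    if not set(constrained.constraints) > set(full.constraints):
        raise ValueError("constrained fit must add constraints to the full fit")
    ncp = constrained.minus2lnL - full.minus2lnL
    if ncp < -_NCP_CLIP:
        raise ValueError(
            f"negative likelihood-ratio statistic ({ncp:.3e}): optimization failure, "
            "not a test statistic"
        )
    ncp = max(ncp, 0.0)
    if ncp < _NCP_CLIP:
        ncp = 0.0
    return LRTResult(ncp=ncp, df=full.n_free - constrained.n_free)


def power_from_ncp(ncp: float, df: int, alpha: float = 0.05) -> float:
    """Power of the chi-square(df) test at level ``alpha`` when the
    likelihood-ratio statistic is noncentral chi-square with ``ncp``."""
    if ncp < 0:
        raise ValueError("ncp must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    crit = chi2.ppf(1.0 - alpha, df)
    if ncp == 0.0:
        return alpha  # size of the test: the null distribution is central
    return float(ncx2.sf(crit, df, ncp))
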