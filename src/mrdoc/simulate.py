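"""Exact multivariate-normal data simulation and measurement-error injection.

Exact simulation produces a finite sample whose column means are zero and
whose sample covariance (divisor n-1) equals a target population covariance
to machine precision.  Maximum-likelihood fits of the generating model to
such data recover the generating parameters, and likelihood-ratio statistics
for constrained refits equal non-centrality parameters — which is what makes
the downstream power calculations deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .models import TwinCovariance

__all__ = ["GroupData", "ErrorSpec", "exact_mvn_sample", "add_measurement_error"]


@dataclass(frozen=True)
class GroupData:
    """Exact-simulated records for one zygosity group."""

    group: str                 # "MZ" or "DZ"
    n_pairs: int
    values: np.ndarray         # n_pairs x p, columns per var_order
    sample_cov: np.ndarray     # p x p, divisor n-1; equals the target
    var_order: tuple[str, ...]
    seed: int

    def to_csv(self, path) -> None:
        """One row per twin pair, columns per var_order."""
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.var_order)).to_csv(path, index=False)

    def marginal(self, var_order: tuple[str, ...]) -> "GroupData":
        """Restrict to a subset of observed variables (e.g. the columns a
        smaller model observes); exactness of the sample moments carries over."""
        try:
            idx = [self.var_order.index(v) for v in var_order]
        except ValueError as exc:
            raise ValueError(f"variable not present in data: {exc}") from exc
        return GroupData(
            group=self.group,
            n_pairs=self.n_pairs,
            values=self.values[:, idx],
            sample_cov=self.sample_cov[np.ix_(idx, idx)],
            var_order=tuple(var_order),
            seed=self.seed,
        )


@dataclass(frozen=True)
class ErrorSpec:
    """Phenotype reliabilities; a reliability of 1.0 adds no error."""

    rhoX: float = 1.0
    rhoY: float = 1.0

    def validate(self) -> None:
        for name, rho in (("rhoX", self.rhoX), ("rhoY", self.rhoY)):
            if not 0.0 < rho <= 1.0:
                raise ValueError(f"reliability {name} must lie in (0, 1], got {rho}")


def exact_mvn_sample(
    target: np.ndarray,
    n_pairs: int,
    seed: int,
    *,
    group: str = "MZ",
    var_order: tuple[str, ...] | None = None,
) -> GroupData:
    """Draw zero-mean normal data whose sample covariance equals ``target``.

    Recipe: draw arbitrary normal deviates, center them, whiten by the
    inverse Cholesky factor of their own sample covariance, then recolor by
    the Cholesky factor of the target.  The guarantee is on the first two
    sample moments; individual records differ across seeds.
    """
    target = np.asarray(target, dtype=float)
    p = target.shape[0]
    if target.shape != (p, p):
        raise ValueError("target covariance must be square")
    if n_pairs <= p:
        raise ValueError(f"need n_pairs > {p} observed variables to whiten, got {n_pairs}")
    try:
        L_target = linalg.cholesky(target, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("target covariance is not positive definite") from exc

    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_pairs, p))
    Z -= Z.mean(axis=0)
    S_raw = (Z.T @ Z) / (n_pairs - 1)
    L_raw = linalg.cholesky(S_raw, lower=True)
    # rows: z_i -> L_target @ L_raw^{-1} @ z_i
    W = linalg.solve_triangular(L_raw, Z.T, lower=True)
    X = (L_target @ W).T
    X -= X.mean(axis=0)  # exact re-centering guards against rounding drift

    S = (X.T @ X) / (n_pairs - 1)
    if var_order is None:
        var_order = tuple(f"v{i}" for i in range(p))
    return GroupData(
        group=group,
        n_pairs=n_pairs,
        values=X,
        sample_cov=S,
        var_order=tuple(var_order),
        seed=seed,
    )


def add_measurement_error(target: TwinCovariance, spec: ErrorSpec) -> TwinCovariance:
    """Degrade the phenotypes of both twins to the reliabilities in ``spec``.

    Independent error with variance ``Var(X) * (1 - rho) / rho`` is added to
    each phenotype of each twin, so that the reliability — the share of
    observed variance due to true score — equals ``rho``.  Because the error
    is independent of everything else, only the phenotype diagonal entries
    of the pair covariance change; every covariance (within-twin,
    cross-twin, score-phenotype) is untouched.  Injecting at the covariance
    level is equivalent, under exact simulation, to adding noise records.
    """
    spec.validate()
    rho = {"X": spec.rhoX, "Y": spec.rhoY}
    out = {}
    for grp in ("MZ", "DZ"):
        sigma = target.group(grp).copy()
        for i, v in enumerate(target.order(grp)):
            base = v.split("_")[0]
            if base in rho:
                sigma[i, i] += sigma[i, i] * (1.0 - rho[base]) / rho[base]
        out[grp] = sigma
    return TwinCovariance(
        sigma_mz=out["MZ"],
        sigma_dz=out["DZ"],
        var_order_mz=target.var_order_mz,
        var_order_dz=target.var_order_dz,
    )
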