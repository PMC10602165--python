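"""Shared fixtures and the structural Monte-Carlo oracle.

The oracle simulates twin pairs *structurally*: it draws A, C, E factor
scores and polygenic scores with the appropriate cross-twin sharing, then
solves the two simultaneous phenotype equations per twin.  It never touches
the analytic covariance assembly it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrdoc.models import ModelKind, ModelParams, var_order_for


def _chol(m: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(m + 1e-15 * np.eye(m.shape[0]))


def _draw_factor_pair(rng, n, cov2, alpha):
    """Twin-pair draws of a cross-trait correlated factor.

    ``cov2`` is the within-twin 2x2 covariance of the (trait-1, trait-2)
    factor scores; ``alpha`` the cross-twin correlation of each score
    (1 shared, 0.5 half-shared via a common+specific split, 0 independent).
    Returns (n x 2, n x 2) for twins 1 and 2.
    """
    L = _chol(cov2)
    if alpha == 1.0:
        shared = rng.standard_normal((n, 2)) @ L.T
        return shared, shared.copy()
    if alpha == 0.0:
        return rng.standard_normal((n, 2)) @ L.T, rng.standard_normal((n, 2)) @ L.T
    Lc = _chol(alpha * cov2)
    Ls = _chol((1.0 - alpha) * cov2)
    common = rng.standard_normal((n, 2)) @ Lc.T
    return (
        common + rng.standard_normal((n, 2)) @ Ls.T,
        common + rng.standard_normal((n, 2)) @ Ls.T,
    )


def structural_oracle(kind, params: ModelParams, group: str, n: int, seed: int) -> np.ndarray:
    """Simulate ``n`` twin pairs record by record; returns an array ordered
    per ``var_order_for(kind, group)``."""
    kind = ModelKind(kind)
    rng = np.random.default_rng(seed)
    alpha = 1.0 if group.upper() == "MZ" else 0.5

    def cov2(v1, v2, r):
        c = r * np.sqrt(v1 * v2)
        return np.array([[v1, c], [c, v2]])

    A1, A2 = _draw_factor_pair(rng, n, cov2(params.VA1, params.VA2, params.ra), alpha)
    C1, C2 = _draw_factor_pair(rng, n, cov2(params.VC1, params.VC2, params.rc), 1.0)
    E1, E2 = _draw_factor_pair(rng, n, cov2(params.VE1, params.VE2, params.re), 0.0)
    PS1, PS2 = _draw_factor_pair(rng, n, cov2(params.vP1, params.vP2, params.rf), alpha)

    ImB = np.array([[1.0, -params.g2], [-params.g1, 1.0]])
    Gamma = np.array([[params.b1, 0.0], [params.b2, params.b3]])

    cols = {}
    for t, (A, C, E, PS) in enumerate(((A1, C1, E1, PS1), (A2, C2, E2, PS2)), start=1):
        phen = np.linalg.solve(ImB, (Gamma @ PS.T) + (A + C + E).T).T
        cols[f"X_t{t}"], cols[f"Y_t{t}"] = phen[:, 0], phen[:, 1]
        cols[f"PS1_t{t}"], cols[f"PS2_t{t}"] = PS[:, 0], PS[:, 1]
    # MZ pairs share scores exactly; the shared-score columns drop the twin tag
    cols["PS1"], cols["PS2"] = cols["PS1_t1"], cols["PS2_t1"]
    order = var_order_for(kind, group)
    return np.column_stack([cols[v] for v in order])


def mc_covariance_check(sigma: np.ndarray, draws: np.ndarray, n_se: float = 3.0):
    """Assert every element of ``sigma`` lies within ``n_se`` Monte-Carlo
    standard errors of the empirical covariance of ``draws``."""
    n = draws.shape[0]
    S = np.cov(draws, rowvar=False)
    d = np.diag(S)
    se = np.sqrt((np.outer(d, d) + S**2) / n)
    worst = np.abs(S - sigma) / se
    assert worst.max() < n_se, f"max deviation {worst.max():.2f} MC SEs at {np.unravel_index(worst.argmax(), worst.shape)}"


@pytest.fixture(scope="session")
def design3_cell() -> ModelParams:
    """The representative MR-DoC2 generating cell used across oracle tests."""
    return ModelParams(b1=0.05, b3=0.05, g1=0.04, g2=0.04, ra=0.2, rc=0.2, re=0.2, rf=0.2)
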