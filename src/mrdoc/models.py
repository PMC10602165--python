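"""Model-implied twin-pair covariance matrices for DoC, MR-DoC and MR-DoC2.

The three models are bivariate twin ACE structural equation models for an
exposure phenotype X and an outcome phenotype Y, optionally augmented with
polygenic scores acting as instrumental variables:

* **DoC** (Direction of Causation): X and Y per twin, causal path ``g1``
  (X -> Y), identified through the contrast of MZ and DZ cross-twin
  cross-trait covariances.  Fit here in its unidirectional form
  (``g2 = 0``) with the unshared-environment correlation ``re`` fixed to 0.
* **MR-DoC**: adds a polygenic score PS1 instrumenting X (path ``b1``)
  and a directional horizontal-pleiotropy path ``b2`` (PS1 -> Y);
  unidirectional, ``re`` fixed to 0.
* **MR-DoC2**: adds a second polygenic score PS2 instrumenting Y (path
  ``b3``), frees the reverse causal path ``g2`` and the E correlation
  ``re``, allows the two scores to correlate (``rf``), and fixes ``b2 = 0``.

Residual (non-instrumented) variance of each phenotype is decomposed into
additive-genetic (A), shared-environment (C) and unshared-environment (E)
components.  Across twins, A correlates 1 (MZ) / 0.5 (DZ), C correlates 1,
E correlates 0.  Polygenic scores are additive-genetic: monozygotic twins
carry *identical* scores, so the MZ group observes each score once (its
8-variable pair covariance would be exactly singular otherwise), while the
DZ group observes one score per twin with cross-twin correlation 0.5.

The reduced form used throughout: with ``B = [[0, g2], [g1, 0]]`` the
matrix of simultaneous causal paths among the phenotypes (rows/cols X, Y),
``Lam = (I - B)^-1``, and ``Gamma = [[b1, 0], [b2, b3]]`` the instrument
loadings, the phenotype vector of one twin is
``(X, Y)' = Lam @ (Gamma @ (PS1, PS2)' + u)`` where ``u`` collects the
A/C/E residuals.  All blocks of the pair covariance follow from this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "ModelKind",
    "ModelParams",
    "TwinCovariance",
    "implied_sigma",
    "submodel_sigma",
    "var_order_for",
]


class ModelKind(str, Enum):
    """The three twin causal models, by their observed-variable sets."""

    DOC = "doc"          # X, Y per twin
    MRDOC = "mrdoc"      # + PS1
    MRDOC2 = "mrdoc2"    # + PS2

    @property
    def pgs_vars(self) -> tuple[str, ...]:
        if self is ModelKind.DOC:
            return ()
        if self is ModelKind.MRDOC:
            return ("PS1",)
        return ("PS1", "PS2")

    def n_observed(self, group: str) -> int:
        """MZ pairs share identical polygenic scores, so each score appears
        once in the MZ observation vector and once per twin in the DZ one."""
        k = len(self.pgs_vars)
        return 4 + (k if group.upper() == "MZ" else 2 * k)


def var_order_for(kind: ModelKind, group: str = "DZ") -> tuple[str, ...]:
    """Observed-variable ordering for one zygosity group.

    DZ: ``(PS1_t1, PS2_t1, X_t1, Y_t1, PS1_t2, PS2_t2, X_t2, Y_t2)`` minus
    absent scores.  MZ: shared scores first (``PS1``, ``PS2``), then the
    twin-1 and twin-2 phenotype blocks.
    """
    kind = ModelKind(kind)
    group = group.upper()
    if group == "MZ":
        return kind.pgs_vars + ("X_t1", "Y_t1", "X_t2", "Y_t2")
    if group == "DZ":
        per_twin = [f"{v}_t{{t}}" for v in kind.pgs_vars] + ["X_t{t}", "Y_t{t}"]
        return tuple(s.format(t=t) for t in (1, 2) for s in per_twin)
    raise KeyError(f"unknown zygosity group {group!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector shared by the three models.

    Causal and instrument paths are unitless regression weights; variance
    components are on the scale of the (unit-variance) phenotype residuals;
    ``ra``/``rc``/``re`` are the cross-trait correlations of the A, C and E
    factors and ``rf`` the PS1-PS2 correlation.  ``rhoX``/``rhoY`` are
    phenotype reliabilities consumed only by measurement-error injection.
    """

    g1: float = 0.0   # causal path X -> Y
    g2: float = 0.0   # causal path Y -> X (free only in MR-DoC2)
    b1: float = 0.0   # instrument path PS1 -> X
    b2: float = 0.0   # directional horizontal pleiotropy PS1 -> Y (MR-DoC only)
    b3: float = 0.0   # instrument path PS2 -> Y (MR-DoC2 only)
    VA1: float = 0.10
    VC1: float = 0.10
    VE1: float = 0.80
    VA2: float = 0.10
    VC2: float = 0.10
    VE2: float = 0.80
    ra: float = 0.0
    rc: float = 0.0
    re: float = 0.0
    rf: float = 0.0
    vP1: float = 1.0
    vP2: float = 1.0
    rhoX: float = 1.0
    rhoY: float = 1.0

    def validate(self) -> None:
        for name in ("VA1", "VC1", "VE1", "VA2", "VC2", "VE2", "vP1", "vP2"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be >= 0")
        for name in ("ra", "rc", "re", "rf"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"correlation {name} must lie in [-1, 1]")
        for name in ("rhoX", "rhoY"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"reliability {name} must lie in (0, 1]")

    def check_mask(self, kind: ModelKind) -> None:
        """Raise if a path that ``kind`` fixes to zero is nonzero."""
        fixed_zero = {
            ModelKind.DOC: ("b1", "b2", "b3", "rf", "re", "g2"),
            ModelKind.MRDOC: ("b3", "rf", "re", "g2"),
            ModelKind.MRDOC2: ("b2",),
        }[kind]
        for name in fixed_zero:
            if getattr(self, name) != 0.0:
                raise ValueError(f"{kind.value} fixes {name} = 0, got {getattr(self, name)!r}")

    def with_(self, **updates: float) -> "ModelParams":
        return replace(self, **updates)


@dataclass(frozen=True)
class TwinCovariance:
    """Model-implied (or marginalized) covariance matrices of the MZ and DZ
    twin-pair observation vectors, with explicit per-group variable orders
    (the MZ group carries each polygenic score once)."""

    sigma_mz: np.ndarray
    sigma_dz: np.ndarray
    var_order_mz: tuple[str, ...]
    var_order_dz: tuple[str, ...]

    def __post_init__(self) -> None:
        for sig, order in ((self.sigma_mz, self.var_order_mz), (self.sigma_dz, self.var_order_dz)):
            if sig.shape != (len(order), len(order)):
                raise ValueError("covariance shape does not match its variable order")

    def group(self, name: str) -> np.ndarray:
        return {"MZ": self.sigma_mz, "DZ": self.sigma_dz}[name.upper()]

    def order(self, name: str) -> tuple[str, ...]:
        return {"MZ": self.var_order_mz, "DZ": self.var_order_dz}[name.upper()]

    def to_dataframes(self):
        """Return (mz, dz) as labelled pandas DataFrames."""
        import pandas as pd

        return tuple(
            pd.DataFrame(self.group(g), index=list(self.order(g)), columns=list(self.order(g)))
            for g in ("MZ", "DZ")
        )

    def save_csv(self, path_mz, path_dz) -> None:
        mz, dz = self.to_dataframes()
        mz.to_csv(path_mz)
        dz.to_csv(path_dz)


def _cross_covariances(params: ModelParams, style: str) -> tuple[float, float, float, float]:
    """Cross-trait A/C/E covariances and the PGS covariance.

    ``style='path'`` reads ra/rc/re/rf as correlations and converts;
    ``style='varcomp'`` reads the same fields as raw covariances (the
    variance-component parameterization used during fitting).
    """
    if style == "path":
        ca = params.ra * math.sqrt(params.VA1 * params.VA2)
        cc = params.rc * math.sqrt(params.VC1 * params.VC2)
        ce = params.re * math.sqrt(params.VE1 * params.VE2)
        cf = params.rf * math.sqrt(params.vP1 * params.vP2)
    elif style == "varcomp":
        ca, cc, ce, cf = params.ra, params.rc, params.re, params.rf
    else:
        raise ValueError(f"unknown parameterization style {style!r}")
    return ca, cc, ce, cf


def implied_sigma(
    kind: ModelKind,
    params: ModelParams,
    style: str = "path",
    *,
    check_mask: bool = True,
    label: str = "",
) -> TwinCovariance:
    """Assemble the model-implied MZ and DZ pair covariance matrices.

    Parameters
    ----------
    kind
        Which model's observed-variable sets (and fixing mask) to use.
    params
        Full parameter vector; entries the model fixes to zero must be zero
        unless ``check_mask=False`` (mis-specification studies generate data
        that violate a fitted model's mask on purpose).
    style
        ``'path'`` (ra/rc/re/rf are correlations) or ``'varcomp'`` (those
        fields hold the A/C/E cross-covariances and PGS covariance directly).
    label
        Optional tag naming the design cell in error messages.
    """
    kind = ModelKind(kind)
    if style == "path":
        params.validate()
    if check_mask:
        params.check_mask(kind)

    det = 1.0 - params.g1 * params.g2
    if abs(det) < 1e-12:
        raise ValueError("causal loop unit root: (1 - g1*g2) = 0")

    ca, cc, ce, cf = _cross_covariances(params, style)

    B = np.array([[0.0, params.g2], [params.g1, 0.0]])
    Lam = np.linalg.inv(np.eye(2) - B)
    Gamma = np.array([[params.b1, 0.0], [params.b2, params.b3]])

    # within-twin residual (A+C+E) covariance of (X, Y)
    R_w = np.array(
        [
            [params.VA1 + params.VC1 + params.VE1, ca + cc + ce],
            [ca + cc + ce, params.VA2 + params.VC2 + params.VE2],
        ]
    )
    P_w = np.array([[params.vP1, cf], [cf, params.vP2]])
    n_pgs = len(kind.pgs_vars)
    pgs_idx = list(range(n_pgs))

    def residual_cross(alpha: float) -> np.ndarray:
        return np.array(
            [
                [alpha * params.VA1 + params.VC1, alpha * ca + cc],
                [alpha * ca + cc, alpha * params.VA2 + params.VC2],
            ]
        )

    # DZ group: one score per twin, cross-twin PGS covariance 0.5 * P_w
    alpha_dz = 0.5
    P_x = alpha_dz * P_w
    phen_w = Lam @ (Gamma @ P_w @ Gamma.T + R_w) @ Lam.T
    phen_x_dz = Lam @ (Gamma @ P_x @ Gamma.T + residual_cross(alpha_dz)) @ Lam.T
    ps_phen_w = (P_w @ Gamma.T @ Lam.T)[np.ix_(pgs_idx, [0, 1])]
    ps_phen_x = (P_x @ Gamma.T @ Lam.T)[np.ix_(pgs_idx, [0, 1])]
    Pw_sub = P_w[np.ix_(pgs_idx, pgs_idx)]
    Px_sub = P_x[np.ix_(pgs_idx, pgs_idx)]
    within = np.block([[Pw_sub, ps_phen_w], [ps_phen_w.T, phen_w]])
    cross = np.block([[Px_sub, ps_phen_x], [ps_phen_x.T, phen_x_dz]])
    sigma_dz = np.block([[within, cross], [cross.T, within]])

    # MZ group: twins carry identical scores -> each score enters once and
    # loads on both twins' phenotypes; cross-twin residual structure at alpha=1
    phen_x_mz = Lam @ (Gamma @ P_w @ Gamma.T + residual_cross(1.0)) @ Lam.T
    ps_phen = (P_w @ Gamma.T @ Lam.T)[np.ix_(pgs_idx, [0, 1])]
    sigma_mz = np.block(
        [
            [Pw_sub, ps_phen, ps_phen],
            [ps_phen.T, phen_w, phen_x_mz],
            [ps_phen.T, phen_x_mz.T, phen_w],
        ]
    )

    out = TwinCovariance(
        sigma_mz=0.5 * (sigma_mz + sigma_mz.T),
        sigma_dz=0.5 * (sigma_dz + sigma_dz.T),
        var_order_mz=var_order_for(kind, "MZ"),
        var_order_dz=var_order_for(kind, "DZ"),
    )
    for group in ("MZ", "DZ"):
        eigmin = np.linalg.eigvalsh(out.group(group)).min()
        if eigmin <= 0:
            where = f" in design cell {label}" if label else ""
            raise ValueError(
                f"implied {group} covariance for {kind.value} is not positive "
                f"definite{where} (min eigenvalue {eigmin:.3e})"
            )
    return out


def submodel_sigma(full: TwinCovariance, kind: ModelKind) -> TwinCovariance:
    """Marginal covariance over the variables ``kind`` observes.

    Fitting a smaller model to data generated under MR-DoC2 amounts to
    fitting it to this multivariate-normal marginal (drop PS2 for MR-DoC,
    both scores for DoC)."""
    kind = ModelKind(kind)
    for g in ("MZ", "DZ"):
        if tuple(full.order(g)) != var_order_for(ModelKind.MRDOC2, g):
            raise ValueError(
                f"expected the full mrdoc2 {g} ordering {var_order_for(ModelKind.MRDOC2, g)}, "
                f"got {tuple(full.order(g))}"
            )
    sel = {}
    for g in ("MZ", "DZ"):
        want = var_order_for(kind, g)
        idx = [full.order(g).index(v) for v in want]
        sel[g] = full.group(g)[np.ix_(idx, idx)]
    return TwinCovariance(
        sigma_mz=sel["MZ"],
        sigma_dz=sel["DZ"],
        var_order_mz=var_order_for(kind, "MZ"),
        var_order_dz=var_order_for(kind, "DZ"),
    )
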