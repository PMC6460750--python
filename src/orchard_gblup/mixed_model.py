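"""REML variance components and BLUP/GBLUP breeding values.

One linear mixed model serves both pipelines:

    y = X b + Z1 u + Z2 r + Z3 r(s) + e

with u ~ N(0, sigma2_a K) for an arbitrary relationship kernel K (pedigree A
or genomic G — swapping K is the *only* difference between BLUP and GBLUP),
r ~ N(0, sigma2_r I) replicate effects, r(s) ~ N(0, sigma2_rs I) set nested
within replicate, e ~ N(0, sigma2_e I).

Variance components are estimated by average-information REML with
expectation-maximisation fallback steps whenever an AI update would leave the
parameter space or reduce the restricted likelihood.  Breeding values come
from the mixed-model equations at the plugged-in components; prediction error
variances are the diagonal of the corresponding block of the inverse
coefficient matrix, and theoretical accuracy is
``r = sqrt(1 - PEV / (K_ii * sigma2_a))``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .pedigree import RelationshipMatrix

__all__ = [
    "TrialData",
    "DesignMatrices",
    "VarianceComponents",
    "BreedingValueSet",
    "build_design",
    "reml_fit",
    "solve_blup",
    "heritability",
    "theoretical_accuracy",
    "fit_model",
]

log = logging.getLogger(__name__)

COMPONENT_NAMES = ("sigma2_a", "sigma2_r", "sigma2_rs", "sigma2_e")


@dataclass
class TrialData:
    """Phenotype records with the trial design factors.

    ``frame`` columns: ``id``, ``seed_source``, ``replicate``, ``set``,
    ``orchard`` plus one column per trait.  One trait is analysed per fit.
    """

    frame: pd.DataFrame
    trait_columns: list[str]

    REQUIRED = ("id", "seed_source", "replicate", "set", "orchard")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.frame.columns:
                raise ValueError(f"phenotype table missing column {c!r}")
        for t in self.trait_columns:
            if t not in self.frame.columns:
                raise ValueError(f"trait column {t!r} not in phenotype table")
        self.frame = self.frame.copy()
        self.frame["id"] = self.frame["id"].astype(str)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    def subset(self, mask) -> "TrialData":
        return TrialData(self.frame.loc[mask].reset_index(drop=True), self.trait_columns)

    def subset_orchards(self, orchards: Sequence[str]) -> "TrialData":
        return self.subset(self.frame["orchard"].isin(list(orchards)))


@dataclass
class DesignMatrices:
    """Incidence structures of the trial model for one trait."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    Z1: np.ndarray  # records x kernel individuals
    Z2: np.ndarray  # records x replicates
    Z3: np.ndarray  # records x sets-within-replicates
    kernel_ids: list[str]
    record_ids: list[str]


def _dummy(values: pd.Series, drop_first: bool) -> tuple[np.ndarray, list[str]]:
    levels = [l for l in pd.unique(values) ]
    counts = values.value_counts()
    levels = [l for l in levels if counts.get(l, 0) > 0]
    if drop_first:
        used = levels[1:]
    else:
        used = levels
    Z = np.zeros((len(values), len(used)))
    for k, lev in enumerate(used):
        Z[values.to_numpy() == lev, k] = 1.0
    return Z, [str(l) for l in used]


def build_design(
    data: TrialData, K: RelationshipMatrix, trait: str
) -> DesignMatrices:
    """Build y, X and the three random-effect incidence matrices.

    Fixed part: intercept + seed-source contrasts (reference-level coding for
    full column rank).  ``Z1`` maps records to every individual carried by the
    kernel (individuals without records get zero rows — they are still
    predicted).  Records whose id is absent from the kernel are a hard error.
    Rows with a missing trait value are dropped with a logged warning.
    """
    df = data.frame
    ok = ~df[trait].isna()
    if (~ok).any():
        log.warning("dropping %d records with missing %s", int((~ok).sum()), trait)
        df = df.loc[ok]
    if len(df) == 0:
        raise ValueError(f"no records with observed trait {trait!r}")

    kernel_pos = {i: k for k, i in enumerate(K.labels)}
    missing = sorted(set(df["id"]) - set(kernel_pos))
    if missing:
        raise KeyError(
            f"records refer to individuals absent from the kernel: {missing[:10]}"
        )

    y = df[trait].to_numpy(dtype=float)
    n = len(df)

    Xs, ss_names = _dummy(df["seed_source"].astype(str), drop_first=True)
    X = np.column_stack([np.ones(n), Xs]) if Xs.shape[1] else np.ones((n, 1))
    fixed_names = ["intercept"] + [f"seed_source[{s}]" for s in ss_names]

    Z1 = np.zeros((n, len(K.labels)))
    for r, ind in enumerate(df["id"]):
        Z1[r, kernel_pos[ind]] = 1.0

    Z2, _ = _dummy(df["replicate"].astype(str), drop_first=False)
    rs = df["replicate"].astype(str) + ":" + df["set"].astype(str)
    Z3, _ = _dummy(rs, drop_first=False)

    return DesignMatrices(
        y=y,
        X=X,
        fixed_names=fixed_names,
        Z1=Z1,
        Z2=Z2,
        Z3=Z3,
        kernel_ids=list(K.labels),
        record_ids=df["id"].tolist(),
    )


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_r: float
    sigma2_rs: float
    sigma2_e: float
    log_likelihood: float
    converged: bool
    n_iterations: int = 0
    boundary: dict[str, bool] = field(default_factory=dict)
    covariance: np.ndarray | None = None  # asymptotic cov of the 4 components

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_a, self.sigma2_r, self.sigma2_rs, self.sigma2_e])

    def standard_errors(self) -> dict[str, float]:
        if self.covariance is None:
            return {k: float("nan") for k in COMPONENT_NAMES}
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return dict(zip(COMPONENT_NAMES, se.tolist()))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in COMPONENT_NAMES}
        d.update(
            log_likelihood=self.log_likelihood,
            converged=self.converged,
            n_iterations=self.n_iterations,
            standard_errors=self.standard_errors(),
        )
        return d


@dataclass
class BreedingValueSet:
    ids: list[str]
    ebv: np.ndarray
    pev: np.ndarray
    accuracy: np.ndarray
    kernel_kind: str
    fixed_effects: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "ebv": self.ebv, "pev": self.pev, "accuracy": self.accuracy}
        )

    def series(self) -> pd.Series:
        return pd.Series(self.ebv, index=self.ids)


def bend_kernel(K: np.ndarray, min_eig: float = 1e-8, bump: float = 1e-6) -> np.ndarray:
    """Add ``bump`` to the diagonal when the smallest eigenvalue is < min_eig."""
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    if w.min() < min_eig:
        log.info("bending kernel: min eigenvalue %.3g < %.3g", w.min(), min_eig)
        K = K + bump * np.eye(K.shape[0])
    return K


class _REMLWork:
    """Per-iteration quantities of the restricted likelihood.

    All formulas use V^-1 explicitly; the projection matrix P is applied
    implicitly through (V^-1, V^-1 X, (X'V^-1X)^-1) so that per-iteration cost
    is one n x n inversion plus O(n^2) products.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Vs: list[np.ndarray]):
        self.y = y
        self.X = X
        self.Vs = Vs  # covariance contributions per component (incl. residual I)
        self.n, self.p = X.shape

    def evaluate(self, sig: np.ndarray):
        V = sum(s * Vi for s, Vi in zip(sig, self.Vs))
        try:
            c, low = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        Vinv = sla.cho_solve((c, low), np.eye(self.n))
        ViX = Vinv @ self.X
        XtViX = self.X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        XtViX_inv = np.linalg.inv(XtViX)
        beta = XtViX_inv @ (ViX.T @ self.y)
        Py = Vinv @ self.y - ViX @ beta
        yPy = float(self.y @ Py)
        ll = -0.5 * (
            logdetV + logdetX + yPy + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return {
            "ll": ll,
            "Vinv": Vinv,
            "ViX": ViX,
            "XtViX_inv": XtViX_inv,
            "beta": beta,
            "Py": Py,
        }

    def apply_P(self, state, w: np.ndarray) -> np.ndarray:
        return state["Vinv"] @ w - state["ViX"] @ (
            state["XtViX_inv"] @ (state["ViX"].T @ w)
        )

    def score_and_ai(self, state):
        """REML score vector and average-information matrix."""
        k = len(self.Vs)
        Py = state["Py"]
        Vinv, ViX, XtViX_inv = state["Vinv"], state["ViX"], state["XtViX_inv"]
        score = np.zeros(k)
        w = [Vi @ Py for Vi in self.Vs]
        Pw = [self.apply_P(state, wi) for wi in w]
        trPV = np.zeros(k)
        yPVPy = np.zeros(k)
        for i, Vi in enumerate(self.Vs):
            tr1 = float((Vinv * Vi).sum())  # tr(V^-1 Vi), both symmetric
            Mi = ViX.T @ (Vi @ ViX)
            tr2 = float(np.trace(XtViX_inv @ Mi))
            trPV[i] = tr1 - tr2
            yPVPy[i] = float(Py @ w[i])
            score[i] = -0.5 * (trPV[i] - yPVPy[i])
        AI = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ Pw[j])
        return score, AI, trPV, yPVPy


def reml_fit(
    design: DesignMatrices,
    K: RelationshipMatrix,
    max_iter: int = 200,
    tol_ll: float = 1e-6,
    tol_par: float = 1e-6,
    verbose: bool = False,
) -> VarianceComponents:
    """AI-REML with EM fallback for the four-component trial model.

    Components are constrained non-negative; a component pinned at the lower
    boundary (< 1e-8 of the phenotypic variance) is reported as 0 with a
    boundary flag.  Non-convergence returns ``converged=False`` with the
    components at the last iterate (reports then display the NA convention).
    """
    y, X = design.y, design.X
    n = len(y)
    Kv = bend_kernel(K.values)
    Vs = [
        design.Z1 @ Kv @ design.Z1.T,
        design.Z2 @ design.Z2.T,
        design.Z3 @ design.Z3.T,
        np.eye(n),
    ]
    q = np.array([design.Z1.shape[1], design.Z2.shape[1], design.Z3.shape[1], n], float)
    work = _REMLWork(y, X, Vs)

    varp = float(np.var(y, ddof=1)) if n > 1 else 1.0
    varp = max(varp, 1e-12)
    floor = 1e-8 * varp
    sig = np.array([0.25 * varp, 0.1 * varp, 0.1 * varp, 0.55 * varp])

    state = work.evaluate(sig)
    if state is None:
        raise np.linalg.LinAlgError("initial covariance matrix not positive definite")

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, AI, trPV, yPVPy = work.score_and_ai(state)
        ll_old, sig_old = state["ll"], sig.copy()

        # active-set AI step: components pinned at the boundary with a
        # negative score stay put; the AI system is solved over the rest
        pinned = (sig <= floor * (1 + 1e-9)) & (score < 0)
        active = np.flatnonzero(~pinned)
        step_ok = False
        if len(active):
            try:
                delta_a = np.linalg.solve(
                    AI[np.ix_(active, active)] + 1e-10 * np.eye(len(active)),
                    score[active],
                )
            except np.linalg.LinAlgError:
                delta_a = None
            if delta_a is not None:
                delta = np.zeros_like(sig)
                delta[active] = delta_a
                frac = 1.0
                for _ in range(5):  # step halving toward the current point
                    cand = np.maximum(sig + frac * delta, floor)
                    cs = work.evaluate(cand)
                    if cs is not None and cs["ll"] >= ll_old - 1e-10:
                        sig, state, step_ok = cand, cs, True
                        break
                    frac *= 0.5

        if not step_ok:
            # EM update: guaranteed ascent, slow but safe
            cand = sig + (sig**2) * (yPVPy - trPV) / q
            cand = np.maximum(cand, floor)
            cs = work.evaluate(cand)
            if cs is None:
                break
            sig, state = cand, cs

        if verbose:
            log.info("REML iter %d  logRL=%.6f  sig=%s", it, state["ll"], sig)
        d_ll = abs(state["ll"] - ll_old)
        rel = np.max(np.abs(sig - sig_old) / np.maximum(sig_old, floor))
        if d_ll < tol_ll and rel < tol_par:
            converged = True
            break

    # final AI matrix for asymptotic covariance of the components
    _, AI, _, _ = work.score_and_ai(state)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = None

    boundary = {}
    out = []
    for name, v in zip(COMPONENT_NAMES, sig):
        pinned = v <= floor * (1 + 1e-9)
        boundary[name] = bool(pinned)
        out.append(0.0 if pinned else float(v))

    vc = VarianceComponents(
        sigma2_a=out[0],
        sigma2_r=out[1],
        sigma2_rs=out[2],
        sigma2_e=out[3],
        log_likelihood=float(state["ll"]),
        converged=converged,
        n_iterations=it,
        boundary=boundary,
        covariance=cov,
    )
    log.info(
        "REML %s in %d iterations, logRL=%.4f, components=%s",
        "converged" if converged else "did NOT converge",
        it,
        vc.log_likelihood,
        np.round(vc.as_array(), 6).tolist(),
    )
    return vc


def solve_blup(
    design: DesignMatrices, K: RelationshipMatrix, vc: VarianceComponents
) -> tuple[BreedingValueSet, pd.Series]:
    """Mixed-model-equation solutions at plugged-in variance components.

    Builds Henderson's coefficient matrix over [fixed | u | r | r(s)], solves
    for all effects, and reads PEV off the u-block diagonal of its inverse.
    Individuals carried by the kernel without records are predicted through
    their kernel relationships.  A zero genetic variance is handled by the
    ridge limit (tiny sigma2_a), where all breeding values shrink to 0.
    """
    if vc.sigma2_e <= 0:
        raise ValueError("solve_blup requires positive residual variance")
    s2a = max(vc.sigma2_a, 1e-12)
    s2r = max(vc.sigma2_r, 1e-12)
    s2rs = max(vc.sigma2_rs, 1e-12)
    s2e = vc.sigma2_e

    Kv = bend_kernel(K.values)
    try:
        Kinv = np.linalg.inv(Kv)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular kernel in MME; consider bending (diagonal inflation)"
        ) from err

    X, Z1, Z2, Z3, y = design.X, design.Z1, design.Z2, design.Z3, design.y
    W = np.hstack([X, Z1, Z2, Z3])
    p = X.shape[1]
    q1, q2, q3 = Z1.shape[1], Z2.shape[1], Z3.shape[1]
    C = W.T @ W / s2e
    i0 = p
    C[i0 : i0 + q1, i0 : i0 + q1] += Kinv / s2a
    i0 += q1
    C[i0 : i0 + q2, i0 : i0 + q2] += np.eye(q2) / s2r
    i0 += q2
    C[i0 : i0 + q3, i0 : i0 + q3] += np.eye(q3) / s2rs
    rhs = W.T @ y / s2e
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular MME coefficient matrix; kernel bending may be required"
        ) from err
    sol = Cinv @ rhs

    beta = sol[:p]
    u = sol[p : p + q1]
    pev = np.diag(Cinv)[p : p + q1].copy()
    pev = _clamp_pev(pev)
    kii = np.diag(Kv)
    acc = theoretical_accuracy(pev, kii, s2a)

    fixed = dict(zip(design.fixed_names, beta.tolist()))
    bvs = BreedingValueSet(
        ids=list(design.kernel_ids),
        ebv=u,
        pev=pev,
        accuracy=acc,
        kernel_kind=K.kind,
        fixed_effects=fixed,
    )
    return bvs, pd.Series(beta, index=design.fixed_names)


def _clamp_pev(pev: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    if (pev < -tol).any():
        raise ValueError(f"negative PEV beyond tolerance: min={pev.min()}")
    return np.clip(pev, 0.0, None)


def heritability(vc: VarianceComponents, full_denominator: bool = False) -> tuple[float, float]:
    """Narrow-sense heritability ``h2 = sigma2_a / (sigma2_a + sigma2_e)``.

    Replicate and set variances are excluded from the default denominator; the
    optional full-phenotypic-variance form includes them (non-default).  The
    standard error comes from a first-order delta method on the asymptotic
    component covariance.
    """
    a, e = vc.sigma2_a, vc.sigma2_e
    extra = (vc.sigma2_r + vc.sigma2_rs) if full_denominator else 0.0
    den = a + e + extra
    if den <= 0:
        raise ZeroDivisionError("heritability undefined: zero total variance")
    h2 = a / den
    se = float("nan")
    if vc.covariance is not None:
        # gradient wrt (sigma2_a, sigma2_r, sigma2_rs, sigma2_e)
        g = np.zeros(4)
        g[0] = (den - a) / den**2
        g[3] = -a / den**2
        if full_denominator:
            g[1] = g[2] = -a / den**2
        se = float(np.sqrt(max(g @ vc.covariance @ g, 0.0)))
    return float(h2), se


def theoretical_accuracy(
    pev: np.ndarray | float, k_ii: np.ndarray | float, sigma2_a: float, tol: float = 1e-8
) -> np.ndarray:
    """Breeding-value accuracy ``r = sqrt(1 - PEV / (K_ii sigma2_a))``.

    PEV must lie in [0, K_ii sigma2_a]; tiny negative overshoot is clamped to
    0 and tiny ratio overshoot to 1, larger violations raise (they signal an
    inconsistent PEV/model pair rather than numerical noise).
    """
    pev = np.asarray(pev, dtype=float)
    k_ii = np.asarray(k_ii, dtype=float)
    denom = k_ii * sigma2_a
    if np.any(denom <= 0):
        raise ValueError("accuracy undefined: K_ii * sigma2_a must be positive")
    ratio = pev / denom
    if np.any(ratio < -tol) or np.any(ratio > 1.0 + max(tol, 1e-6)):
        raise ValueError(
            f"PEV outside [0, K_ii*sigma2_a]: ratio range "
            f"[{ratio.min():.6g}, {ratio.max():.6g}]"
        )
    ratio = np.clip(ratio, 0.0, 1.0)
    return np.sqrt(1.0 - ratio)


def fit_model(
    data: TrialData,
    K: RelationshipMatrix,
    trait: str,
    reml_kwargs: dict | None = None,
) -> tuple[VarianceComponents, BreedingValueSet]:
    """Convenience wrapper: design -> REML -> MME for one trait and kernel."""
    design = build_design(data, K, trait)
    vc = reml_fit(design, K, **(reml_kwargs or {}))
    bvs, _ = solve_blup(design, K, vc)
    return vc, bvs
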