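"""Marker QC, EM imputation, genomic relationship matrix, LD statistics.

Dosages are coded 0/1/2 (NaN = missing).  The genomic kernel is the
trace-scaled cross-product of centred dosages, ``G = ZZ' / (tr[ZZ'] / n)``
with ``Z = M - P`` and ``P`` twice the per-marker reference-allele frequency,
so the mean diagonal of ``G`` is exactly 1.  LD uses the composite estimate:
squared Pearson correlation of dosage vectors over pairwise-complete
individuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix

__all__ = [
    "GenotypeMatrix",
    "FilterThresholds",
    "FilterReport",
    "LDDecayCurve",
    "EmptyFilterError",
    "filter_markers",
    "impute_em",
    "compute_G",
    "composite_r2",
    "pairwise_r2",
    "ld_decay",
    "spectral_decomposition",
]

log = logging.getLogger(__name__)


class EmptyFilterError(ValueError):
    """All markers were removed by filtering; downstream G is undefined."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with per-marker metadata.

    ``dosages`` is float with NaN for missing; observed values must be in
    {0, 1, 2} on input (imputation may introduce fractional values in [0, 2]).
    ``marker_meta`` is indexed by marker id with columns ``chrom``, ``pos``,
    ``qa`` (genTrain-like score) and ``qb`` (GenCall-like score).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    marker_meta: pd.DataFrame
    imputed: bool = False

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.individual_ids), len(self.marker_ids)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != ({n} individuals, {m} markers)"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if not self.imputed and obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")
        if list(self.marker_meta.index.astype(str)) != self.marker_ids:
            raise ValueError("marker_meta must be indexed by marker id, same order")
        if (self.marker_meta["pos"] < 0).any():
            raise ValueError("marker positions must be non-negative")

    # -- derived per-marker statistics ------------------------------------
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Reference-allele frequency from non-missing entries."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def subset_markers(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.individual_ids,
            [self.marker_ids[k] for k in keep],
            self.dosages[:, keep],
            self.marker_meta.iloc[keep],
            imputed=self.imputed,
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {x: k for k, x in enumerate(self.individual_ids)}
        idx = [pos[str(i)] for i in ids]
        return GenotypeMatrix(
            [str(i) for i in ids],
            self.marker_ids,
            self.dosages[idx, :],
            self.marker_meta,
            imputed=self.imputed,
        )


@dataclass
class FilterThresholds:
    """Five-rule marker QC; score/frequency rules are strict inequalities."""

    quality_a: float = 0.5  # keep qa > quality_a
    quality_b: float = 0.15  # keep qb > quality_b
    maf: float = 0.01  # keep MAF > maf
    call_rate: float = 0.6  # keep call rate > call_rate
    ld_r2: float = 0.9  # prune one of each pair with r2 >= ld_r2
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self) -> None:
        for name in ("quality_a", "quality_b", "maf", "call_rate", "ld_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_pass: int
    removed: dict[str, int]
    thresholds: FilterThresholds

    def to_dict(self) -> dict:
        t = self.thresholds
        return {
            "n_input": self.n_input,
            "n_pass": self.n_pass,
            "removed": dict(self.removed),
            "thresholds": {
                "quality_a": t.quality_a,
                "quality_b": t.quality_b,
                "maf": t.maf,
                "call_rate": t.call_rate,
                "ld_r2": t.ld_r2,
            },
        }


def filter_markers(
    g: GenotypeMatrix, thresholds: FilterThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the five QC rules; LD pruning runs last, on survivors only.

    Per-marker rules (quality scores, MAF, call rate) are order-independent;
    each removed marker is charged to its first failing rule.  LD pruning is
    greedy over a sliding window in genome order, removing the
    later-positioned marker of any pair with composite r2 >= ``ld_r2``.
    """
    t = thresholds or FilterThresholds()
    qa = g.marker_meta["qa"].to_numpy(dtype=float)
    qb = g.marker_meta["qb"].to_numpy(dtype=float)
    maf = g.maf()
    cr = g.call_rate()

    removed = {"quality_a": 0, "quality_b": 0, "maf": 0, "call_rate": 0, "ld": 0}
    keep = np.ones(len(g.marker_ids), dtype=bool)
    for rule, ok in (
        ("quality_a", qa > t.quality_a),
        ("quality_b", qb > t.quality_b),
        ("maf", maf > t.maf),
        ("call_rate", cr > t.call_rate),
    ):
        fails = keep & ~ok
        removed[rule] = int(fails.sum())
        keep &= ok

    surv = np.flatnonzero(keep)
    pruned = _ld_prune(g, surv, t)
    removed["ld"] = len(surv) - len(pruned)

    if len(pruned) == 0:
        raise EmptyFilterError("all markers removed by filtering")

    out = g.subset_markers(pruned)
    report = FilterReport(
        n_input=len(g.marker_ids), n_pass=len(pruned), removed=removed, thresholds=t
    )
    for rule, cnt in removed.items():
        log.info("filter rule %-10s removed %d markers", rule, cnt)
    log.info("filter: %d of %d markers pass", report.n_pass, report.n_input)
    return out, report


def _ld_prune(g: GenotypeMatrix, surv: np.ndarray, t: FilterThresholds) -> np.ndarray:
    """Greedy windowed LD pruning in genome order; keeps the earlier marker."""
    if len(surv) == 0:
        return surv
    meta = g.marker_meta.iloc[surv]
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].astype(str).to_numpy()))
    surv_sorted = surv[order]
    chroms = meta["chrom"].astype(str).to_numpy()[order]
    keep_mask = np.ones(len(surv_sorted), dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + t.ld_window]
            active = [k for k in win if keep_mask[k]]
            if len(active) > 1:
                cols = surv_sorted[active]
                r2 = pairwise_r2(g.dosages[:, cols])
                for a in range(len(active)):
                    if not keep_mask[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if keep_mask[active[b]] and r2[a, b] >= t.ld_r2:
                            keep_mask[active[b]] = False  # drop later-positioned
            if start + t.ld_window >= len(idx):
                break
            start += t.ld_step
    return np.sort(surv_sorted[keep_mask])


# ----------------------------------------------------------------------
# EM imputation
# ----------------------------------------------------------------------

def impute_em(
    g: GenotypeMatrix,
    tol: float = 1e-4,
    max_iter: int = 100,
    ridge: float = 0.05,
) -> GenotypeMatrix:
    """EM imputation of missing dosages via the realized individual covariance.

    Initialise missing entries at column means; iterate (1) estimate the
    individual-by-individual covariance of the completed matrix, (2) replace
    each missing entry by its conditional expectation given the observed
    entries at that marker under a Gaussian model with that covariance.  Stops
    when the largest absolute change of any imputed value drops below ``tol``.
    On non-convergence the column-mean imputation is returned with a logged
    warning (``imputation_converged`` attribute False).

    ``ridge`` shrinks the realized covariance toward the diagonal (relative to
    its mean diagonal); without it the self-estimated covariance feedback can
    oscillate and over-fit the imputed entries.

    Observed entries are never modified; imputed values are clipped to [0, 2].
    """
    missing = np.isnan(g.dosages)
    if not missing.any():
        out = GenotypeMatrix(
            g.individual_ids, g.marker_ids, g.dosages.copy(), g.marker_meta, imputed=True
        )
        out.imputation_converged = True
        out.imputation_iterations = 0
        return out
    if missing.all(axis=0).any():
        j = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(f"marker {g.marker_ids[j]!r} has no observed entries")

    X = g.dosages.copy()
    col_mean = np.nanmean(g.dosages, axis=0)
    mean_filled = np.where(missing, col_mean[None, :], X)
    W = mean_filled.copy()
    n, m = W.shape

    # group markers by missingness pattern so each pattern is solved once
    patterns: dict[bytes, list[int]] = {}
    for j in np.flatnonzero(missing.any(axis=0)):
        patterns.setdefault(missing[:, j].tobytes(), []).append(j)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = W.mean(axis=0)
        C = (W - mu[None, :]) @ (W - mu[None, :]).T / m
        C[np.diag_indices_from(C)] += ridge * max(np.trace(C) / n, 1.0)
        Cinv = np.linalg.inv(C)
        delta = 0.0
        for key, cols in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            obs = ~miss
            Bmm = Cinv[np.ix_(miss, miss)]
            Bmo = Cinv[np.ix_(miss, obs)]
            resid = W[np.ix_(obs, cols)] - mu[None, cols]
            # E[x_m | x_o] = mu - Bmm^-1 Bmo (x_o - mu)
            new = mu[None, cols] - np.linalg.solve(Bmm, Bmo @ resid)
            np.clip(new, 0.0, 2.0, out=new)
            delta = max(delta, float(np.abs(new - W[np.ix_(miss, cols)]).max()))
            W[np.ix_(miss, cols)] = new
        if delta < tol:
            converged = True
            break

    if not converged:
        log.warning(
            "EM imputation did not converge in %d iterations; returning "
            "column-mean imputation",
            max_iter,
        )
        W = mean_filled

    W[~missing] = g.dosages[~missing]
    out = GenotypeMatrix(g.individual_ids, g.marker_ids, W, g.marker_meta, imputed=True)
    out.imputation_converged = converged
    out.imputation_iterations = it
    return out


# ----------------------------------------------------------------------
# Genomic relationship matrix
# ----------------------------------------------------------------------

def compute_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """Trace-scaled genomic relationship matrix from complete dosages.

    ``Z = M - P`` with ``P = 2 p`` the per-marker column mean; the raw
    cross-product ``ZZ'`` is divided by its trace over the number of
    individuals, which forces ``mean(diag(G)) == 1``.
    """
    M = g.dosages
    if np.isnan(M).any():
        raise ValueError("compute_G requires complete dosages; impute first")
    P = M.mean(axis=0)
    var = M.var(axis=0)
    if (var > 0).sum() < 2:
        raise ValueError("need at least 2 polymorphic markers to build G")
    Z = M - P[None, :]
    ZZt = Z @ Z.T
    scale = np.trace(ZZt) / len(g.individual_ids)
    if scale <= 0:
        raise ValueError("degenerate marker matrix: zero trace")
    G = ZZt / scale
    G = (G + G.T) / 2.0
    return RelationshipMatrix(g.individual_ids, G, kind="G")


# ----------------------------------------------------------------------
# Linkage disequilibrium
# ----------------------------------------------------------------------

def composite_r2(g: GenotypeMatrix, marker_i: str, marker_j: str) -> float:
    """Composite LD: squared Pearson correlation of the two dosage columns.

    Computed over pairwise-complete individuals.  Returns NaN (never 0) when
    either column has zero variance among those individuals.
    """
    ii = g.marker_ids.index(str(marker_i))
    jj = g.marker_ids.index(str(marker_j))
    x, y = g.dosages[:, ii], g.dosages[:, jj]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete composite r2 matrix for dosage columns of ``X``.

    Missing entries (NaN) are handled exactly via mask cross-products; zero
    variance pairs yield NaN.
    """
    X = np.asarray(X, dtype=float)
    mask = (~np.isnan(X)).astype(float)
    Xf = np.where(np.isnan(X), 0.0, X)
    n = mask.T @ mask
    sx = Xf.T @ mask
    sy = sx.T
    sxy = Xf.T @ Xf
    sxx = (Xf * Xf).T @ mask
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
        r2[(vx <= 0) | (vy <= 0) | (n < 2)] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


@dataclass
class LDDecayCurve:
    """Mean composite r2 in physical-distance bins (intra-chromosome pairs)."""

    bin_edges: np.ndarray  # length nbins + 1, bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_r2 = np.asarray(self.mean_r2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def decay_distance_at(self, threshold: float) -> float | None:
        """Distance at which mean r2 first drops to ``threshold``.

        Linear interpolation between adjacent bin midpoints; ``None`` when the
        curve never reaches the threshold ("not reached").
        """
        mids = self.midpoints
        ok = self.n_pairs > 0
        mids, means = mids[ok], self.mean_r2[ok]
        if len(means) == 0:
            return None
        for k, m in enumerate(means):
            if m <= threshold:
                if k == 0:
                    return float(mids[0])
                m0, m1 = means[k - 1], m
                d0, d1 = mids[k - 1], mids[k]
                if m0 == m1:
                    return float(d1)
                return float(d0 + (d1 - d0) * (m0 - threshold) / (m0 - m1))
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay(
    g: GenotypeMatrix,
    max_distance_bp: int = 50_000,
    bin_width_bp: int = 500,
    max_pairs_per_chrom: int | None = None,
    rng: np.random.Generator | None = None,
) -> LDDecayCurve:
    """Mean composite r2 per distance bin over intra-chromosome marker pairs."""
    chroms = g.marker_meta["chrom"].astype(str).to_numpy()
    pos = g.marker_meta["pos"].to_numpy(dtype=float)
    edges = np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp, dtype=float)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    found_any = False
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        idx = idx[np.argsort(pos[idx])]
        p = pos[idx]
        ii, jj = [], []
        left = 0
        for right in range(1, len(idx)):
            while p[right] - p[left] > max_distance_bp:
                left += 1
            for k in range(left, right):
                ii.append(k)
                jj.append(right)
        if not ii:
            continue
        found_any = True
        ii = np.asarray(ii)
        jj = np.asarray(jj)
        if max_pairs_per_chrom is not None and len(ii) > max_pairs_per_chrom:
            r = rng or np.random.default_rng(0)
            sel = r.choice(len(ii), size=max_pairs_per_chrom, replace=False)
            ii, jj = ii[sel], jj[sel]
        r2_mat = pairwise_r2(g.dosages[:, idx])
        d = p[jj] - p[ii]
        r2 = r2_mat[ii, jj]
        ok = ~np.isnan(r2)
        d, r2 = d[ok], r2[ok]
        which = np.minimum((d // bin_width_bp).astype(int), nbins - 1)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)

    if not found_any:
        raise ValueError("no intra-chromosome marker pairs within max_distance_bp")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, means, counts)


def spectral_decomposition(
    K: RelationshipMatrix, n_components: int = 10, atol: float = 1e-8
) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigendecomposition of a relationship kernel, descending eigenvalues.

    Returns (scores, eigenvalues) where column ``k`` of ``scores`` is
    eigenvector_k * sqrt(max(eigenvalue_k, 0)).  Eigenvalues sum to tr(K).
    """
    V = K.values
    if not np.allclose(V, V.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    k = min(n_components, len(w))
    scores = U[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))[None, :]
    df = pd.DataFrame(
        scores, index=K.labels, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, w
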