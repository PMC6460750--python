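"""Independent oracle implementations used only by the test suite.

These deliberately share no code with the package: the relationship oracle
enumerates Wright's paths with exact rationals, the mixed-model oracle works
through direct dense inversion of V, and the LD oracle is a discrete-time
forward Wright-Fisher simulation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


# ----------------------------------------------------------------------
# Wright's path-coefficient relationship (exact rational arithmetic)
# ----------------------------------------------------------------------

def path_relationship_matrix(records: list[tuple[str, str, str]]) -> dict:
    """A-matrix entries by explicit path enumeration, as Fractions.

    ``records`` are (id, sire, dam) with '0' = unknown.  Returns a dict keyed
    by frozenset({i, j}) (and single-element frozensets for diagonals).
    """
    parents = {i: tuple(p for p in (s, d) if p != "0") for i, s, d in records}
    ids = [r[0] for r in records]
    for i, s, d in records:
        for p in (s, d):
            if p != "0" and p not in parents:
                parents[p] = ()
                ids.append(p)

    def ancestors(x, seen=None):
        seen = set() if seen is None else seen
        for p in parents.get(x, ()):
            if p not in seen:
                seen.add(p)
                ancestors(p, seen)
        return seen

    def paths_up(x, target, path):
        """All ancestor paths from x to target with no repeated nodes."""
        if x == target:
            yield list(path)
            return
        for p in parents.get(x, ()):
            if p not in path:
                yield from paths_up(p, target, path + [p])

    inbreeding_cache: dict[str, Fraction] = {}

    def F(x) -> Fraction:
        if x in inbreeding_cache:
            return inbreeding_cache[x]
        ps = parents.get(x, ())
        val = Fraction(0)
        if len(ps) == 2:
            val = kinship_numerator(ps[0], ps[1]) / 2
        inbreeding_cache[x] = val
        return val

    def kinship_numerator(i, j) -> Fraction:
        """Numerator relationship a_ij via path counting between distinct i, j."""
        if i == j:
            return Fraction(1) + F(i)
        total = Fraction(0)
        common = (ancestors(i) | {i}) & (ancestors(j) | {j})
        for anc in common:
            for p1 in paths_up(i, anc, [i]):
                nodes1 = set(p1)
                for p2 in paths_up(j, anc, [j]):
                    # paths must share only the common ancestor
                    if (nodes1 & set(p2)) == {anc}:
                        L = (len(p1) - 1) + (len(p2) - 1)
                        total += Fraction(1, 2**L) * (1 + F(anc))
        return total

    out = {}
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            out[frozenset((ids[a], ids[b]))] = kinship_numerator(ids[a], ids[b])
    return out


def enumerate_pedigrees(n: int):
    """Yield every (id, sire, dam) pedigree on individuals 1..n.

    Individual i may take any of {unknown, 1..i-1} for sire and dam
    independently, which covers all acyclic single-generation-order pedigrees.
    """
    import itertools

    choices = [[str(k) for k in range(i)] for i in range(1, n + 1)]  # '0' = unknown
    for combo in itertools.product(*(itertools.product(c, c) for c in choices)):
        yield [(str(i + 1), s, d) for i, (s, d) in enumerate(combo)]


def random_pedigree(n: int, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    recs = []
    for i in range(1, n + 1):
        s = str(rng.integers(0, i))
        d = str(rng.integers(0, i))
        recs.append((str(i), s, d))
    return recs


# ----------------------------------------------------------------------
# Dense direct-inversion mixed-model oracle
# ----------------------------------------------------------------------

def dense_v(sig, Z1, Z2, Z3, K):
    n = Z1.shape[0]
    return (
        sig[0] * Z1 @ K @ Z1.T
        + sig[1] * Z2 @ Z2.T
        + sig[2] * Z3 @ Z3.T
        + sig[3] * np.eye(n)
    )


def restricted_loglik(sig, y, X, Z1, Z2, Z3, K) -> float:
    """REML log-likelihood by direct slogdet/inversion (no Cholesky reuse)."""
    n, p = X.shape
    V = dense_v(sig, Z1, Z2, Z3, K)
    sV, ldV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sX, ldX = np.linalg.slogdet(XtViX)
    if sV <= 0 or sX <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (ldV + ldX + r @ Vi @ y + (n - p) * np.log(2 * np.pi)))


def gls_blup(sig, y, X, Z1, Z2, Z3, K):
    """GLS fixed effects and conditional-expectation breeding values + PEV.

    u_hat = sigma2_a K Z1' V^-1 (y - X beta_hat);
    PEV = sigma2_a K - sigma2_a K Z1' P Z1 K sigma2_a (diagonal), with
    P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.
    """
    V = dense_v(sig, Z1, Z2, Z3, K)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    s2a = sig[0]
    u = s2a * K @ Z1.T @ P @ y
    Cuu = s2a * K - (s2a * K @ Z1.T) @ P @ (Z1 @ K * s2a)
    return beta, u, np.diag(Cuu).copy()


# ----------------------------------------------------------------------
# Forward Wright-Fisher drift-recombination simulator (LD decay oracle)
# ----------------------------------------------------------------------

def forward_wf_haplotypes(
    n_e: int,
    n_markers: int,
    length_bp: float,
    recomb_rate_per_bp: float,
    n_generations: int,
    rng: np.random.Generator,
):
    """Haplotypes after forward drift with recombination on one chromosome.

    2*n_e haplotypes initialised at frequency 0.5 independently per site, then
    n_generations of random union of gametes with Poisson crossovers.
    Returns (haplotypes, positions).
    """
    positions = np.sort(rng.uniform(0, length_bp, size=n_markers))
    H = (rng.uniform(size=(2 * n_e, n_markers)) < 0.5).astype(np.int8)
    for _ in range(n_generations):
        new = np.empty_like(H)
        for k in range(2 * n_e):
            parent = rng.integers(n_e)
            h1, h2 = H[2 * parent], H[2 * parent + 1]
            n_cross = rng.poisson(recomb_rate_per_bp * length_bp)
            if n_cross == 0:
                new[k] = h1 if rng.integers(2) == 0 else h2
            else:
                cross = np.sort(rng.uniform(0, length_bp, size=n_cross))
                phase = (rng.integers(2) + np.searchsorted(cross, positions, side="right")) % 2
                new[k] = np.where(phase == 0, h1, h2)
        H = new
    return H, positions


def mean_r2_by_distance(H, positions, edges):
    """Binned mean squared correlation between haplotype columns."""
    keep = (H.mean(axis=0) > 0.05) & (H.mean(axis=0) < 0.95)
    H = H[:, keep].astype(float)
    positions = positions[keep]
    m = H.shape[1]
    Hc = H - H.mean(axis=0)
    sd = Hc.std(axis=0)
    corr = (Hc.T @ Hc) / (len(H) * np.outer(sd, sd))
    r2 = corr**2
    d = np.abs(positions[:, None] - positions[None, :])
    iu = np.triu_indices(m, k=1)
    dist, vals = d[iu], r2[iu]
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        means.append(vals[sel].mean() if sel.any() else np.nan)
    return np.array(means)
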