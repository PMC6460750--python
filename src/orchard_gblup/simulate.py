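"""Synthetic two-orchard open-pollinated populations with linked markers.

Founder haplotypes are drawn from a coalescent drift--recombination model
(msprime) with a per-orchard effective size, so that linkage disequilibrium
decays with physical distance at a controllable rate: the per-bp recombination
rate is calibrated so expected r2 halves at ``ld_decay_bp`` in the reference
(first) orchard, and an orchard with stronger founder culling (smaller
retained fraction => smaller effective size) decays more slowly.

Open-pollinated families: each family shares a known mother; fathers are drawn
from the orchard pollen pool (with a configurable selfing rate) and recorded
as unknown in the documented pedigree.  Phenotypes follow the trial model
(seed source + replicate + set-within-replicate + additive value + residual).

All randomness derives from named substreams of a single master seed, so
identical configs give bit-identical populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream, substream_seed
from .genomics import GenotypeMatrix
from .mixed_model import TrialData
from .pedigree import UNKNOWN_PARENT, Pedigree

__all__ = [
    "InvalidConfigError",
    "SimulationConfig",
    "SyntheticPopulation",
    "simulate_founder_haplotypes",
    "simulate_orchard_population",
    "simulate_phenotypes",
]


class InvalidConfigError(ValueError):
    """A SimulationConfig violates its invariants."""


def _per_orchard(value, n: int, name: str) -> tuple:
    if isinstance(value, (list, tuple, np.ndarray)):
        if len(value) != n:
            raise InvalidConfigError(
                f"{name}: expected scalar or {n} per-orchard values, got {len(value)}"
            )
        return tuple(value)
    return tuple([value] * n)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-orchard progeny trial.

    Scalar fields may be given per orchard as tuples (``n_founders_per_orchard``,
    ``n_families``, ``selection_intensity``).  ``offspring_per_family`` is
    either a fixed count or a ``(min, max, mean)`` triple from which family
    sizes are drawn (shifted binomial, support [min, max], expectation mean).
    """

    n_founders_per_orchard: int | tuple = (60, 40)
    n_families: int | tuple = (45, 25)
    offspring_per_family: int | tuple = (1, 24, 9.6)
    n_markers: int = 1000
    n_chromosomes: int = 5
    chrom_length_bp: int = 1_000_000
    ld_decay_bp: float = 3000.0
    n_qtl: int = 100
    h2_target: float = 0.3
    selection_intensity: float | tuple = (1.0, 0.5)
    n_replicates: int = 3
    n_sets_per_replicate: int = 2
    trait_direction: str = "higher_better"
    trait_name: str = "trait"
    orchard_names: tuple = ("W", "T")
    selfing_rate: float = 0.04
    missing_rate: float = 0.05
    quality_a_range: tuple = (0.0, 1.0)
    quality_b_range: tuple = (0.0, 1.0)
    sigma2_rep_frac: float = 0.10
    sigma2_set_frac: float = 0.10
    seed_source_effect_sd: float = 0.3
    qtl_among_markers: bool = True
    sigma2_e: float | None = None
    n_atsc_families: int = 0
    atsc_offspring_per_family: int = 4
    seed: int = 0

    # -- derived ----------------------------------------------------------
    @property
    def n_orchards(self) -> int:
        return len(self.orchard_names)

    def founders(self) -> tuple:
        return _per_orchard(self.n_founders_per_orchard, self.n_orchards, "n_founders_per_orchard")

    def families(self) -> tuple:
        return _per_orchard(self.n_families, self.n_orchards, "n_families")

    def intensities(self) -> tuple:
        return _per_orchard(self.selection_intensity, self.n_orchards, "selection_intensity")

    def validate(self) -> None:
        if any(f <= 0 for f in self.founders()):
            raise InvalidConfigError("n_founders_per_orchard must be positive")
        if any(f <= 0 for f in self.families()):
            raise InvalidConfigError("n_families must be positive")
        off = self.offspring_per_family
        if isinstance(off, (tuple, list)):
            lo, hi, mean = off
            if lo <= 0 or hi < lo or not (lo <= mean <= hi):
                raise InvalidConfigError(f"invalid offspring_per_family triple {off}")
        elif off <= 0:
            raise InvalidConfigError("offspring_per_family must be positive")
        if self.n_markers <= 0 or self.n_chromosomes <= 0:
            raise InvalidConfigError("n_markers and n_chromosomes must be positive")
        if self.n_markers < self.n_chromosomes:
            raise InvalidConfigError("n_markers must be >= n_chromosomes")
        if not 0.0 <= self.h2_target <= 1.0:
            raise InvalidConfigError("h2_target must lie in [0, 1]")
        if self.h2_target == 1.0 and self.sigma2_e is not None and self.sigma2_e > 0:
            raise InvalidConfigError("h2_target=1 contradicts a forced positive sigma2_e")
        for s in self.intensities():
            if not 0.0 < s <= 1.0:
                raise InvalidConfigError("selection_intensity must lie in (0, 1]")
        if self.ld_decay_bp <= 0:
            raise InvalidConfigError("ld_decay_bp must be positive (math.inf allowed)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise InvalidConfigError("selfing_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.n_replicates <= 0 or self.n_sets_per_replicate <= 0:
            raise InvalidConfigError("design counts must be positive")
        if self.trait_direction not in ("higher_better", "lower_better"):
            raise InvalidConfigError(f"unknown trait_direction {self.trait_direction!r}")
        if self.n_qtl < 0 or (self.n_qtl == 0 and self.h2_target > 0):
            raise InvalidConfigError("n_qtl must be positive when h2_target > 0")


@dataclass
class OrchardHaplotypes:
    """Founder haplotype pool of one orchard: (2*n_founders) x n_markers."""

    orchard: str
    haplotypes: np.ndarray  # int8, rows = haplotypes (two per founder)
    positions: np.ndarray  # bp, 1-based
    chrom: np.ndarray  # chromosome label per marker
    effective_size: float
    recomb_rate_per_bp: float


@dataclass
class SyntheticPopulation:
    pedigree: Pedigree  # documented pedigree (sires unknown)
    genotypes: GenotypeMatrix  # progeny only, missing entries masked
    phenotypes: TrialData
    true_breeding_values: pd.Series
    true_variance_components: dict
    orchard_labels: pd.Series
    realized_pedigree: Pedigree  # truth: actual sires recorded
    founder_ids: dict = field(default_factory=dict)
    realized_parent_ids: list = field(default_factory=list)
    complete_dosages: np.ndarray | None = None  # pre-masking truth
    qtl_marker_indices: np.ndarray | None = None
    config: SimulationConfig | None = None


# ----------------------------------------------------------------------
# Founder haplotypes
# ----------------------------------------------------------------------

def _orchard_effective_size(cfg: SimulationConfig, o: int) -> float:
    return max(2.0, cfg.founders()[o] * cfg.intensities()[o])


def _markers_per_chromosome(n_markers: int, n_chrom: int) -> list[int]:
    base = n_markers // n_chrom
    counts = [base] * n_chrom
    for k in range(n_markers - base * n_chrom):
        counts[k] += 1
    return counts


def simulate_founder_haplotypes(config: SimulationConfig) -> dict[str, OrchardHaplotypes]:
    """Biallelic founder haplotypes on a physical map, one pool per orchard.

    The per-bp recombination rate is ``1 / (4 * Ne_ref * ld_decay_bp)`` with
    ``Ne_ref`` the first orchard's effective size, so expected r2 (~ 1/(1+rho)
    with rho = 4 Ne c d) halves near ``ld_decay_bp`` there; orchards with
    smaller effective size show slower measured decay at the same rate.
    ``ld_decay_bp = inf`` disables recombination entirely (complete LD within
    chromosomes).
    """
    import msprime

    config.validate()
    ne_ref = _orchard_effective_size(config, 0)
    rate = 0.0 if math.isinf(config.ld_decay_bp) else 1.0 / (4.0 * ne_ref * config.ld_decay_bp)

    per_chrom = _markers_per_chromosome(config.n_markers, config.n_chromosomes)
    pools: dict[str, OrchardHaplotypes] = {}
    for o, name in enumerate(config.orchard_names):
        ne = _orchard_effective_size(config, o)
        n_founders = config.founders()[o]
        haps, pos, chroms = [], [], []
        for c in range(config.n_chromosomes):
            m_target = per_chrom[c]
            seed_anc = substream_seed(config.seed, f"founders:{name}:chr{c}:ancestry")
            seed_mut = substream_seed(config.seed, f"founders:{name}:chr{c}:mutations")
            H, p = _simulate_chromosome(
                msprime, n_founders, ne, rate, config.chrom_length_bp, m_target,
                seed_anc, seed_mut, substream(config.seed, f"founders:{name}:chr{c}:pick"),
            )
            haps.append(H)
            pos.append(p)
            chroms.append(np.full(m_target, f"chr{c + 1}", dtype=object))
        pools[name] = OrchardHaplotypes(
            orchard=name,
            haplotypes=np.hstack(haps).astype(np.int8),
            positions=np.concatenate(pos),
            chrom=np.concatenate(chroms),
            effective_size=ne,
            recomb_rate_per_bp=rate,
        )
    return pools


def _simulate_chromosome(
    msprime, n_founders, ne, rate, length, m_target, seed_anc, seed_mut, pick_rng
):
    """One chromosome's founder haplotypes with at least m_target usable sites."""
    mu = 2.5 * m_target / (4.0 * ne * length)  # aim ~2.5x the needed sites
    for _ in range(8):
        ts = msprime.sim_ancestry(
            samples=n_founders,
            population_size=ne,
            sequence_length=length,
            recombination_rate=rate,
            random_seed=seed_anc,
        )
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seed_mut, model=msprime.BinaryMutationModel(),
            discrete_genome=True,
        )
        Gm = mts.genotype_matrix()  # sites x haplotypes
        pos = np.array([int(s.position) + 1 for s in mts.sites()])
        biallelic = (Gm.max(axis=1) <= 1)
        freq = Gm.mean(axis=1)
        usable = biallelic & (freq >= 0.05) & (freq <= 0.95)
        # deduplicate positions (discrete genome can stack mutations)
        _, first = np.unique(pos, return_index=True)
        keep = np.zeros(len(pos), dtype=bool)
        keep[first] = True
        usable &= keep
        idx = np.flatnonzero(usable)
        if len(idx) >= m_target:
            chosen = np.sort(pick_rng.choice(idx, size=m_target, replace=False))
            return Gm[chosen].T.copy(), pos[chosen]
        mu *= 2.0
    raise RuntimeError(
        f"could not obtain {m_target} polymorphic sites on a chromosome; "
        "increase chrom_length_bp or reduce marker density"
    )


# ----------------------------------------------------------------------
# Population
# ----------------------------------------------------------------------

def _family_sizes(cfg: SimulationConfig, n_fam: int, rng: np.random.Generator) -> np.ndarray:
    off = cfg.offspring_per_family
    if isinstance(off, (tuple, list)):
        lo, hi, mean = off
        if hi == lo:
            return np.full(n_fam, int(lo))
        p = (mean - lo) / (hi - lo)
        return lo + rng.binomial(hi - lo, p, size=n_fam)
    return np.full(n_fam, int(off))


def _gamete(hapA, hapB, positions, chrom, rate, rng):
    """Recombine one parent's two haplotypes into a gamete, per chromosome."""
    out = np.empty_like(hapA)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = positions[idx]
        length = float(p.max() - p.min()) if len(p) > 1 else 0.0
        n_cross = rng.poisson(rate * length) if (rate > 0 and length > 0) else 0
        current = int(rng.integers(2))
        if n_cross == 0:
            src = hapA if current == 0 else hapB
            out[idx] = src[idx]
            continue
        cross = np.sort(rng.uniform(p.min(), p.max(), size=n_cross))
        phase = (current + np.searchsorted(cross, p, side="right")) % 2
        out[idx] = np.where(phase == 0, hapA[idx], hapB[idx])
    return out


def simulate_orchard_population(config: SimulationConfig) -> SyntheticPopulation:
    """Full synthetic progeny trial: pedigree, genotypes, phenotypes, truth.

    Founder culling retains ``round(selection_intensity * n_founders)`` parents
    per orchard; mothers are drawn from the retained pool, fathers drawn per
    offspring from the same pollen pool (selfing with probability
    ``selfing_rate``).  The documented pedigree records sires as unknown; the
    realized pedigree keeps the true sires for truth-based checks.
    """
    config.validate()
    pools = simulate_founder_haplotypes(config)

    ped_docs: list[tuple[str, str, str]] = []
    ped_true: list[tuple[str, str, str]] = []
    prog_ids: list[str] = []
    prog_orchard: list[str] = []
    prog_family: list[str] = []
    dosage_rows: list[np.ndarray] = []
    founder_ids: dict[str, list[str]] = {}
    realized_parents: list[str] = []

    first = pools[config.orchard_names[0]]
    positions, chroms, rate = first.positions, first.chrom, first.recomb_rate_per_bp

    for o, name in enumerate(config.orchard_names):
        pool = pools[name]
        n_found = config.founders()[o]
        fids = [f"{name}F{k + 1:03d}" for k in range(n_found)]
        founder_ids[name] = fids
        for fid in fids:
            ped_docs.append((fid, UNKNOWN_PARENT, UNKNOWN_PARENT))
            ped_true.append((fid, UNKNOWN_PARENT, UNKNOWN_PARENT))

        rng_cull = substream(config.seed, f"cull:{name}")
        n_keep = max(1, int(round(config.intensities()[o] * n_found)))
        retained = sorted(rng_cull.permutation(n_found)[:n_keep].tolist())

        rng_mate = substream(config.seed, f"mating:{name}")
        n_fam = config.families()[o]
        mother_pool = np.array(retained)
        mothers = rng_mate.choice(mother_pool, size=n_fam, replace=n_fam > len(mother_pool))
        sizes = _family_sizes(config, n_fam, rng_mate)

        hap = pool.haplotypes  # 2 per founder: rows 2k, 2k+1
        for f, (mom, fam_size) in enumerate(zip(mothers, sizes)):
            fam = f"{name}FAM{f + 1:03d}"
            for k in range(fam_size):
                if rng_mate.uniform() < config.selfing_rate:
                    dad = int(mom)
                else:
                    dad = int(rng_mate.choice(mother_pool))
                child = f"{name}P{len(prog_ids) + 1:04d}"
                g_m = _gamete(hap[2 * mom], hap[2 * mom + 1], positions, chroms, rate, rng_mate)
                g_p = _gamete(hap[2 * dad], hap[2 * dad + 1], positions, chroms, rate, rng_mate)
                dosage_rows.append((g_m + g_p).astype(float))
                ped_docs.append((child, UNKNOWN_PARENT, fids[mom]))
                ped_true.append((child, fids[dad], fids[mom]))
                realized_parents.extend([fids[mom], fids[dad]])
                prog_ids.append(child)
                prog_orchard.append(name)
                prog_family.append(fam)

    if config.n_atsc_families > 0:
        _add_atsc_group(
            config, positions, chroms, rate, ped_docs, ped_true,
            prog_ids, prog_orchard, prog_family, dosage_rows, founder_ids,
        )

    complete = np.vstack(dosage_rows)
    if not config.qtl_among_markers and config.n_qtl > 0:
        rng_qtl = substream(config.seed, "qtl")
        qtl_idx = np.sort(rng_qtl.choice(complete.shape[1], size=config.n_qtl, replace=False))
        marker_idx = np.setdiff1d(np.arange(complete.shape[1]), qtl_idx)
    else:
        rng_qtl = substream(config.seed, "qtl")
        n_qtl = min(config.n_qtl, complete.shape[1])
        qtl_idx = np.sort(rng_qtl.choice(complete.shape[1], size=n_qtl, replace=False))
        marker_idx = np.arange(complete.shape[1])

    tbv = _true_breeding_values(config, complete, qtl_idx)

    genotypes = _released_genotypes(config, prog_ids, complete, marker_idx, positions, chroms)

    pop = SyntheticPopulation(
        pedigree=Pedigree(ped_docs),
        genotypes=genotypes,
        phenotypes=None,  # filled below
        true_breeding_values=pd.Series(tbv, index=prog_ids, name="tbv"),
        true_variance_components={},
        orchard_labels=pd.Series(prog_orchard, index=prog_ids, name="orchard"),
        realized_pedigree=Pedigree(ped_true),
        founder_ids=founder_ids,
        realized_parent_ids=sorted(set(realized_parents)),
        complete_dosages=complete[:, marker_idx],
        qtl_marker_indices=qtl_idx,
        config=config,
    )
    pop._family = pd.Series(prog_family, index=prog_ids)
    pop.phenotypes = simulate_phenotypes(pop, config)
    return pop


def _add_atsc_group(
    config, positions, chroms, rate, ped_docs, ped_true,
    prog_ids, prog_orchard, prog_family, dosage_rows, founder_ids,
):
    """Optional small control group with its own founder pool."""
    atsc_cfg = replace(
        config,
        orchard_names=("ATSC",),
        n_founders_per_orchard=max(4, 2 * config.n_atsc_families),
        selection_intensity=1.0,
        n_families=config.n_atsc_families,
    )
    pool = simulate_founder_haplotypes(atsc_cfg)["ATSC"]
    n_found = atsc_cfg.founders()[0]
    fids = [f"AF{k + 1:03d}" for k in range(n_found)]
    founder_ids["ATSC"] = fids
    for fid in fids:
        ped_docs.append((fid, UNKNOWN_PARENT, UNKNOWN_PARENT))
        ped_true.append((fid, UNKNOWN_PARENT, UNKNOWN_PARENT))
    rng = substream(config.seed, "mating:ATSC")
    mothers = rng.choice(n_found, size=config.n_atsc_families, replace=False)
    hap = pool.haplotypes
    for f, mom in enumerate(mothers):
        for _ in range(config.atsc_offspring_per_family):
            dad = int(rng.choice(n_found))
            child = f"AP{len(prog_ids) + 1:04d}"
            g_m = _gamete(hap[2 * mom], hap[2 * mom + 1], positions, chroms, rate, rng)
            g_p = _gamete(hap[2 * dad], hap[2 * dad + 1], positions, chroms, rate, rng)
            dosage_rows.append((g_m + g_p).astype(float))
            ped_docs.append((child, UNKNOWN_PARENT, fids[mom]))
            ped_true.append((child, fids[dad], fids[mom]))
            prog_ids.append(child)
            prog_orchard.append("ATSC")
            prog_family.append(f"AFAM{f + 1:03d}")


def _true_breeding_values(config, complete, qtl_idx) -> np.ndarray:
    """Additive values from QTL effects, rescaled so var(TBV) = sigma2_a."""
    sigma2_a = config.h2_target
    n = complete.shape[0]
    if sigma2_a == 0.0 or len(qtl_idx) == 0:
        return np.zeros(n)
    rng = substream(config.seed, "qtl_effects")
    effects = rng.normal(size=len(qtl_idx))
    Q = complete[:, qtl_idx]
    raw = (Q - Q.mean(axis=0)) @ effects
    v = raw.var(ddof=1)
    if v <= 0:
        return np.zeros(n)
    return raw * math.sqrt(sigma2_a / v)


def _released_genotypes(config, prog_ids, complete, marker_idx, positions, chroms):
    """Mask missing entries MCAR and attach quality-score metadata."""
    D = complete[:, marker_idx].copy()
    rng_miss = substream(config.seed, "missing")
    if config.missing_rate > 0:
        mask = rng_miss.uniform(size=D.shape) < config.missing_rate
        D[mask] = np.nan
    rng_q = substream(config.seed, "quality")
    qa = rng_q.uniform(*config.quality_a_range, size=len(marker_idx))
    qb = rng_q.uniform(*config.quality_b_range, size=len(marker_idx))
    marker_ids = [f"m{int(k) + 1:05d}" for k in marker_idx]
    meta = pd.DataFrame(
        {
            "chrom": chroms[marker_idx],
            "pos": positions[marker_idx],
            "qa": qa,
            "qb": qb,
        },
        index=marker_ids,
    )
    return GenotypeMatrix(prog_ids, marker_ids, D, meta)


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

def simulate_phenotypes(pop: SyntheticPopulation, config: SimulationConfig) -> TrialData:
    """Trial phenotypes: seed source + replicate + set(rep) + TBV + residual.

    Additive values are the population's true breeding values (from complete
    QTL dosages).  Residual variance defaults to ``1 - h2_target`` on the unit
    phenotypic scale; replicate and set effects add ``sigma2_rep_frac`` and
    ``sigma2_set_frac`` of that scale each.  Realized narrow-sense h2
    (var(TBV) / (var(TBV) + sigma2_e)) sits within sampling error of target.
    """
    config.validate()
    ids = list(pop.true_breeding_values.index)
    n = len(ids)
    tbv = pop.true_breeding_values.to_numpy()
    sigma2_e = config.sigma2_e if config.sigma2_e is not None else 1.0 - config.h2_target
    if config.h2_target == 1.0:
        sigma2_e = 0.0
    sigma2_r = config.sigma2_rep_frac
    sigma2_rs = config.sigma2_set_frac

    rng = substream(config.seed, "phenotype")
    rep_labels = [f"rep{r + 1}" for r in range(config.n_replicates)]
    rep_eff = rng.normal(0.0, math.sqrt(sigma2_r), size=config.n_replicates)
    set_eff = rng.normal(
        0.0, math.sqrt(sigma2_rs), size=(config.n_replicates, config.n_sets_per_replicate)
    )

    orchards = pop.orchard_labels.loc[ids].to_numpy()
    seed_sources = sorted(set(orchards))
    ss_eff = {s: e for s, e in zip(
        seed_sources, rng.normal(0.0, config.seed_source_effect_sd, size=len(seed_sources))
    )}

    rep_idx = rng.integers(config.n_replicates, size=n)

    # families are partitioned into sets within each replicate
    fam = pop._family.loc[ids].to_numpy() if hasattr(pop, "_family") else np.array(ids)
    fams = pd.unique(fam)
    set_of: dict[tuple[int, str], int] = {}
    for r in range(config.n_replicates):
        perm = rng.permutation(len(fams))
        for j, fi in enumerate(perm):
            set_of[(r, fams[fi])] = j % config.n_sets_per_replicate

    set_idx = np.array([set_of[(int(r), f)] for r, f in zip(rep_idx, fam)])
    resid = rng.normal(0.0, math.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)

    y = (
        10.0
        + np.array([ss_eff[o] for o in orchards])
        + rep_eff[rep_idx]
        + set_eff[rep_idx, set_idx]
        + tbv
        + resid
    )

    frame = pd.DataFrame(
        {
            "id": ids,
            "seed_source": orchards,
            "replicate": [rep_labels[r] for r in rep_idx],
            "set": [f"set{s + 1}" for s in set_idx],
            "orchard": orchards,
            config.trait_name: y,
        }
    )
    pop.true_variance_components = {
        "sigma2_a": float(pop.true_breeding_values.var(ddof=1)) if n > 1 else 0.0,
        "sigma2_r": sigma2_r,
        "sigma2_rs": sigma2_rs,
        "sigma2_e": sigma2_e,
    }
    return TrialData(frame, [config.trait_name])
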