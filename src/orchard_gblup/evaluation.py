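"""Cross-validation predictive accuracy and genetic-gain comparison.

Scenarios are named ``TRAIN-VALID`` over orchard groups (e.g. ``W-W``,
``W-T``, ``WT-WT``).  Within-population scenarios use k-fold CV: each fold's
phenotypes are withheld and predicted from the remaining folds.  Between-
population scenarios use the full training population every time, with folds
partitioning the validation population so that ``n_folds x n_replications``
prediction sets still exist.

Predictive accuracy is the Pearson correlation between the full-data
pedigree-model EBVs of the validation individuals and their cross-validated
predictions (marker-only for GBLUP).  Genetic gain is the mean breeding value
of the top fraction selected in the trait's favourable direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mixed_model import (
    BreedingValueSet,
    TrialData,
    VarianceComponents,
    build_design,
    reml_fit,
    solve_blup,
)
from .pedigree import RelationshipMatrix

__all__ = [
    "CVScenario",
    "CVResult",
    "GeneticGainResult",
    "make_folds",
    "predictive_accuracy",
    "cross_validate",
    "genetic_gain",
    "gain_comparison_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVScenario:
    """Training/validation orchard groups plus fold/replication structure."""

    training: tuple
    validation: tuple
    n_folds: int = 10
    n_replications: int = 30
    seed: int = 0

    @classmethod
    def from_name(cls, name: str, **kw) -> "CVScenario":
        """Parse ``'W-T'`` / ``'WT-WT'`` style scenario names."""
        try:
            tr, va = name.split("-")
        except ValueError as err:
            raise ValueError(f"scenario name must be TRAIN-VALID, got {name!r}") from err
        return cls(training=tuple(tr), validation=tuple(va), **kw)

    @property
    def name(self) -> str:
        return f"{''.join(self.training)}-{''.join(self.validation)}"

    @property
    def between(self) -> bool:
        return set(self.training) != set(self.validation)


@dataclass
class CVResult:
    scenario: str
    trait: str
    model: str
    mean_rp: float
    sd_rp: float
    per_replication: list
    n_fits: int = 0
    zero_information: bool = False

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "trait": self.trait,
            "model": self.model,
            "mean_rp": self.mean_rp,
            "sd_rp": self.sd_rp,
            "n_replications": len(self.per_replication),
        }


@dataclass
class GeneticGainResult:
    trait: str
    gain: float
    proportion: float
    direction: str
    n_selected: int
    selected_ids: list = field(default_factory=list)


def make_folds(ids: Sequence[str], n_folds: int, replication_seed: int) -> dict[str, int]:
    """Random fold assignment, fold sizes differing by at most one.

    A pure function of ``(ids, n_folds, replication_seed)``: the same inputs
    always give the same assignment.
    """
    ids = [str(i) for i in ids]
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n_folds > len(ids):
        raise ValueError(f"n_folds={n_folds} exceeds {len(ids)} individuals")
    rng = np.random.default_rng(np.random.SeedSequence([int(replication_seed) & 0xFFFFFFFF]))
    perm = rng.permutation(len(ids))
    assignment = {}
    for k, j in enumerate(perm):
        assignment[ids[j]] = k % n_folds
    return assignment


def predictive_accuracy(ebv_reference: pd.Series, predicted: pd.Series) -> float:
    """Pearson correlation of aligned reference EBVs and CV predictions.

    Raises on zero variance (an undefined correlation is never reported as 0).
    """
    common = ebv_reference.index.intersection(predicted.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned individuals for a correlation")
    x = ebv_reference.loc[common].to_numpy(dtype=float)
    y = predicted.loc[common].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in EBV or prediction vector; r_p undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _orchard_ids(data: TrialData, groups: Sequence[str]) -> list[str]:
    df = data.frame
    return df.loc[df["orchard"].isin(list(groups)), "id"].tolist()


def cross_validate(
    data: TrialData,
    kernel: RelationshipMatrix,
    reference_ebv: pd.Series,
    scenario: CVScenario,
    trait: str,
    model: str = "GBLUP",
    vc: VarianceComponents | None = None,
    reml_kwargs: dict | None = None,
) -> CVResult:
    """Run one CV scenario for one trait and kernel.

    ``kernel`` must cover training and validation individuals jointly (for
    GBLUP this is the G matrix over both orchards, so marker relationships
    connect training and validation; for BLUP it is A).  Variance components
    are estimated once on the full training records (or passed in via ``vc``);
    each replication x fold then re-solves the mixed-model equations with the
    validation phenotypes withheld, which is the step that defines a "fit".

    Validation individuals with no kernel link to the training set produce
    (near-)constant predictions; such replications are flagged as structurally
    zero-information and contribute r_p = 0 with ``zero_information=True``.
    """
    train_ids = set(_orchard_ids(data, scenario.training))
    valid_ids = sorted(set(_orchard_ids(data, scenario.validation)))
    if not train_ids or not valid_ids:
        raise ValueError(f"scenario {scenario.name}: empty training or validation set")
    if scenario.between and model.upper() == "GBLUP" and kernel.kind != "G":
        raise ValueError("between-orchard GBLUP requires a joint G kernel over both orchards")

    pool = data.subset(data.frame["orchard"].isin(
        sorted(set(scenario.training) | set(scenario.validation))
    ))

    if vc is None:
        train_data = data.subset(data.frame["id"].isin(train_ids))
        design_tr = build_design(train_data, kernel, trait)
        vc = reml_fit(design_tr, kernel, **(reml_kwargs or {}))

    rp_values: list[float] = []
    n_fits = 0
    any_zero_info = False
    for r in range(scenario.n_replications):
        rep_seed = scenario.seed + r  # each replication re-runnable in isolation
        folds = make_folds(valid_ids, scenario.n_folds, rep_seed)
        predicted = {}
        for k in range(scenario.n_folds):
            held = {i for i, f in folds.items() if f == k}
            if scenario.between:
                keep = pool.frame["id"].isin(train_ids)
            else:
                keep = pool.frame["id"].isin(train_ids - held)
            fit_data = pool.subset(keep)
            design = build_design(fit_data, kernel, trait)
            bvs, _ = solve_blup(design, kernel, vc)
            n_fits += 1
            ub = bvs.series()
            for i in held:
                predicted[i] = float(ub.loc[i])
        pred = pd.Series(predicted).loc[valid_ids]
        if pred.std() < 1e-10 * max(1.0, abs(pred.mean())) or pred.std() == 0:
            any_zero_info = True
            rp_values.append(0.0)
            continue
        rp_values.append(predictive_accuracy(reference_ebv, pred))

    arr = np.array(rp_values)
    result = CVResult(
        scenario=scenario.name,
        trait=trait,
        model=model.upper(),
        mean_rp=float(arr.mean()),
        sd_rp=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        per_replication=arr.tolist(),
        n_fits=n_fits,
        zero_information=any_zero_info,
    )
    log.info(
        "CV %s %s %s: mean r_p=%.3f sd=%.3f (%d fits)%s",
        result.scenario, trait, result.model, result.mean_rp, result.sd_rp,
        n_fits, " [zero-information]" if any_zero_info else "",
    )
    return result


def genetic_gain(
    bvs: BreedingValueSet | pd.Series,
    proportion: float = 0.2,
    direction: str = "higher_better",
    trait: str = "trait",
) -> GeneticGainResult:
    """Mean breeding value of the selected top fraction.

    Individuals are ranked in the favourable direction; ``ceil(proportion*n)``
    are selected, ties broken by stable id order.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    series = bvs.series() if isinstance(bvs, BreedingValueSet) else bvs
    if len(series) == 0:
        raise ValueError("empty breeding-value set")
    n_sel = math.ceil(proportion * len(series))
    df = pd.DataFrame({"id": series.index.astype(str), "bv": series.to_numpy(dtype=float)})
    df = df.sort_values(
        ["bv", "id"], ascending=[direction == "lower_better", True], kind="stable"
    )
    sel = df.head(n_sel)
    return GeneticGainResult(
        trait=trait,
        gain=float(sel["bv"].mean()),
        proportion=proportion,
        direction=direction,
        n_selected=n_sel,
        selected_ids=sel["id"].tolist(),
    )


def gain_comparison_report(
    blup_bvs: dict[str, BreedingValueSet | pd.Series],
    gblup_bvs: dict[str, BreedingValueSet | pd.Series],
    traits: Sequence[str],
    proportion: float = 0.2,
    directions: dict[str, str] | None = None,
    extra_columns: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Per-trait side-by-side gains under the pedigree and genomic models.

    ``extra_columns`` may carry per-trait h2/se/r values to reproduce the
    full comparison-table layout.
    """
    rows = []
    directions = directions or {}
    for t in traits:
        if t not in blup_bvs or t not in gblup_bvs:
            raise KeyError(f"trait {t!r} missing from one of the breeding-value sets")
        b = blup_bvs[t].series() if isinstance(blup_bvs[t], BreedingValueSet) else blup_bvs[t]
        g = gblup_bvs[t].series() if isinstance(gblup_bvs[t], BreedingValueSet) else gblup_bvs[t]
        if set(b.index) != set(g.index):
            diff = sorted(set(b.index) ^ set(g.index))
            raise ValueError(f"breeding-value sets cover different individuals: {diff[:10]}")
        direction = directions.get(t, "higher_better")
        row = {
            "trait": t,
            "gain_blup": genetic_gain(b, proportion, direction, t).gain,
            "gain_gblup": genetic_gain(g, proportion, direction, t).gain,
            "proportion": proportion,
            "direction": direction,
        }
        if extra_columns and t in extra_columns:
            row.update(extra_columns[t])
        rows.append(row)
    return pd.DataFrame(rows)
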