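"""The numerical experiments: validation and parameter sweeps.

Four orchestrations probe how fingerprint-based classification responds to
the simulation parameters:

* :func:`validate_against_reference` — simulate cohorts at reference sizes
  and compare differential fingerprints, per-class standard-deviation curves
  and cross-validated AUCs against the reference cohort itself.
* :func:`cohort_size_sweep` — CV AUC as a function of cohort size.
* :func:`noise_grid_sweep` — full factorial grid of biological-variability
  and measurement-noise scale factors.
* :func:`complexity_sweep` — molecular complexity: each class rebuilt from
  ``m`` freshly drawn, disjoint calibration vectors (``2 x m`` in total) with
  the biological-variability strength pinned at the full-pool calibration.

Every sweep cell is reproducible from ``(settings, seed)`` alone; cells use
independent derived random streams, so serial and concurrent execution give
identical results. Replicate cohorts redraw both the cohort and (for the
complexity sweep) the basis subsets; measurement noise is redrawn per
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .calibration import (
    DescriptiveModel,
    DiscriminantModel,
    NoiseModel,
    calibrate_descriptive,
    estimate_discriminant,
)
from .classification import ClassificationResult, repeated_kfold_cv
from .cohort import SpectralCohort
from .errors import UnsplittableError, ValidationError
from .generator import SimulationConfig, simulate_case_control, subsample_basis_pair
from .rng import child_seed

__all__ = [
    "SweepResult",
    "ValidationReport",
    "validate_against_reference",
    "cohort_size_sweep",
    "noise_grid_sweep",
    "complexity_sweep",
]

SCHEMA_VERSION = "1"


@dataclass
class SweepResult:
    """Grid of simulation settings mapped to CV-AUC summaries.

    ``cells`` has one row per grid point with ``mean_auc``, ``std_auc`` and
    ``n_replicates`` (the number of stored fold-level AUCs); ``folds`` is the
    long table of every fold AUC behind each cell, so the aggregation
    ``cells.mean_auc == folds.groupby(axes).auc.mean()`` holds exactly.
    """

    axes: Dict[str, list]
    cells: pd.DataFrame
    folds: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.cells["n_replicates"] <= 0).any():
            raise ValidationError("every sweep cell needs at least one replicate")
        if ((self.cells["mean_auc"] < 0) | (self.cells["mean_auc"] > 1)).any():
            raise ValidationError("mean_auc out of [0, 1]")

    @property
    def axis_names(self) -> list:
        return list(self.axes)

    def cell(self, **coords) -> pd.Series:
        mask = np.ones(len(self.cells), dtype=bool)
        for name, value in coords.items():
            mask &= np.isclose(self.cells[name].to_numpy(dtype=float), float(value))
        hits = self.cells[mask]
        if len(hits) != 1:
            raise KeyError(f"coordinates {coords} match {len(hits)} cells")
        return hits.iloc[0]


def _aggregate(folds: pd.DataFrame, axes: Dict[str, list], settings: dict) -> SweepResult:
    names = list(axes)
    grouped = folds.groupby(names, sort=True)["auc"]
    cells = grouped.agg(
        mean_auc="mean", std_auc=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n_replicates="size"
    ).reset_index()
    return SweepResult(axes={k: sorted(v) for k, v in axes.items()}, cells=cells, folds=folds, settings=settings)


CaseSpec = Union[DescriptiveModel, DiscriminantModel]


def _cv_folds_for_cohort(cohort: SpectralCohort, k: int, penalty_strength: float, seed: int):
    return repeated_kfold_cv(
        cohort, k=k, repeats=1, penalty_strength=penalty_strength, seed=seed
    ).fold_aucs


# ---------------------------------------------------------------------------
# validation against a reference cohort
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Comparison of simulated cohorts with the reference they calibrate on."""

    wavenumbers: np.ndarray
    diff_reference: np.ndarray
    diff_simulated_mean: np.ndarray
    diff_simulated_std: np.ndarray
    std_reference: Dict[str, np.ndarray]
    std_simulated_mean: Dict[str, np.ndarray]
    auc_reference: ClassificationResult
    auc_simulated: ClassificationResult
    settings: dict


def validate_against_reference(
    reference_cases: SpectralCohort,
    reference_controls: SpectralCohort,
    noise: Optional[NoiseModel],
    n_datasets: int = 10,
    seed: int = 0,
    k: int = 10,
    reference_repeats: int = 10,
    penalty_strength: float = 1.0,
) -> ValidationReport:
    """Simulate ``n_datasets`` cohorts at reference sizes and compare their
    statistics and CV performance with the reference cohort.

    The reference AUC uses ``reference_repeats``-times repeated k-fold CV;
    the simulated AUC runs one k-fold CV per simulated dataset, totalling
    ``n_datasets * k`` folds.
    """
    control_model = calibrate_descriptive(reference_controls)
    case_model = calibrate_descriptive(reference_cases)
    diff_ref = estimate_discriminant(reference_cases, reference_controls).d

    diffs, stds_control, stds_case, sim_folds, sim_rocs = [], [], [], [], []
    for ds in range(n_datasets):
        sim = simulate_case_control(
            control_model,
            case_model,
            noise,
            SimulationConfig(
                n_controls=reference_controls.n,
                n_cases=reference_cases.n,
                seed=child_seed(seed, 0, ds),
            ),
        )
        sim_controls = sim.with_label("control")
        sim_cases = sim.with_label("case")
        diffs.append(estimate_discriminant(sim_cases, sim_controls).d)
        stds_control.append(sim_controls.absorbance.std(axis=0, ddof=1))
        stds_case.append(sim_cases.absorbance.std(axis=0, ddof=1))
        res = repeated_kfold_cv(
            sim, k=k, repeats=1, penalty_strength=penalty_strength, seed=child_seed(seed, 1, ds)
        )
        sim_folds.extend(res.fold_aucs.tolist())
        sim_rocs.append(res.roc_points[:, 1])

    reference = SpectralCohort.concat([reference_controls, reference_cases])
    auc_ref = repeated_kfold_cv(
        reference, k=k, repeats=reference_repeats, penalty_strength=penalty_strength,
        seed=child_seed(seed, 2),
    )
    settings = {
        "n_datasets": n_datasets,
        "k": k,
        "reference_repeats": reference_repeats,
        "penalty_strength": penalty_strength,
        "seed": int(seed),
        "schema_version": SCHEMA_VERSION,
    }
    auc_sim = ClassificationResult.from_folds(
        sim_folds,
        [np.column_stack([np.linspace(0, 1, len(r)), r])[:, 1] for r in sim_rocs],
        {**settings, "evaluation": "simulated"},
    )
    return ValidationReport(
        wavenumbers=reference_controls.wavenumbers,
        diff_reference=diff_ref,
        diff_simulated_mean=np.mean(diffs, axis=0),
        diff_simulated_std=np.std(diffs, axis=0, ddof=1) if n_datasets > 1 else np.zeros_like(diff_ref),
        std_reference={
            "control": reference_controls.absorbance.std(axis=0, ddof=1),
            "case": reference_cases.absorbance.std(axis=0, ddof=1),
        },
        std_simulated_mean={
            "control": np.mean(stds_control, axis=0),
            "case": np.mean(stds_case, axis=0),
        },
        auc_reference=auc_ref,
        auc_simulated=auc_sim,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def cohort_size_sweep(
    control_model: DescriptiveModel,
    case_spec: CaseSpec,
    noise: Optional[NoiseModel],
    sizes: Sequence[int],
    replicates: int = 10,
    seed: int = 0,
    k: int = 10,
    beta_scale: float = 1.0,
    eps_scale: float = 1.0,
    penalty_strength: float = 1.0,
) -> SweepResult:
    """CV AUC at each total cohort size (balanced arms, ``size // 2`` each)."""
    sizes = sorted(int(s) for s in sizes)
    for s in sizes:
        if s < 2 * k:
            raise UnsplittableError(f"cohort size {s} cannot support {k}-fold stratified CV")
    rows = []
    for si, size in enumerate(sizes):
        per_arm = size // 2
        for rep in range(replicates):
            sim = simulate_case_control(
                control_model,
                case_spec,
                noise,
                SimulationConfig(
                    n_controls=per_arm,
                    n_cases=size - per_arm,
                    beta_scale=beta_scale,
                    eps_scale=eps_scale,
                    case_mode="two-pool" if isinstance(case_spec, DescriptiveModel) else "discriminant",
                    seed=child_seed(seed, 0, si, rep),
                ),
            )
            for auc in _cv_folds_for_cohort(sim, k, penalty_strength, child_seed(seed, 1, si, rep)):
                rows.append({"n": size, "replicate": rep, "auc": auc})
    folds = pd.DataFrame(rows)
    settings = {
        "sweep": "cohort_size",
        "replicates": replicates,
        "k": k,
        "beta_scale": beta_scale,
        "eps_scale": eps_scale,
        "penalty_strength": penalty_strength,
        "seed": int(seed),
        "schema_version": SCHEMA_VERSION,
    }
    return _aggregate(folds, {"n": sizes}, settings)


def noise_grid_sweep(
    control_model: DescriptiveModel,
    case_spec: CaseSpec,
    noise: NoiseModel,
    beta_scales: Sequence[float],
    eps_scales: Sequence[float],
    n_controls: int,
    n_cases: int,
    replicates: int = 10,
    seed: int = 0,
    k: int = 10,
    penalty_strength: float = 1.0,
) -> SweepResult:
    """Full factorial grid over biological-variability and noise scales.

    The calibration point is ``(beta_scale, eps_scale) = (1, 1)``; the
    within-person scenario corresponds to ``(0.5, 1)`` — the between-person
    spread of the biological coefficients halved at unchanged noise.
    """
    beta_scales = sorted(float(b) for b in beta_scales)
    eps_scales = sorted(float(e) for e in eps_scales)
    rows = []
    for bi, beta in enumerate(beta_scales):
        for ei, eps in enumerate(eps_scales):
            for rep in range(replicates):
                sim = simulate_case_control(
                    control_model,
                    case_spec,
                    noise,
                    SimulationConfig(
                        n_controls=n_controls,
                        n_cases=n_cases,
                        beta_scale=beta,
                        eps_scale=eps,
                        case_mode="two-pool" if isinstance(case_spec, DescriptiveModel) else "discriminant",
                        seed=child_seed(seed, 0, bi, ei, rep),
                    ),
                )
                for auc in _cv_folds_for_cohort(
                    sim, k, penalty_strength, child_seed(seed, 1, bi, ei, rep)
                ):
                    rows.append(
                        {"beta_scale": beta, "eps_scale": eps, "replicate": rep, "auc": auc}
                    )
    folds = pd.DataFrame(rows)
    settings = {
        "sweep": "noise_grid",
        "replicates": replicates,
        "k": k,
        "n_controls": n_controls,
        "n_cases": n_cases,
        "penalty_strength": penalty_strength,
        "seed": int(seed),
        "schema_version": SCHEMA_VERSION,
    }
    return _aggregate(folds, {"beta_scale": beta_scales, "eps_scale": eps_scales}, settings)


def complexity_sweep(
    control_model: DescriptiveModel,
    case_model: DescriptiveModel,
    noise: Optional[NoiseModel],
    m_values: Sequence[int],
    beta_scales: Sequence[float] = (1.0,),
    sizes: Optional[Sequence[int]] = None,
    replicates: int = 10,
    seed: int = 0,
    k: int = 10,
    eps_scale: float = 1.0,
    penalty_strength: float = 1.0,
    auc_threshold: float = 0.99,
) -> SweepResult:
    """Molecular-complexity sweep over ``(m, beta_scale, n)``.

    Each replicate draws a fresh pair of disjoint ``m``-vector subsets (one
    per class, ``2 x m`` distinct source vectors in total), keeps the mean
    spectra constant and the ``beta_sigma`` pinned at the full-pool value,
    simulates a balanced cohort and cross-validates. ``sizes`` defaults to
    the calibrating pool sizes. The result's settings carry, per
    ``(beta_scale, n)``, the largest ``m`` whose mean AUC still reaches
    ``auc_threshold`` (NaN when none does).
    """
    pool = min(control_model.m, case_model.m)
    m_values = sorted(int(m) for m in m_values)
    if m_values and 2 * m_values[-1] > pool:
        raise ValidationError(
            f"m={m_values[-1]} exceeds the pool: need 2*m <= {pool} for disjoint draws"
        )
    beta_scales = sorted(float(b) for b in beta_scales)
    if sizes is None:
        sizes = [control_model.m + case_model.m]
    sizes = sorted(int(s) for s in sizes)

    rows = []
    for mi, m in enumerate(m_values):
        for bi, beta in enumerate(beta_scales):
            for si, size in enumerate(sizes):
                per_arm = size // 2
                for rep in range(replicates):
                    sub_control, sub_case = subsample_basis_pair(
                        control_model,
                        case_model,
                        m,
                        seed=child_seed(seed, 0, mi, bi, si, rep),
                        pin_beta_sigma=True,
                    )
                    sim = simulate_case_control(
                        sub_control,
                        sub_case,
                        noise,
                        SimulationConfig(
                            n_controls=per_arm,
                            n_cases=size - per_arm,
                            beta_scale=beta,
                            eps_scale=eps_scale,
                            seed=child_seed(seed, 1, mi, bi, si, rep),
                        ),
                    )
                    for auc in _cv_folds_for_cohort(
                        sim, k, penalty_strength, child_seed(seed, 2, mi, bi, si, rep)
                    ):
                        rows.append(
                            {
                                "m": m,
                                "beta_scale": beta,
                                "n": size,
                                "replicate": rep,
                                "auc": auc,
                            }
                        )
    folds = pd.DataFrame(rows)
    settings = {
        "sweep": "complexity",
        "replicates": replicates,
        "k": k,
        "eps_scale": eps_scale,
        "penalty_strength": penalty_strength,
        "auc_threshold": auc_threshold,
        "seed": int(seed),
        "schema_version": SCHEMA_VERSION,
    }
    result = _aggregate(
        folds, {"m": m_values, "beta_scale": beta_scales, "n": sizes}, settings
    )
    # largest m still achieving the threshold, per (beta_scale, n)
    thresholds = {}
    for beta in beta_scales:
        for size in sizes:
            sub = result.cells[
                np.isclose(result.cells["beta_scale"], beta) & (result.cells["n"] == size)
            ]
            ok = sub[sub["mean_auc"] >= auc_threshold]["m"]
            thresholds[f"beta={beta:g},n={size}"] = int(ok.max()) if len(ok) else float("nan")
    result.settings["m_threshold"] = thresholds
    return result
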