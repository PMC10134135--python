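"""Drawing simulated spectral cohorts from calibrated models.

All operations are pure functions of ``(inputs, seed)``: the same seed gives
bit-identical cohorts. The biological-variability coefficients ``beta`` and
the measurement-noise vector ``eps`` can be scaled independently; both scale
factors multiply *standard deviations*, so ``beta_scale = 0.5`` halves the
spread of the biological coefficients (the within-person scenario) and
``eps_scale = 0`` removes measurement noise entirely.

Beta coefficients are drawn i.i.d. per simulated spectrum and per calibration
vector. Real molecular concentrations are correlated, but the centered
calibration vectors already encode the empirical covariance of the pool, so
no explicit dependency structure is added on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import norm

from .calibration import DescriptiveModel, DiscriminantModel, NoiseModel
from .cohort import SpectralCohort, check_same_grid
from .errors import ValidationError
from .rng import child_rng

__all__ = [
    "ComponentLibrary",
    "SimulationConfig",
    "simulate_descriptive",
    "simulate_case_control",
    "subsample_basis",
    "subsample_basis_pair",
    "simulate_bottom_up",
    "apply_noise",
]

logger = logging.getLogger(__name__)


@dataclass
class ComponentLibrary:
    """Single-component spectra with concentration distributions (bottom-up).

    Each simulated spectrum is ``sum_i c_i * x_i`` with concentrations
    ``c_i ~ N(conc_mu_i, conc_sigma_i^2)`` drawn independently per spectrum.
    """

    wavenumbers: np.ndarray
    component_spectra: np.ndarray  # (M, p)
    conc_mu: np.ndarray
    conc_sigma: np.ndarray
    names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.component_spectra = np.atleast_2d(np.asarray(self.component_spectra, dtype=float))
        self.conc_mu = np.asarray(self.conc_mu, dtype=float)
        self.conc_sigma = np.asarray(self.conc_sigma, dtype=float)
        M, p = self.component_spectra.shape
        if p != self.wavenumbers.size:
            raise ValidationError("component spectra and grid lengths differ")
        if not np.all(np.isfinite(self.component_spectra)):
            raise ValidationError("component spectra must be finite")
        if self.conc_mu.shape != (M,) or self.conc_sigma.shape != (M,):
            raise ValidationError("conc_mu and conc_sigma need one entry per component")
        if np.any(self.conc_sigma < 0):
            raise ValidationError("conc_sigma must be elementwise >= 0")
        if self.names is None:
            self.names = [f"component_{i}" for i in range(M)]
        elif len(self.names) != M:
            raise ValidationError("names needs one entry per component")

    @property
    def M(self) -> int:
        return self.component_spectra.shape[0]


@dataclass
class SimulationConfig:
    """Settings for one simulated case-control cohort.

    ``case_mode`` selects how the case arm is generated: ``"two-pool"`` draws
    from a separately calibrated case model; ``"discriminant"`` adds
    ``delta * d`` to control draws. ``m_subset`` restricts each class's model
    to that many randomly chosen calibration vectors (disjoint between the
    arms); ``pin_beta_sigma`` keeps the full-pool ``beta_sigma`` instead of
    recalibrating to the reduced pool, which holds the strength of biological
    variability constant while its structural complexity changes.
    """

    n_controls: int
    n_cases: int
    beta_scale: float = 1.0
    eps_scale: float = 1.0
    m_subset: Optional[int] = None
    pin_beta_sigma: bool = True
    case_mode: str = "two-pool"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValidationError("cohort sizes must be >= 0")
        if self.n_controls == 0 and self.n_cases == 0:
            raise ValidationError("at least one arm must be non-empty")
        if self.beta_scale < 0 or self.eps_scale < 0:
            raise ValidationError("beta_scale and eps_scale must be >= 0")
        if self.case_mode not in ("two-pool", "discriminant"):
            raise ValidationError(f"unknown case_mode {self.case_mode!r}")


def _draw_descriptive(
    model: DescriptiveModel,
    noise: Optional[NoiseModel],
    n: int,
    beta_scale: float,
    eps_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """mean + beta @ basis + eps, with a fixed draw order for reproducibility."""
    betas = rng.standard_normal((n, model.m)) * (beta_scale * model.beta_sigma)
    spectra = model.mean_spectrum + betas @ model.basis
    if noise is not None and eps_scale > 0:
        spectra = spectra + rng.standard_normal((n, model.p)) * (eps_scale * noise.sigma)
    return spectra


def simulate_descriptive(
    model: DescriptiveModel,
    noise: Optional[NoiseModel],
    n: int,
    beta_scale: float = 1.0,
    eps_scale: float = 1.0,
    seed: int = 0,
    label: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> SpectralCohort:
    """Draw ``n`` spectra from a calibrated descriptive model.

    Each spectrum is ``mean + sum_i beta_i s_i + eps`` with
    ``beta_i ~ N(0, (beta_scale * beta_sigma)^2)`` i.i.d. per spectrum and
    vector, and ``eps_j ~ N(0, (eps_scale * sigma_j)^2)`` per feature.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if beta_scale < 0 or eps_scale < 0:
        raise ValidationError("scales must be >= 0")
    if noise is not None:
        check_same_grid(model, noise)
    rng = child_rng(seed)
    spectra = _draw_descriptive(model, noise, n, beta_scale, eps_scale, rng)
    label = label or model.label
    return SpectralCohort.from_arrays(
        model.wavenumbers,
        spectra,
        label=label,
        id_prefix=id_prefix or label,
        provenance={"generator": "descriptive", "seed": int(seed)},
    )


def subsample_basis(
    model: DescriptiveModel,
    m_subset: int,
    seed: int = 0,
    pin_beta_sigma: bool = False,
    indices: Optional[np.ndarray] = None,
) -> DescriptiveModel:
    """Restrict a model to ``m_subset`` calibration vectors sampled without
    replacement; the mean spectrum is kept unchanged.

    By default ``beta_sigma`` is recalibrated to ``1/sqrt(m_subset - 1)``;
    with ``pin_beta_sigma`` the full-pool value is kept (constant strength of
    biological variability — used by the molecular-complexity sweep).
    ``indices`` overrides the random draw, for paired/disjoint selections.
    """
    if not 2 <= m_subset <= model.m:
        raise ValidationError(f"m_subset must be in [2, {model.m}], got {m_subset}")
    if indices is None:
        indices = child_rng(seed).choice(model.m, size=m_subset, replace=False)
    else:
        indices = np.asarray(indices, dtype=int)
        if indices.size != m_subset or np.unique(indices).size != m_subset:
            raise ValidationError("indices must be m_subset distinct values")
        if indices.min() < 0 or indices.max() >= model.m:
            raise ValidationError("indices out of range of the basis pool")
    beta_sigma = model.beta_sigma if pin_beta_sigma else 1.0 / np.sqrt(m_subset - 1)
    return DescriptiveModel(
        wavenumbers=model.wavenumbers,
        mean_spectrum=model.mean_spectrum,
        basis=model.basis[indices],
        beta_sigma=beta_sigma,
        label=model.label,
        source_indices=model.source_indices[indices],
        recon_residual=None if model.recon_residual is None else model.recon_residual[indices],
    )


def subsample_basis_pair(
    control_model: DescriptiveModel,
    case_model: DescriptiveModel,
    m_subset: int,
    seed: int = 0,
    pin_beta_sigma: bool = True,
) -> Tuple[DescriptiveModel, DescriptiveModel]:
    """Paired subsampling with guaranteed-disjoint source index sets.

    The two reduced models are based on ``2 * m_subset`` distinct source
    indices (first ``m_subset`` for the control pool, next for the case pool),
    so the simulated classes rest on independent sets of calibration vectors.
    """
    pool = min(control_model.m, case_model.m)
    if 2 * m_subset > pool:
        raise ValidationError(
            f"paired subsampling needs 2*m_subset <= pool size ({pool}), got m_subset={m_subset}"
        )
    perm = child_rng(seed).permutation(pool)
    idx_control = perm[:m_subset]
    idx_case = perm[m_subset : 2 * m_subset]
    return (
        subsample_basis(control_model, m_subset, indices=idx_control, pin_beta_sigma=pin_beta_sigma),
        subsample_basis(case_model, m_subset, indices=idx_case, pin_beta_sigma=pin_beta_sigma),
    )


def simulate_case_control(
    control_model: DescriptiveModel,
    case_model_or_discriminant: Union[DescriptiveModel, DiscriminantModel],
    noise: Optional[NoiseModel],
    config: SimulationConfig,
) -> SpectralCohort:
    """Simulate a labelled case-control cohort under one configuration.

    A single root seed governs both arms (and the basis subsampling, when
    ``m_subset`` is set) through fixed child streams, so the whole cohort is
    reproducible from ``(models, noise, config)`` alone.
    """
    case_spec = case_model_or_discriminant
    if case_spec is None:
        raise ValidationError("a case model or discriminant model is required")
    check_same_grid(control_model, case_spec)
    if noise is not None:
        check_same_grid(control_model, noise)

    two_pool = isinstance(case_spec, DescriptiveModel)
    if config.case_mode == "two-pool" and not two_pool:
        raise ValidationError("two-pool mode needs a calibrated case DescriptiveModel")
    if config.case_mode == "discriminant" and two_pool:
        raise ValidationError("discriminant mode needs a DiscriminantModel")

    if config.m_subset is not None:
        if two_pool:
            control_model, case_spec = subsample_basis_pair(
                control_model,
                case_spec,
                config.m_subset,
                seed=config.seed,
                pin_beta_sigma=config.pin_beta_sigma,
            )
        else:
            control_model = subsample_basis(
                control_model,
                config.m_subset,
                seed=config.seed,
                pin_beta_sigma=config.pin_beta_sigma,
            )

    parts = []
    if config.n_controls > 0:
        rng = child_rng(config.seed, 0)
        ctrl = _draw_descriptive(
            control_model, noise, config.n_controls, config.beta_scale, config.eps_scale, rng
        )
        parts.append(
            SpectralCohort.from_arrays(control_model.wavenumbers, ctrl, "control", "control")
        )
    if config.n_cases > 0:
        rng = child_rng(config.seed, 1)
        if two_pool:
            cases = _draw_descriptive(
                case_spec, noise, config.n_cases, config.beta_scale, config.eps_scale, rng
            )
        else:
            cases = _draw_descriptive(
                control_model, noise, config.n_cases, config.beta_scale, config.eps_scale, rng
            )
            deltas = case_spec.delta_mu + case_spec.delta_sigma * rng.standard_normal(
                config.n_cases
            )
            cases = cases + np.outer(deltas, case_spec.d)
        parts.append(
            SpectralCohort.from_arrays(control_model.wavenumbers, cases, "case", "case")
        )
    cohort = SpectralCohort.concat(parts)
    cohort.provenance.update(
        {
            "generator": "case-control",
            "case_mode": config.case_mode,
            "beta_scale": float(config.beta_scale),
            "eps_scale": float(config.eps_scale),
            "m_subset": config.m_subset,
            "seed": int(config.seed),
        }
    )
    return cohort


def simulate_bottom_up(
    library: ComponentLibrary, n: int, seed: int = 0, label: str = "control"
) -> SpectralCohort:
    """Concentration-weighted sums of single-component spectra.

    Concentrations are Gaussian and not truncated at zero, consistent with
    the linear model; a warning is logged when any component's negative-mass
    probability exceeds 1%.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    with np.errstate(divide="ignore"):
        z = np.where(library.conc_sigma > 0, library.conc_mu / library.conc_sigma, np.inf)
    p_neg = norm.cdf(-z)
    if np.any(p_neg > 0.01):
        worst = int(np.argmax(p_neg))
        logger.warning(
            "component %s has %.1f%% probability of a negative concentration",
            library.names[worst],
            100 * p_neg[worst],
        )
    rng = child_rng(seed)
    conc = library.conc_mu + rng.standard_normal((n, library.M)) * library.conc_sigma
    spectra = conc @ library.component_spectra
    return SpectralCohort.from_arrays(
        library.wavenumbers,
        spectra,
        label=label,
        id_prefix=label,
        provenance={"generator": "bottom-up", "seed": int(seed)},
    )


def apply_noise(
    cohort: SpectralCohort, noise: NoiseModel, eps_scale: float = 1.0, seed: int = 0
) -> SpectralCohort:
    """Add per-feature white noise ``N(0, (eps_scale * sigma_j)^2)`` to every
    spectrum; ``eps_scale = 0`` returns the input values unchanged."""
    if eps_scale < 0:
        raise ValidationError("eps_scale must be >= 0")
    check_same_grid(cohort, noise)
    if eps_scale == 0:
        return cohort.select(np.arange(cohort.n))
    rng = child_rng(seed)
    noisy = cohort.absorbance + rng.standard_normal(cohort.absorbance.shape) * (
        eps_scale * noise.sigma
    )
    return SpectralCohort(
        wavenumbers=cohort.wavenumbers,
        absorbance=noisy,
        labels=cohort.labels.copy(),
        sample_ids=cohort.sample_ids.copy(),
        provenance=dict(cohort.provenance),
        label_set=cohort.label_set,
    )
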