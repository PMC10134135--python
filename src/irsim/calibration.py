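"""Calibration of the descriptive generative model and the noise model.

The descriptive approach expresses a spectrum of a molecularly complex sample
as the cohort mean plus a Gaussian-weighted combination of centered
calibration vectors::

    Y = b_bar + sum_i beta_i * s_i,      s_i = b_i - b_bar,
    beta_i ~ N(0, sigma_beta^2),         sigma_beta^2 = 1 / (m - 1)

calibrated from ``m`` experimentally measured spectra ``b_1..b_m`` of one
molecular state. With this choice the model's expected value equals the
cohort mean and its per-feature variance equals the cohort's unbiased sample
variance — an exact algebraic identity, not an asymptotic statement::

    Var(Y_j) = sigma_beta^2 * sum_i s_ij^2 = 1/(m-1) * sum_i (b_ij - b_bar_j)^2

Measurement noise is modeled as an additive white-noise vector with
per-wavenumber standard deviations estimated from replicate blank (water)
measurements. Class differences are represented either by a separately
calibrated case model (two-pool) or by a single discriminant vector
``d = mean(cases) - mean(controls)`` scaled by a Gaussian coefficient
``delta(mu_d, sigma_d)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import SpectralCohort, check_same_grid
from .errors import CalibrationError, ValidationError

__all__ = [
    "DescriptiveModel",
    "NoiseModel",
    "DiscriminantModel",
    "calibrate_descriptive",
    "calibrate_noise",
    "estimate_discriminant",
]


@dataclass
class DescriptiveModel:
    """Calibrated generative model of one molecular state.

    :meth:`reconstruct` rebuilds every calibration spectrum bit-for-bit from
    ``mean_spectrum`` and ``basis``; the basis rows sum to zero (centering
    identity).
    """

    wavenumbers: np.ndarray
    mean_spectrum: np.ndarray
    basis: np.ndarray  # (m, p) centered calibration vectors
    beta_sigma: float
    label: str = "control"
    #: indices of the basis rows in the pool they were drawn from (provenance
    #: for subsampling; identity range after calibration)
    source_indices: Optional[np.ndarray] = None
    #: ulp-level compensation for exact reconstruction: a single IEEE add
    #: ``mean + basis[i]`` cannot represent every calibration spectrum (near
    #: cancellation the achievable sums are quantized coarser than the
    #: target), so the exact residual of that add is kept and re-added by
    #: :meth:`reconstruct`. Entries are bounded by one ulp of the spectrum.
    recon_residual: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        if self.mean_spectrum.shape != self.wavenumbers.shape:
            raise ValidationError("mean_spectrum and grid lengths differ")
        if self.basis.shape[1] != self.wavenumbers.size:
            raise ValidationError("basis and grid lengths differ")
        if not np.isfinite(self.beta_sigma) or self.beta_sigma < 0:
            raise ValidationError("beta_sigma must be finite and >= 0")
        if self.source_indices is None:
            self.source_indices = np.arange(self.basis.shape[0])
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=int)

    @property
    def m(self) -> int:
        """Number of calibration vectors (the molecular-complexity parameter)."""
        return self.basis.shape[0]

    @property
    def p(self) -> int:
        return self.basis.shape[1]

    def implied_variance(self) -> np.ndarray:
        """Model-implied per-feature variance, ``beta_sigma^2 * sum_i s_ij^2``."""
        return self.beta_sigma**2 * np.sum(self.basis**2, axis=0)

    def reconstruct(self) -> np.ndarray:
        """``mean_spectrum + basis``, compensated: equals the calibrating
        spectra bit-for-bit for a freshly calibrated model."""
        recon = self.mean_spectrum + self.basis
        if self.recon_residual is not None:
            recon = recon + self.recon_residual
        return recon


@dataclass
class NoiseModel:
    """Additive white measurement noise, per-wavenumber standard deviations."""

    wavenumbers: np.ndarray
    sigma: np.ndarray
    n_replicates: int = 0

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != self.wavenumbers.shape:
            raise ValidationError("sigma and grid lengths differ")
        if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma < 0):
            raise ValidationError("noise sigma must be finite and elementwise >= 0")

    @property
    def p(self) -> int:
        return self.sigma.size


@dataclass
class DiscriminantModel:
    """Single-vector class-difference model.

    A case spectrum is a control draw plus ``delta * d`` with
    ``delta ~ N(delta_mu, delta_sigma^2)``. How the delta parameters should be
    calibrated is application-specific; the defaults ``delta_mu = 1``,
    ``delta_sigma = 0`` apply the estimated mean difference deterministically.
    """

    wavenumbers: np.ndarray
    d: np.ndarray
    delta_mu: float = 1.0
    delta_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != self.wavenumbers.shape:
            raise ValidationError("d and grid lengths differ")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("d must be finite")
        if self.delta_sigma < 0:
            raise ValidationError("delta_sigma must be >= 0")


def _single_state(cohort: SpectralCohort) -> str:
    states = sorted(set(map(str, cohort.labels)))
    if len(states) != 1:
        raise CalibrationError(
            f"cohort mixes labels {states}; calibrate one molecular state at a time"
        )
    return states[0]


def calibrate_descriptive(cohort: SpectralCohort) -> DescriptiveModel:
    """Calibrate the descriptive model on ``m >= 2`` spectra of one state.

    Returns the model with ``mean_spectrum`` the arithmetic mean, ``basis``
    the centered spectra, and ``beta_sigma = 1/sqrt(m - 1)`` so that the
    model-implied per-feature variance equals the cohort's unbiased (ddof=1)
    sample variance exactly.
    """
    label = _single_state(cohort)
    m = cohort.n
    if m < 2:
        raise CalibrationError(
            f"calibration needs at least 2 spectra, got {m}; "
            "the between-sample variability is otherwise undefined"
        )
    mean = cohort.absorbance.mean(axis=0)
    basis = cohort.absorbance - mean
    # exact-reconstruction contract: (mean + basis) + residual == spectra
    # bit-for-bit. The residual of the add is exactly representable
    # (Sterbenz: the rounded sum lies within ulps of the target).
    residual = cohort.absorbance - (mean + basis)
    return DescriptiveModel(
        wavenumbers=cohort.wavenumbers,
        mean_spectrum=mean,
        basis=basis,
        beta_sigma=1.0 / np.sqrt(m - 1),
        label=label,
        recon_residual=residual if residual.any() else None,
    )


def calibrate_noise(blanks: SpectralCohort) -> NoiseModel:
    """Per-wavenumber noise standard deviation from replicate blanks (ddof=1)."""
    if blanks.n < 2:
        raise CalibrationError(
            f"noise calibration needs at least 2 replicate blanks, got {blanks.n}"
        )
    sigma = blanks.absorbance.std(axis=0, ddof=1)
    return NoiseModel(wavenumbers=blanks.wavenumbers, sigma=sigma, n_replicates=blanks.n)


def estimate_discriminant(
    cases: SpectralCohort,
    controls: SpectralCohort,
    delta_mu: float = 1.0,
    delta_sigma: float = 0.0,
) -> DiscriminantModel:
    """Differential fingerprint ``d = mean(cases) - mean(controls)``."""
    check_same_grid(cases, controls)
    d = cases.absorbance.mean(axis=0) - controls.absorbance.mean(axis=0)
    return DiscriminantModel(
        wavenumbers=cases.wavenumbers, d=d, delta_mu=delta_mu, delta_sigma=delta_sigma
    )
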