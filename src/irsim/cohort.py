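"""The in-memory container for spectral cohorts.

A :class:`SpectralCohort` holds ``n`` absorbance spectra measured on a shared,
strictly increasing wavenumber grid (cm^-1), with one class label and one
unique sample identifier per spectrum. Absorbance is dimensionless; no
non-negativity is imposed (centered and simulated spectra may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import GridMismatchError, ValidationError

__all__ = ["SpectralCohort", "check_same_grid"]

#: labels understood by the pipeline; cohorts may declare others explicitly
DEFAULT_LABEL_SET = ("control", "case", "blank")


@dataclass
class SpectralCohort:
    """n spectra on a common wavenumber grid with labels and metadata.

    Parameters
    ----------
    wavenumbers : (p,) array
        Strictly increasing grid in cm^-1.
    absorbance : (n, p) array
        One spectrum per row, absorbance units.
    labels : (n,) array of str
        Class tag per spectrum, drawn from ``label_set``.
    sample_ids : (n,) array of str
        Unique identifiers.
    provenance : dict
        Free-text metadata carried through io round trips.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    provenance: dict = field(default_factory=dict)
    label_set: tuple = DEFAULT_LABEL_SET

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.wavenumbers.ndim != 1:
            raise ValidationError("wavenumbers must be a 1-D grid")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("wavenumber grid must be strictly increasing")
        n, p = self.absorbance.shape
        if n < 1:
            raise ValidationError("a cohort needs at least one spectrum")
        if p != self.wavenumbers.size:
            raise ValidationError(
                f"absorbance has {p} features but the grid has {self.wavenumbers.size}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance values must all be finite")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("wavenumber grid must be finite")
        if self.labels.shape != (n,) or self.sample_ids.shape != (n,):
            raise ValidationError("labels and sample_ids must have one entry per spectrum")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad = set(map(str, self.labels)) - set(self.label_set)
        if bad:
            raise ValidationError(
                f"labels {sorted(bad)} outside declared label set {list(self.label_set)}"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return self.absorbance.shape[0]

    @property
    def p(self) -> int:
        return self.absorbance.shape[1]

    def label_counts(self) -> dict:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    # -- subsetting ----------------------------------------------------------
    def select(self, mask_or_index) -> "SpectralCohort":
        """Row subset preserving grid and metadata."""
        idx = np.asarray(mask_or_index)
        return SpectralCohort(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            provenance=dict(self.provenance),
            label_set=self.label_set,
        )

    def with_label(self, label: str) -> "SpectralCohort":
        mask = self.labels.astype(str) == label
        if not mask.any():
            raise ValidationError(f"cohort has no spectra labelled {label!r}")
        return self.select(mask)

    # -- construction --------------------------------------------------------
    @staticmethod
    def concat(cohorts: Iterable["SpectralCohort"]) -> "SpectralCohort":
        cohorts = list(cohorts)
        if not cohorts:
            raise ValidationError("cannot concatenate zero cohorts")
        first = cohorts[0]
        for c in cohorts[1:]:
            check_same_grid(first, c)
        provenance: dict = {}
        for c in cohorts:
            provenance.update(c.provenance)
        label_set = tuple(dict.fromkeys(l for c in cohorts for l in c.label_set))
        return SpectralCohort(
            wavenumbers=first.wavenumbers,
            absorbance=np.vstack([c.absorbance for c in cohorts]),
            labels=np.concatenate([c.labels for c in cohorts]),
            sample_ids=np.concatenate([c.sample_ids for c in cohorts]),
            provenance=provenance,
            label_set=label_set,
        )

    @staticmethod
    def from_arrays(
        wavenumbers,
        absorbance,
        label: str,
        id_prefix: str,
        provenance: Mapping | None = None,
    ) -> "SpectralCohort":
        """Build a single-label cohort with generated sample ids."""
        absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
        n = absorbance.shape[0]
        width = max(4, len(str(n)))
        ids = np.array([f"{id_prefix}_{i:0{width}d}" for i in range(n)], dtype=object)
        return SpectralCohort(
            wavenumbers=wavenumbers,
            absorbance=absorbance,
            labels=np.array([label] * n, dtype=object),
            sample_ids=ids,
            provenance=dict(provenance or {}),
        )


def check_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless grids are bit-identical.

    Strict equality is deliberate: no resampling or interpolation is performed
    anywhere in the package, which keeps calibration bit-reproducible.
    """
    ga = np.asarray(getattr(a, "wavenumbers", a), dtype=float)
    gb = np.asarray(getattr(b, "wavenumbers", b), dtype=float)
    if ga.shape != gb.shape or not np.array_equal(ga, gb):
        raise GridMismatchError(
            f"wavenumber grids differ (lengths {ga.size} vs {gb.size}); "
            "resampling is not performed — align grids upstream"
        )
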