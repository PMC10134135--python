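"""Readers and writers for cohorts, model archives and result reports.

Cohorts travel as a wide delimited CSV — header row ``sample_id`` followed by
the wavenumber values in cm^-1, one row per spectrum — with a JSON sidecar
(``<stem>.meta.json``) keyed by sample id for labels and provenance. Floats
are written with ``repr`` precision, so a write→read round trip is lossless.
All writes are atomic (temp file + rename in the target directory).

Calibrated models are serialized into a single ``.npz`` archive whose layout
is documented in :func:`save_model_archive`. Classification and sweep results
are written as a schema-versioned JSON report plus tidy CSV tables.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calibration import DescriptiveModel, DiscriminantModel, NoiseModel
from .classification import ClassificationResult
from .cohort import SpectralCohort
from .errors import ValidationError
from .experiments import SweepResult

__all__ = [
    "read_cohort",
    "write_cohort",
    "sidecar_path",
    "save_model_archive",
    "load_model_archive",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# atomic write helpers
# ---------------------------------------------------------------------------


def _atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_bytes(path: Path, writer) -> None:
    """Call ``writer(tmp_path)`` then rename onto ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def sidecar_path(csv_path: Union[str, Path]) -> Path:
    """Metadata sidecar next to a cohort CSV: ``<stem>.meta.json``."""
    csv_path = Path(csv_path)
    return csv_path.with_name(csv_path.stem + ".meta.json")


def write_cohort(cohort: SpectralCohort, path: Union[str, Path]) -> Path:
    """Write the wide CSV and its JSON sidecar; returns the CSV path."""
    path = Path(path)
    header = "sample_id," + ",".join(repr(float(w)) for w in cohort.wavenumbers)
    lines = [header]
    for sid, row in zip(cohort.sample_ids, cohort.absorbance):
        lines.append(str(sid) + "," + ",".join(repr(float(v)) for v in row))
    _atomic_write_text(path, "\n".join(lines) + "\n")

    meta = {
        "schema_version": SCHEMA_VERSION,
        "label_set": list(cohort.label_set),
        "labels": {str(s): str(l) for s, l in zip(cohort.sample_ids, cohort.labels)},
        "provenance": cohort.provenance,
    }
    _atomic_write_text(sidecar_path(path), json.dumps(meta, indent=1, default=str))
    return path


def read_cohort(path: Union[str, Path]) -> SpectralCohort:
    """Load a cohort CSV + sidecar written by :func:`write_cohort`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    side = sidecar_path(path)
    if not side.exists():
        raise ValidationError(f"missing metadata sidecar: {side}")
    try:
        frame = pd.read_csv(path, header=0, dtype={0: str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse cohort CSV {path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0] != "sample_id":
        raise ValidationError(f"{path}: first column must be 'sample_id'")
    try:
        wavenumbers = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric wavenumber header column ({exc})") from exc
    if np.any(np.diff(wavenumbers) <= 0):
        raise ValidationError(f"{path}: wavenumber header must be strictly increasing")
    sample_ids = frame["sample_id"].astype(str).to_numpy()
    dup = pd.Series(sample_ids).duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate sample_id {sample_ids[dup.idxmax()]!r}")
    values = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    absorbance = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(absorbance)):
        row = int(np.argwhere(~np.isfinite(absorbance))[0][0])
        raise ValidationError(
            f"{path}: non-numeric or missing absorbance value in record {sample_ids[row]!r}"
        )
    meta = json.loads(side.read_text())
    label_map = meta.get("labels", {})
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValidationError(f"{side}: no label for sample_id {missing[0]!r}")
    labels = np.array([label_map[s] for s in sample_ids], dtype=object)
    return SpectralCohort(
        wavenumbers=wavenumbers,
        absorbance=absorbance,
        labels=labels,
        sample_ids=sample_ids.astype(object),
        provenance=meta.get("provenance", {}),
        label_set=tuple(meta.get("label_set", sorted(set(map(str, labels))))),
    )


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------


def save_model_archive(
    path: Union[str, Path],
    control: Optional[DescriptiveModel] = None,
    case: Optional[DescriptiveModel] = None,
    noise: Optional[NoiseModel] = None,
    discriminant: Optional[DiscriminantModel] = None,
) -> Path:
    """Serialize calibrated models into one ``.npz`` archive.

    Layout: ``wavenumbers``; per descriptive model a ``<role>_mean``,
    ``<role>_basis`` and ``<role>_source_indices``; ``noise_sigma``;
    ``discriminant_d``; and a ``meta`` JSON string holding scalars
    (``beta_sigma`` per model, ``delta_mu``/``delta_sigma``, replicate count,
    labels, schema version).
    """
    path = Path(path)
    models = {"control": control, "case": case}
    grids = [m.wavenumbers for m in (control, case, noise, discriminant) if m is not None]
    if not grids:
        raise ValidationError("nothing to save: all models are None")
    arrays = {"wavenumbers": grids[0]}
    meta: dict = {"schema_version": SCHEMA_VERSION, "descriptive": {}}
    for role, model in models.items():
        if model is None:
            continue
        arrays[f"{role}_mean"] = model.mean_spectrum
        arrays[f"{role}_basis"] = model.basis
        arrays[f"{role}_source_indices"] = model.source_indices
        meta["descriptive"][role] = {
            "beta_sigma": float(model.beta_sigma),
            "m": int(model.m),
            "label": model.label,
        }
    if noise is not None:
        arrays["noise_sigma"] = noise.sigma
        meta["noise"] = {"n_replicates": int(noise.n_replicates)}
    if discriminant is not None:
        arrays["discriminant_d"] = discriminant.d
        meta["discriminant"] = {
            "delta_mu": float(discriminant.delta_mu),
            "delta_sigma": float(discriminant.delta_sigma),
        }
    arrays["meta"] = np.array(json.dumps(meta))

    def _write(tmp):
        with open(tmp, "wb") as fh:  # file handle: keeps numpy from renaming to *.npz
            np.savez(fh, **arrays)

    _atomic_write_bytes(path, _write)
    return path


def load_model_archive(path: Union[str, Path]) -> dict:
    """Load an archive written by :func:`save_model_archive`.

    Returns a dict with keys among ``control``, ``case``, ``noise``,
    ``discriminant`` and always ``wavenumbers``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"model archive not found: {path}")
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        wn = data["wavenumbers"]
        out: dict = {"wavenumbers": wn}
        for role, info in meta.get("descriptive", {}).items():
            out[role] = DescriptiveModel(
                wavenumbers=wn,
                mean_spectrum=data[f"{role}_mean"],
                basis=data[f"{role}_basis"],
                beta_sigma=info["beta_sigma"],
                label=info["label"],
                source_indices=data[f"{role}_source_indices"],
            )
        if "noise" in meta:
            out["noise"] = NoiseModel(
                wavenumbers=wn,
                sigma=data["noise_sigma"],
                n_replicates=meta["noise"]["n_replicates"],
            )
        if "discriminant" in meta:
            out["discriminant"] = DiscriminantModel(
                wavenumbers=wn,
                d=data["discriminant_d"],
                delta_mu=meta["discriminant"]["delta_mu"],
                delta_sigma=meta["discriminant"]["delta_sigma"],
            )
    return out


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(
    result: Union[ClassificationResult, SweepResult], path: Union[str, Path]
) -> Path:
    """Write a result as a JSON report (plus CSV tables for sweeps).

    ``path`` is the JSON report path; a :class:`SweepResult` additionally
    writes ``<stem>_cells.csv`` and ``<stem>_folds.csv`` next to it, and a
    :class:`ClassificationResult` writes ``<stem>_roc.csv``.
    """
    path = Path(path)
    if isinstance(result, ClassificationResult):
        report = {
            "schema_version": SCHEMA_VERSION,
            "kind": "classification",
            "fold_aucs": [float(a) for a in result.fold_aucs],
            "mean_auc": float(result.mean_auc),
            "std_auc": float(result.std_auc),
            "config_digest": result.config_digest,
            "settings": result.settings,
        }
        _atomic_write_text(path, json.dumps(report, indent=1, default=str))
        roc = pd.DataFrame(result.roc_points, columns=["fpr", "tpr"])
        _atomic_write_bytes(
            path.with_name(path.stem + "_roc.csv"), lambda tmp: roc.to_csv(tmp, index=False)
        )
    elif isinstance(result, SweepResult):
        report = {
            "schema_version": SCHEMA_VERSION,
            "kind": "sweep",
            "axes": result.axes,
            "settings": result.settings,
            "cells": result.cells.to_dict(orient="records"),
        }
        _atomic_write_text(path, json.dumps(report, indent=1, default=str))
        _atomic_write_bytes(
            path.with_name(path.stem + "_cells.csv"),
            lambda tmp: result.cells.to_csv(tmp, index=False),
        )
        _atomic_write_bytes(
            path.with_name(path.stem + "_folds.csv"),
            lambda tmp: result.folds.to_csv(tmp, index=False),
        )
    else:
        raise ValidationError(f"cannot serialize result of type {type(result).__name__}")
    return path


def read_results(path: Union[str, Path]) -> dict:
    """Load a JSON report written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"report not found: {path}")
    report = json.loads(path.read_text())
    if "schema_version" not in report:
        raise ValidationError(f"{path}: missing schema_version stamp")
    return report
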