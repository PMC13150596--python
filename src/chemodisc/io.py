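"""Labelled spectral matrices: the dataset container and its CSV round-trip.

A :class:`SpectralDataset` holds replicate absorbance spectra on a common,
strictly monotone axis (wavelength in nm for UV-vis, wavenumber in cm^-1 for
FTIR -- the latter conventionally stored descending, 1800 -> 600).  Every row
carries a sample id, a replicate id and a class label; all multivariate
stages operate on this container.

The on-disk format is plain CSV: first row is the numeric axis, first three
columns are ``sample_id``, ``replicate_id`` and ``class``.  Only the
comma-separator / dot-decimal dialect is accepted; locale variants are
rejected rather than guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "SpectralFormatError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "average_replicates",
]

_LABEL_COLUMNS = ("sample_id", "replicate_id", "class")


class SpectralFormatError(ValueError):
    """Raised when a spectral CSV file does not parse as the expected dialect."""


class ValidationError(ValueError):
    """Raised when dataset content violates the container's invariants."""


def _check_monotone(axis: np.ndarray) -> bool:
    """Return True for ascending axes, False for descending; raise otherwise."""
    d = np.diff(axis)
    if axis.size >= 2 and np.all(d > 0):
        return True
    if axis.size >= 2 and np.all(d < 0):
        return False
    if axis.size < 2:
        raise ValidationError("axis needs at least 2 points")
    raise ValidationError("axis must be strictly monotone (either direction)")


@dataclass
class SpectralDataset:
    """Matrix of labelled spectra on a common monotone axis.

    Parameters
    ----------
    axis
        Strictly monotone grid, ascending (nm) or descending (cm^-1).
    intensities
        Absorbance matrix, one row per replicate spectrum, ``(n, len(axis))``.
    sample_ids, replicate_ids, classes
        Per-row labels; ``classes`` must contain at most two distinct values
        for supervised stages.
    modality
        Free tag, conventionally ``"uv"`` or ``"ftir"``.
    metadata
        Provenance dict (preprocessing history, generator config, ...).
    """

    axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    replicate_ids: list[int]
    classes: list[str]
    modality: str = "uv"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.replicate_ids = [int(r) for r in self.replicate_ids]
        self.classes = [str(c) for c in self.classes]
        n = self.intensities.shape[0]
        if self.intensities.size == 0 and n <= 1 and not self.sample_ids:
            # explicit empty dataset (0 rows) keeps a (0, p) shape
            self.intensities = self.intensities.reshape(0, self.axis.size)
            n = 0
        if not (len(self.sample_ids) == len(self.replicate_ids) == len(self.classes) == n):
            raise ValidationError(
                f"row labels ({len(self.sample_ids)}) do not match intensity rows ({n})"
            )
        if n and self.intensities.shape[1] != self.axis.size:
            raise ValidationError(
                f"intensities have {self.intensities.shape[1]} columns "
                f"but axis has {self.axis.size} points"
            )
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensities)):
            raise ValidationError("axis/intensities contain non-finite values")
        self.ascending = _check_monotone(self.axis)

    # -- convenience ------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.classes))

    def require_two_classes(self) -> tuple[str, str]:
        labels = self.class_labels
        if len(labels) != 2:
            raise ValidationError(
                f"supervised stage requires exactly 2 classes, found {labels}"
            )
        return labels[0], labels[1]

    def class_vector(self) -> np.ndarray:
        return np.asarray(self.classes)

    def with_intensities(self, intensities: np.ndarray, **meta) -> "SpectralDataset":
        """Copy with replaced intensity matrix and merged metadata."""
        new = replace(self, intensities=np.asarray(intensities, dtype=float))
        new.metadata = {**self.metadata, **meta}
        return new

    def subset_rows(self, indices) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            intensities=self.intensities[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            replicate_ids=[self.replicate_ids[i] for i in idx],
            classes=[self.classes[i] for i in idx],
        )

    def subset_columns(self, indices) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(self, axis=self.axis[idx], intensities=self.intensities[:, idx])


# -- CSV round-trip -------------------------------------------------------


def write_dataset(ds: SpectralDataset, path) -> None:
    """Write ``ds`` as CSV: axis header row, label columns, full precision."""
    path = Path(path)
    df = pd.DataFrame(ds.intensities, columns=[repr(float(v)) for v in ds.axis])
    df.insert(0, "class", ds.classes)
    df.insert(0, "replicate_id", ds.replicate_ids)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"modality": ds.modality, **ds.metadata}, indent=2, default=str))


def read_dataset(path, modality: str | None = None) -> SpectralDataset:
    """Read a spectral CSV written in the dialect of :func:`write_dataset`.

    The first row must contain the three label-column names followed by the
    numeric axis; every axis cell must parse as a float with a dot decimal.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, dtype={"sample_id": str, "class": str}, float_precision="round_trip"
        )
    except Exception as exc:  # ragged rows, encoding, ...
        raise SpectralFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SpectralFormatError(f"{path}: missing label columns {missing}")
    axis_cols = [c for c in df.columns if c not in _LABEL_COLUMNS]
    axis = np.empty(len(axis_cols))
    for j, col in enumerate(axis_cols):
        try:
            axis[j] = float(col)
        except ValueError as exc:
            raise SpectralFormatError(
                f"{path}: non-numeric axis header {col!r} (column {j + 4})"
            ) from exc
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: empty dataset (header only)")
    body = df[axis_cols]
    if body.isna().any().any() or not all(np.issubdtype(t, np.number) for t in body.dtypes):
        bad = next(c for c in axis_cols
                   if body[c].isna().any() or not np.issubdtype(body[c].dtype, np.number))
        raise SpectralFormatError(f"{path}: non-numeric or missing cell in column {bad!r}")

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    mod = modality or meta.pop("modality", None) or "uv"
    meta.pop("modality", None)
    return SpectralDataset(
        axis=axis,
        intensities=body.to_numpy(dtype=float),
        sample_ids=list(df["sample_id"]),
        replicate_ids=[int(r) for r in df["replicate_id"]],
        classes=list(df["class"]),
        modality=mod,
        metadata=meta,
    )


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Collapse replicates to one mean spectrum per sample id.

    Row order is the first-appearance order of sample ids; replicate ids are
    reset to 0.  A sample id mapped to more than one class label is a
    labelling error and is rejected.
    """
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    sample_class: dict[str, str] = {}
    for i, (sid, cls) in enumerate(zip(ds.sample_ids, ds.classes)):
        if sid not in rows:
            rows[sid] = []
            order.append(sid)
            sample_class[sid] = cls
        elif sample_class[sid] != cls:
            raise ValidationError(
                f"sample {sid!r} carries conflicting class labels "
                f"({sample_class[sid]!r} vs {cls!r})"
            )
        rows[sid].append(i)
    intensities = np.vstack([ds.intensities[rows[sid]].mean(axis=0) for sid in order])
    return SpectralDataset(
        axis=ds.axis,
        intensities=intensities,
        sample_ids=order,
        replicate_ids=[0] * len(order),
        classes=[sample_class[sid] for sid in order],
        modality=ds.modality,
        metadata={**ds.metadata, "replicates_averaged": True},
    )
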