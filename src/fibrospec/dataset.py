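"""The :class:`SpectrumSet` container and its CSV round-trip.

A spectrum set is the object every pipeline stage consumes and emits: a
shared ascending wavenumber axis, an absorbance matrix (one row per
measurement) and per-row metadata (sample id, replicate number, class
label).  The on-disk format is a plain wide CSV whose first three columns
are ``sample_id,replicate,label`` followed by one numeric column per
wavenumber, which is how most FTIR instrument software exports tables
(often with the axis descending — the reader reorders to ascending).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, SpectraFormatError

_META_COLUMNS = ("sample_id", "replicate", "label")

CASE = "case"
CONTROL = "control"


@dataclass
class SpectrumSet:
    """Wavenumber axis + absorbance matrix + per-row metadata.

    Parameters
    ----------
    axis
        Strictly increasing wavenumbers in cm^-1, shape ``(p,)``.
    absorbance
        Absorbance in AU, shape ``(n, p)``; all entries finite.
    sample_id
        Integer subject identifier per row, shape ``(n,)``.
    replicate
        Replicate measurement number per row (>= 1), shape ``(n,)``.
    label
        Class label per row: ``"case"``, ``"control"`` or ``""`` for
        unlabelled data.
    """

    axis: np.ndarray
    absorbance: np.ndarray
    sample_id: np.ndarray
    replicate: np.ndarray
    label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_id = np.asarray(self.sample_id, dtype=int)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if self.label is None:
            self.label = np.full(self.n_rows, "", dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        self._validate()

    def _validate(self) -> None:
        if self.axis.ndim != 1:
            raise DataIntegrityError("axis must be one-dimensional")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise DataIntegrityError("axis must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.axis.size:
            raise DataIntegrityError(
                f"absorbance has {p} columns but axis has {self.axis.size} points"
            )
        for name in ("sample_id", "replicate", "label"):
            if getattr(self, name).shape != (n,):
                raise DataIntegrityError(f"{name} must have one entry per row")
        if not np.all(np.isfinite(self.absorbance)):
            raise DataIntegrityError("absorbance contains non-finite values")
        if np.any(self.replicate < 1):
            raise DataIntegrityError("replicate numbers must be >= 1")
        pairs = list(zip(self.sample_id.tolist(), self.replicate.tolist()))
        if len(pairs) != len(set(pairs)):
            raise DataIntegrityError("duplicated (sample_id, replicate) pair")

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def take(self, rows) -> "SpectrumSet":
        """Row subset (new object; metadata carried along)."""
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(
            axis=self.axis.copy(),
            absorbance=self.absorbance[rows],
            sample_id=self.sample_id[rows],
            replicate=self.replicate[rows],
            label=self.label[rows],
        )

    def with_absorbance(self, absorbance: np.ndarray, axis: np.ndarray | None = None) -> "SpectrumSet":
        """Same metadata, new matrix (and optionally a new axis)."""
        return replace(
            self,
            absorbance=np.asarray(absorbance, dtype=float),
            axis=self.axis.copy() if axis is None else np.asarray(axis, dtype=float),
        )


def read_spectra_csv(path) -> SpectrumSet:
    """Read a wide-format spectra CSV.

    The header must be ``sample_id,replicate,label`` followed by numeric
    wavenumber columns.  Files with a descending axis (the common FTIR
    export convention) are reordered to the internal ascending convention.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"label": str}, keep_default_na=False, float_precision="round_trip"
    )
    header = list(df.columns)
    if tuple(header[:3]) != _META_COLUMNS:
        raise SpectraFormatError(
            f"{path}: header must start with {','.join(_META_COLUMNS)}; "
            f"got {','.join(header[:3]) if header else '(empty)'}"
        )
    wn_names = header[3:]
    try:
        axis = np.array([float(c) for c in wn_names])
    except ValueError:
        bad = next(c for c in wn_names if not _is_number(c))
        raise SpectraFormatError(f"{path}: non-numeric wavenumber column {bad!r}") from None
    if wn_names == []:
        raise SpectraFormatError(f"{path}: no wavenumber columns")

    spectral = df[wn_names]
    numeric = spectral.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any() and len(df):
        r, c = np.argwhere(numeric.isna().values)[0]
        raise SpectraFormatError(
            f"{path}: non-numeric absorbance at row {r + 1}, column {wn_names[c]!r}"
        )
    try:
        sample_id = df["sample_id"].astype(int).to_numpy()
        repl = df["replicate"].astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SpectraFormatError(f"{path}: non-integer sample_id/replicate: {exc}") from None

    order = np.argsort(axis, kind="stable")
    return SpectrumSet(
        axis=axis[order],
        absorbance=numeric.to_numpy(dtype=float).reshape(len(df), len(wn_names))[:, order],
        sample_id=sample_id,
        replicate=repl,
        label=df["label"].to_numpy(dtype=object),
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Write a :class:`SpectrumSet` in the format read_spectra_csv expects.

    Absorbances are written with 17 significant digits so the round trip
    is lossless up to float formatting.
    """
    df = pd.DataFrame(
        {
            "sample_id": spectra.sample_id,
            "replicate": spectra.replicate,
            "label": spectra.label,
        }
    )
    spec_df = pd.DataFrame(
        spectra.absorbance, columns=[_format_wavenumber(w) for w in spectra.axis]
    )
    pd.concat([df, spec_df], axis=1).to_csv(path, index=False, float_format="%.17g")


def _format_wavenumber(w: float) -> str:
    return f"{w:g}"


def average_replicates(spectra: SpectrumSet) -> SpectrumSet:
    """Collapse replicate measurements to one mean spectrum per sample.

    Each sample's rows are averaged arithmetically; the output carries one
    row per sample id (in order of first appearance) with ``replicate=1``.
    A sample carrying conflicting class labels is a data-integrity error.
    Idempotent: averaging an already-averaged set is the identity.
    """
    ids = spectra.sample_id
    _, first_pos = np.unique(ids, return_index=True)
    ordered_ids = ids[np.sort(first_pos)]
    rows, labels = [], []
    for sid in ordered_ids:
        mask = ids == sid
        lab = set(spectra.label[mask].tolist())
        if len(lab) > 1:
            raise DataIntegrityError(
                f"sample {sid} carries conflicting labels {sorted(lab)}"
            )
        rows.append(spectra.absorbance[mask].mean(axis=0))
        labels.append(lab.pop())
    return SpectrumSet(
        axis=spectra.axis.copy(),
        absorbance=np.array(rows).reshape(len(ordered_ids), spectra.n_points),
        sample_id=ordered_ids,
        replicate=np.ones(len(ordered_ids), dtype=int),
        label=np.array(labels, dtype=object),
    )
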