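"""Spectral marker bands and their tentative biochemical assignments.

The packaged table lists the 24 plasma wavenumbers found discriminant for
fibromyalgia vs. control, each with the tentative assignment conventional
in biofluid IR work (``v`` = stretching, ``d`` = bending vibration).  The
bands span phosphodiester/phosphate and carbohydrate absorptions
(943-1,192 cm^-1), Amide III, CH deformations and lipid bands
(1,319-1,477 cm^-1), and the protein Amide II/I region (1,545-1,668 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import DataIntegrityError

_FINGERPRINT_LO = 900.0
_FINGERPRINT_HI = 1800.0


@dataclass(frozen=True)
class MarkerTable:
    """Mapping from marker wavenumber (cm^-1) to assignment text."""

    entries: dict

    def __post_init__(self) -> None:
        wn = list(self.entries)
        if len(wn) != len(set(wn)):
            raise DataIntegrityError("marker wavenumbers must be unique")
        out = [w for w in wn if not _FINGERPRINT_LO <= w <= _FINGERPRINT_HI]
        if out:
            raise DataIntegrityError(f"marker wavenumbers outside fingerprint region: {out}")

    @property
    def wavenumbers(self) -> list:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def load_marker_table() -> MarkerTable:
    """Load the packaged 24-band marker table."""
    with resources.files("fibrospec.data").joinpath("marker_bands.csv").open() as fh:
        df = pd.read_csv(fh)
    return MarkerTable(entries=dict(zip(df["wavenumber"].astype(float), df["assignment"])))


def assign_markers(wavenumbers, table: MarkerTable | None = None, tolerance: float = 4.0):
    """Match query wavenumbers to the nearest marker band within a tolerance.

    Parameters
    ----------
    wavenumbers
        Query positions in cm^-1 (e.g. GA-selected variables).
    table
        Marker table; defaults to the packaged 24-band table.
    tolerance
        Maximum |query - band| in cm^-1 for a match (default 4, one
        acquisition-resolution step).

    Returns
    -------
    list of (wavenumber, assignment-or-None) in query order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if table is None:
        table = load_marker_table()
    bands = sorted(table.entries)
    out = []
    for q in wavenumbers:
        best = min(bands, key=lambda b: (abs(b - q), b))
        out.append((q, table.entries[best] if abs(best - q) <= tolerance else None))
    return out
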