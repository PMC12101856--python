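"""Shared spectral data container and its on-disk CSV dialect.

A :class:`SpectrumSet` bundles a common wavenumber grid, an intensity matrix
(one row per recorded spectrum) and per-spectrum metadata (group label,
sampling time and the known hormone concentrations in ng/ml).  Every other
module consumes and produces this container.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Metadata columns required on every SpectrumSet.
METADATA_COLUMNS = ("spectrum_id", "group", "time_h", "gh_ng_ml", "te_ng_ml")


@dataclasses.dataclass
class SpectrumSet:
    """A set of spectra sharing one strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumbers:
        Shared grid in cm^-1, shape ``(n_channels,)``, strictly increasing.
    intensities:
        Intensity matrix in arbitrary units, shape ``(n_spectra, n_channels)``.
    metadata:
        One row per spectrum with at least the columns in
        :data:`METADATA_COLUMNS`.  Extra columns (e.g. a rat identifier) are
        preserved.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} channels, "
                f"grid has {self.wavenumbers.size}"
            )
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if len(self.metadata) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(self.metadata)} metadata rows for "
                f"{self.intensities.shape[0]} spectra"
            )
        conc = self.metadata[["gh_ng_ml", "te_ng_ml"]].to_numpy(dtype=float)
        if np.any(conc < 0):
            raise ValueError("metadata contains negative concentrations")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    def select(self, mask) -> "SpectrumSet":
        """Subset by boolean mask or integer index array over spectra."""
        mask = np.asarray(mask)
        return SpectrumSet(
            self.wavenumbers,
            self.intensities[mask],
            self.metadata.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """Copy with a replaced intensity matrix (same grid and metadata)."""
        return SpectrumSet(self.wavenumbers, intensities, self.metadata.copy())

    # ------------------------------------------------------------------ I/O

    def to_csv(self, spectra_path, metadata_path) -> None:
        """Write the two-file CSV dialect.

        The spectra file has a ``wavenumber_cm1`` column followed by one
        intensity column per spectrum id; the metadata file has one row per
        spectrum.  UTF-8, ``.`` decimal separator.
        """
        ids = self.metadata["spectrum_id"].astype(str).tolist()
        table = pd.DataFrame({"wavenumber_cm1": self.wavenumbers})
        for i, sid in enumerate(ids):
            table[sid] = self.intensities[i]
        table.to_csv(spectra_path, index=False)
        self.metadata.to_csv(metadata_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path, metadata_path) -> "SpectrumSet":
        """Read the dialect written by :meth:`to_csv`."""
        table = pd.read_csv(spectra_path)
        metadata = pd.read_csv(metadata_path)
        wavenumbers = table["wavenumber_cm1"].to_numpy()
        ids = metadata["spectrum_id"].astype(str).tolist()
        missing = [sid for sid in ids if sid not in table.columns]
        if missing:
            raise ValueError(f"spectra file lacks columns for ids: {missing[:5]}")
        intensities = np.column_stack([table[sid].to_numpy() for sid in ids]).T
        return cls(wavenumbers, intensities, metadata)


def concat_spectrum_sets(sets: list[SpectrumSet]) -> SpectrumSet:
    """Stack sets that share an identical grid."""
    if not sets:
        raise ValueError("no spectrum sets to concatenate")
    grid = sets[0].wavenumbers
    for s in sets[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("spectrum sets have different grids")
    return SpectrumSet(
        grid,
        np.vstack([s.intensities for s in sets]),
        pd.concat([s.metadata for s in sets], ignore_index=True),
    )


def load_run_dir(path) -> SpectrumSet:
    """Read ``spectra.csv`` + ``metadata.csv`` from a directory."""
    p = Path(path)
    return SpectrumSet.from_csv(p / "spectra.csv", p / "metadata.csv")
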