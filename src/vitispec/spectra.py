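"""Spectra, spectral libraries, resampling, aggregation and text/CSV I/O.

A :class:`Spectrum` is a reflectance vector (unitless fractions in [0, 1])
on a :class:`~vitispec.grid.WavelengthGrid`.  A :class:`SpectralLibrary`
bundles many spectra sharing one grid with per-sample metadata (pot,
metal treatment, stress level, replicate, leaf).  Instrument exports are
two-column text files (wavelength, reflectance); libraries round-trip
through a wide CSV with one ``R<nm>`` column per channel.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, canonical_grid

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "METADATA_COLUMNS",
    "resample_to_grid",
    "aggregate",
    "read_spectrum_text",
    "read_library_csv",
    "write_library_csv",
]

#: Per-sample metadata columns, in canonical CSV order.
METADATA_COLUMNS = ["sample_id", "pot_id", "metal", "level", "replicate", "leaf"]

#: Tolerated instrument-noise excursion outside [0, 1] before rejection.
REFLECTANCE_SLACK = 0.05


def _validate_reflectance(values: np.ndarray, where: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{where}: missing reflectance values")
    if values.min() < -REFLECTANCE_SLACK or values.max() > 1 + REFLECTANCE_SLACK:
        raise ValueError(
            f"{where}: reflectance outside [-{REFLECTANCE_SLACK}, "
            f"{1 + REFLECTANCE_SLACK}] (got range "
            f"[{values.min():.4g}, {values.max():.4g}])"
        )
    if values.min() < 0 or values.max() > 1:
        warnings.warn(
            f"{where}: reflectance slightly outside [0, 1]; clipping",
            stacklevel=3,
        )
        values = np.clip(values, 0.0, 1.0)
    return values


@dataclass
class Spectrum:
    """One reflectance spectrum on a wavelength grid."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.reflectance = _validate_reflectance(
            self.reflectance, f"spectrum {self.sample_id!r}"
        )
        if len(self.reflectance) != len(self.grid):
            raise ValueError(
                f"spectrum {self.sample_id!r}: {len(self.reflectance)} values "
                f"for {len(self.grid)} channels"
            )

    def at(self, wavelength_nm: float) -> float:
        """Reflectance at an exact channel centre."""
        return float(self.reflectance[self.grid.index_of(wavelength_nm)])


class SpectralLibrary:
    """A collection of spectra on one shared grid, with sample metadata.

    Parameters
    ----------
    grid : WavelengthGrid
        Shared channel grid.
    reflectance : ndarray, shape (n_samples, n_channels)
    metadata : DataFrame
        One row per sample with columns ``sample_id, pot_id, metal,
        level, replicate, leaf``; sample_ids must be unique.
    """

    def __init__(self, grid: WavelengthGrid, reflectance: np.ndarray,
                 metadata: pd.DataFrame):
        reflectance = np.atleast_2d(np.asarray(reflectance, dtype=float))
        if reflectance.shape[1] != len(grid):
            raise ValueError(
                f"reflectance has {reflectance.shape[1]} channels, "
                f"grid has {len(grid)}"
            )
        missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(metadata) != reflectance.shape[0]:
            raise ValueError("metadata row count does not match spectra count")
        if metadata["sample_id"].duplicated().any():
            dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids: {sorted(set(dups))}")
        if metadata[METADATA_COLUMNS].isna().any().any():
            raise ValueError("incomplete sample metadata")
        self.grid = grid
        self.reflectance = _validate_reflectance(reflectance, "library")
        self.metadata = metadata[METADATA_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return self.reflectance.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])

    def spectrum(self, sample_id: str) -> Spectrum:
        idx = self.metadata.index[self.metadata["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(sample_id)
        return Spectrum(self.grid, self.reflectance[idx[0]], sample_id)

    def __iter__(self):
        for i, sid in enumerate(self.metadata["sample_id"]):
            yield Spectrum(self.grid, self.reflectance[i], sid)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then R<nm> channel columns."""
        cols = [f"R{ch:g}" for ch in self.grid.channels]
        wide = pd.DataFrame(self.reflectance, columns=cols)
        return pd.concat([self.metadata.reset_index(drop=True), wide], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectralLibrary":
        chan_cols = [c for c in frame.columns if re.fullmatch(r"R\d+(\.\d+)?", c)]
        if not chan_cols:
            raise ValueError("no R<nm> channel columns found")
        wavelengths = np.array([float(c[1:]) for c in chan_cols])
        order = np.argsort(wavelengths)
        wavelengths = wavelengths[order]
        chan_cols = [chan_cols[i] for i in order]
        steps = np.diff(wavelengths)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("channel columns are not uniformly spaced")
        step = steps[0] if len(steps) else 1.0
        grid = WavelengthGrid(wavelengths[0], wavelengths[-1], step)
        return cls(grid, frame[chan_cols].to_numpy(float),
                   frame[METADATA_COLUMNS].copy())


def resample_to_grid(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid.

    The source wavelengths must span the target grid; extrapolation is
    refused.  Values already on-grid pass through unchanged.
    """
    src = spectrum.grid.channels
    if grid.channels[0] < src[0] - 1e-9 or grid.channels[-1] > src[-1] + 1e-9:
        raise ValueError(
            f"target grid {grid} extends beyond source span "
            f"[{src[0]:g}, {src[-1]:g}] nm"
        )
    values = np.interp(grid.channels, src, spectrum.reflectance)
    return Spectrum(grid, values, spectrum.sample_id)


def aggregate(library: SpectralLibrary, level: str = "pot") -> SpectralLibrary:
    """Collapse leaf spectra to per-pot means (channel-wise).

    Aggregation is idempotent: a library already at pot granularity maps
    to itself.  Pot metadata is retained; the leaf index is set to 0 to
    mark pot-level rows.
    """
    if level != "pot":
        raise ValueError(f"unsupported aggregation level {level!r}")
    meta = library.metadata
    rows = []
    spectra = []
    for pot_id, sub in meta.groupby("pot_id", sort=False):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            raise ValueError(f"pot {pot_id} has no spectra")
        spectra.append(library.reflectance[sub.index].mean(axis=0))
        first = sub.iloc[0]
        rows.append({
            "sample_id": str(pot_id),
            "pot_id": pot_id,
            "metal": first["metal"],
            "level": first["level"],
            "replicate": first["replicate"],
            "leaf": 0,
        })
    return SpectralLibrary(library.grid, np.vstack(spectra), pd.DataFrame(rows))


_NUMERIC_ROW = re.compile(
    r"^\s*([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)[\s,;\t]+"
    r"([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*$"
)


def read_spectrum_text(path, grid: WavelengthGrid | None = None,
                       sample_id: str = "") -> Spectrum:
    """Read a two-column (wavelength nm, reflectance) instrument export.

    Header or comment lines that do not parse as two numbers are
    skipped.  Duplicate wavelengths (e.g. detector-seam overlap) are
    averaged with a warning.  The result is resampled to ``grid``
    (default: the canonical 350-2500 nm grid restricted to the source
    span if narrower).
    """
    wl, refl = [], []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _NUMERIC_ROW.match(line)
            if m:
                in_data = True
                wl.append(float(m.group(1)))
                refl.append(float(m.group(2)))
            elif in_data:  # headers are tolerated, interior garbage is not
                raise ValueError(f"{path}: non-numeric row at line {lineno}")
    if not wl:
        raise ValueError(f"{path}: no numeric (wavelength, reflectance) rows")
    wl = np.asarray(wl)
    refl = np.asarray(refl)
    if len(np.unique(wl)) < len(wl):
        warnings.warn(f"{path}: duplicate wavelengths averaged", stacklevel=2)
        frame = pd.DataFrame({"wl": wl, "r": refl}).groupby("wl", sort=True).mean()
        wl = frame.index.to_numpy()
        refl = frame["r"].to_numpy()
    else:
        order = np.argsort(wl)
        wl, refl = wl[order], refl[order]
    src_grid_values = wl
    src = Spectrum(_irregular_grid_stub(src_grid_values), refl, sample_id)
    if grid is None:
        canon = canonical_grid()
        lo = max(canon.start_nm, np.ceil(wl[0]))
        hi = min(canon.stop_nm, np.floor(wl[-1]))
        grid = WavelengthGrid(lo, hi, 1.0)
    return resample_to_grid(src, grid)


class _IrregularGrid(WavelengthGrid):
    """Internal: wraps arbitrary increasing wavelengths for resampling."""

    def __init__(self, channels: np.ndarray):  # bypass uniform-step checks
        object.__setattr__(self, "start_nm", float(channels[0]))
        object.__setattr__(self, "stop_nm", float(channels[-1]))
        object.__setattr__(self, "step_nm", float("nan"))
        object.__setattr__(self, "channels", np.asarray(channels, float))


def _irregular_grid_stub(channels: np.ndarray) -> WavelengthGrid:
    if len(channels) > 1 and np.any(np.diff(channels) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return _IrregularGrid(np.asarray(channels, float))


def write_library_csv(library: SpectralLibrary, path) -> None:
    """Write a library as wide CSV (metadata columns then R<nm> columns)."""
    library.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_library_csv(path) -> SpectralLibrary:
    """Read a wide-CSV spectral library written by :func:`write_library_csv`."""
    frame = pd.read_csv(path)
    return SpectralLibrary.from_frame(frame)
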