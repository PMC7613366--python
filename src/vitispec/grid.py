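"""Wavelength grids and spectral regions.

The canonical measurement grid is 350-2500 nm at 1 nm spacing (2151
channels), the full range of a field spectroradiometer.  The spectrum is
partitioned into four conventional vegetation regions -- visible (VIS),
red edge (RDE), near infrared (NIR) and mid infrared (MIR) -- whose
closed intervals deliberately overlap: the red edge straddles the
VIS/NIR boundary, so a wavelength can belong to more than one region.
A fixed precedence (RDE > VIS > NIR > MIR) defines a unique *primary*
region for bookkeeping purposes such as tallying selected wavelengths
per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "build_grid",
    "canonical_grid",
    "REGIONS",
    "REGION_PRECEDENCE",
    "classify_regions",
    "primary_region",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered, uniformly spaced set of channel centres in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float
    channels: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.step_nm <= 0:
            raise ValueError(f"step must be positive, got {self.step_nm}")
        if self.start_nm > self.stop_nm:
            raise ValueError(
                f"start ({self.start_nm}) must not exceed stop ({self.stop_nm})"
            )
        span = self.stop_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"range {self.start_nm}-{self.stop_nm} nm is not divisible "
                f"by step {self.step_nm} nm"
            )
        chans = self.start_nm + self.step_nm * np.arange(int(round(n_steps)) + 1)
        object.__setattr__(self, "channels", chans)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact channel centre; raises if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= self.n_channels or abs(pos - idx) > 1e-9:
            raise KeyError(f"{wavelength_nm} nm is not a channel of {self}")
        return idx

    def __repr__(self) -> str:
        return (
            f"WavelengthGrid({self.start_nm:g}-{self.stop_nm:g} nm, "
            f"step {self.step_nm:g} nm, {self.n_channels} channels)"
        )


def build_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform wavelength grid; (stop-start) must divide by step."""
    return WavelengthGrid(start_nm, stop_nm, step_nm)


def canonical_grid() -> WavelengthGrid:
    """The canonical 350-2500 nm, 1 nm grid (2151 channels)."""
    return build_grid(350.0, 2500.0, 1.0)


#: Closed spectral intervals (nm).  RDE overlaps both VIS and NIR.
REGIONS: dict[str, tuple[float, float]] = {
    "VIS": (350.0, 700.0),
    "RDE": (680.0, 750.0),
    "NIR": (700.0, 1300.0),
    "MIR": (1300.0, 2500.0),
}

#: Precedence used to assign a unique primary region at overlaps.
REGION_PRECEDENCE: tuple[str, ...] = ("RDE", "VIS", "NIR", "MIR")


def classify_regions(wavelength_nm: float) -> set[str]:
    """All regions whose closed interval contains the wavelength."""
    if not (350.0 <= wavelength_nm <= 2500.0):
        raise ValueError(f"wavelength {wavelength_nm} nm outside 350-2500 nm")
    return {
        name for name, (lo, hi) in REGIONS.items() if lo <= wavelength_nm <= hi
    }


def primary_region(wavelength_nm: float) -> str:
    """Unique region assignment using the RDE > VIS > NIR > MIR precedence."""
    members = classify_regions(wavelength_nm)
    for name in REGION_PRECEDENCE:
        if name in members:
            return name
    raise AssertionError("regions cover 350-2500 nm")  # pragma: no cover
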