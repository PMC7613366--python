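"""Synthetic heavy-metal stress experiment generator.

Emulates a controlled dosing study on grapevine seedlings: five metals
(Cu, Zn, Pb, Cr, Cd) applied through irrigation water at 1-4x the
maximum allowed level (MAL), four replicate pots per metal x level cell,
plus a shared four-pot control group (84 pots in all), with at least
five leaves measured per pot (420 leaf spectra on the 350-2500 nm,
1 nm grid).

The reflectance model is deliberately phenomenological rather than a
radiative-transfer leaf model: a parametric healthy baseline (green
peak, logistic red edge, NIR plateau, water-absorption dips near 1450
and 1940 nm) plus a stress response that is monotone in dose --
a small broadband lift and Gaussian bumps at metal-specific sensitive
bands.  Per-pot lognormal gain jitter on each band makes the bands
quasi-independent directions of variation, which is what lets a
multi-component feature selector attribute separate components to
separate bands.  Leaf concentrations follow a linear dose-response with
multiplicative lognormal noise and are left-censored at the instrument
detection limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, canonical_grid
from .spectra import SpectralLibrary

__all__ = [
    "METALS",
    "DesignSpec",
    "StressResponseModel",
    "NoiseModel",
    "ConcentrationTable",
    "default_design",
    "default_response",
    "default_noise",
    "baseline_reflectance",
    "generate_concentrations",
    "generate_dataset",
]

METALS = ("Cu", "Zn", "Pb", "Cr", "Cd")

#: Instrument detection limits, mg/kg dry weight.
DETECTION_LIMITS = {"Zn": 0.008, "Cu": 0.025, "Pb": 0.01, "Cr": 0.04, "Cd": 0.009}

#: Metal-specific sensitive band centres (nm) used by the stress response.
SENSITIVE_BANDS = {
    "Cu": (2431, 809, 489, 616),
    "Zn": (2032, 883, 665, 564, 688, 437),
    "Pb": (1865, 728, 692, 683, 356),
    "Cr": (863, 2044, 415, 652, 713, 1036),
    "Cd": (1373, 631, 744, 438),
}


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the dosing experiment.

    With the defaults (five metals, four stressed levels, four
    replicates per cell, one shared control group) the pot count is
    4 + 5*4*4 = 84 and the spectra count 84*5 = 420.
    """

    metals: tuple[str, ...] = METALS
    levels: tuple[int, ...] = (0, 1, 2, 3, 4)  # MAL multipliers; 0 = control
    replicates_per_cell: int = 4
    control_shared: bool = True
    leaves_per_pot: int = 5
    mal_ugL: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        missing = [m for m in self.metals if m not in self.mal_ugL]
        if missing:
            raise ValueError(f"MAL (ug/L) required for metals: {missing}")
        if 0 not in self.levels:
            raise ValueError("levels must include the control level 0")

    @property
    def stressed_levels(self) -> tuple[int, ...]:
        return tuple(l for l in self.levels if l > 0)

    @property
    def n_pots(self) -> int:
        stressed = len(self.metals) * len(self.stressed_levels) * self.replicates_per_cell
        if self.control_shared:
            return self.replicates_per_cell + stressed
        return len(self.metals) * self.replicates_per_cell + stressed

    @property
    def n_spectra(self) -> int:
        return self.n_pots * self.leaves_per_pot

    def pot_table(self) -> pd.DataFrame:
        """One row per pot: pot_id, metal ('none' for control), level, dose, replicate."""
        rows = []
        if self.control_shared:
            for r in range(1, self.replicates_per_cell + 1):
                rows.append(("C-R%d" % r, "none", "C", 0, r))
        else:
            for m in self.metals:
                for r in range(1, self.replicates_per_cell + 1):
                    rows.append((f"{m}-C-R{r}", "none", "C", 0, r))
        for m in self.metals:
            for lvl in self.stressed_levels:
                for r in range(1, self.replicates_per_cell + 1):
                    rows.append((f"{m}-L{lvl}-R{r}", m, f"L{lvl}", lvl, r))
        return pd.DataFrame(
            rows, columns=["pot_id", "metal", "level", "dose", "replicate"]
        )


def default_design(cr_mal_ugL: float = 100.0, **overrides) -> DesignSpec:
    """The default 84-pot design.

    MALs for Cu, Zn, Pb and Cd follow the irrigation-water standard
    values 200, 2000, 100 and 10 ug/L.  No standard value is bundled for
    Cr; ``cr_mal_ugL`` defaults to 100 ug/L (a common irrigation limit)
    and can be overridden.
    """
    mal = {"Cu": 200.0, "Zn": 2000.0, "Pb": 100.0, "Cr": float(cr_mal_ugL),
           "Cd": 10.0}
    return DesignSpec(mal_ugL=mal, **overrides)


def baseline_reflectance(grid: WavelengthGrid | None = None) -> np.ndarray:
    """Parametric healthy-leaf reflectance on the given grid.

    Green peak near 550 nm, logistic red-edge rise at ~680-750 nm to an
    NIR plateau, a gentle decline through the MIR, and water-absorption
    dips near 1450 and 1940 nm.
    """
    grid = grid or canonical_grid()
    wl = grid.channels
    r = np.full_like(wl, 0.045, dtype=float)
    r += 0.10 * np.exp(-0.5 * ((wl - 550.0) / 35.0) ** 2)        # green peak
    r += 0.41 / (1.0 + np.exp(-(wl - 718.0) / 14.0))             # red edge
    r -= 0.00012 * np.clip(wl - 1300.0, 0.0, None)               # MIR decline
    r -= 0.17 * np.exp(-0.5 * ((wl - 1450.0) / 40.0) ** 2)       # water dip
    r -= 0.26 * np.exp(-0.5 * ((wl - 1940.0) / 55.0) ** 2)       # water dip
    return np.clip(r, 0.01, 1.0)


@dataclass(frozen=True)
class StressResponseModel:
    """How dose reshapes the spectrum and the leaf concentrations.

    ``band_amplitude_per_dose`` is the reflectance increase per MAL
    multiple at each sensitive band centre (Gaussian, ``band_sigma_nm``
    wide); ``broadband_per_dose`` is a flat reflectance lift per MAL
    multiple.  ``band_gain_cv`` is the coefficient of variation of a
    per-pot, per-band lognormal gain on the band bumps.  Concentration
    dose-response is mean mg/kg = baseline + slope * dose.
    """

    sensitive_bands: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(SENSITIVE_BANDS))
    band_amplitude_per_dose: float = 0.012
    band_sigma_nm: float = 10.0
    broadband_per_dose: float = 0.006
    band_gain_cv: float = 0.25
    conc_baseline_mgkg: dict[str, float] = field(
        default_factory=lambda: {"Cu": 8.0, "Zn": 30.0, "Pb": 2.0,
                                 "Cr": 1.5, "Cd": 0.3})
    conc_slope_mgkg: dict[str, float] = field(
        default_factory=lambda: {"Cu": 20.0, "Zn": 60.0, "Pb": 18.0,
                                 "Cr": 5.0, "Cd": 4.0})

    def __post_init__(self):
        if self.band_amplitude_per_dose < 0 or self.broadband_per_dose < 0:
            raise ValueError("effect amplitudes must be non-negative")
        if any(s < 0 for s in self.conc_slope_mgkg.values()):
            raise ValueError("concentration slopes must be non-negative")

    def mean_concentration(self, metal: str, dose: float) -> float:
        return self.conc_baseline_mgkg[metal] + self.conc_slope_mgkg[metal] * dose


def default_response(**overrides) -> StressResponseModel:
    return replace(StressResponseModel(), **overrides) if overrides \
        else StressResponseModel()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings.

    ``smooth_sd`` is the standard deviation of spectrally correlated
    (Gaussian-smoothed, ``smooth_scale_nm`` correlation length) leaf
    noise; ``uv_blue_sd`` is extra white noise added below 400 nm,
    mimicking the noisy 350-400 nm atmospheric window.  ``conc_cv`` is
    the lognormal coefficient of variation of measured concentrations.
    """

    smooth_sd: float = 0.006
    smooth_scale_nm: float = 30.0
    uv_blue_sd: float = 0.012
    conc_cv: float = 0.20
    detection_limits: dict[str, float] = field(
        default_factory=lambda: dict(DETECTION_LIMITS))
    seed: int = 0

    def __post_init__(self):
        if min(self.smooth_sd, self.uv_blue_sd, self.conc_cv) < 0:
            raise ValueError("noise amplitudes must be non-negative")


def default_noise(seed: int = 0, **overrides) -> NoiseModel:
    return NoiseModel(seed=seed, **overrides)


@dataclass
class ConcentrationTable:
    """Measured leaf concentrations, long format.

    One row per (pot, metal): every metal is assayed in every pot; the
    pot's treated metal follows its dose-response, the others sit at
    their baselines.  Values below the instrument detection limit are
    reported *at* the limit with ``censored`` set.
    """

    table: pd.DataFrame  # columns: pot_id, metal, concentration_mgkg, censored

    def for_metal(self, metal: str) -> pd.DataFrame:
        sub = self.table[self.table["metal"] == metal]
        if sub.empty:
            raise KeyError(metal)
        return sub.set_index("pot_id")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        return cls(pd.read_csv(path))


def _band_gains(rng, response: StressResponseModel, metals, n_pots):
    """Per-pot lognormal gain for every (metal, band) bump, mean 1."""
    cv = response.band_gain_cv
    gains = {}
    for m in metals:
        k = len(response.sensitive_bands[m])
        if cv <= 0:
            gains[m] = np.ones((n_pots, k))
        else:
            sigma = np.sqrt(np.log1p(cv ** 2))
            gains[m] = rng.lognormal(-sigma ** 2 / 2, sigma, size=(n_pots, k))
    return gains


def generate_concentrations(design: DesignSpec,
                            response: StressResponseModel | None = None,
                            noise: NoiseModel | None = None) -> ConcentrationTable:
    """Simulate the laboratory concentration assay for every (pot, metal)."""
    response = response or default_response()
    noise = noise or default_noise()
    rng = np.random.default_rng(noise.seed + 1)  # decoupled from spectra stream
    pots = design.pot_table()
    rows = []
    for _, pot in pots.iterrows():
        for metal in design.metals:
            dose = pot["dose"] if pot["metal"] == metal else 0
            mean = response.mean_concentration(metal, dose)
            if noise.conc_cv > 0:
                sigma = np.sqrt(np.log1p(noise.conc_cv ** 2))
                value = mean * rng.lognormal(-sigma ** 2 / 2, sigma)
            else:
                value = mean
            dl = noise.detection_limits.get(metal, 0.0)
            censored = value < dl
            rows.append({
                "pot_id": pot["pot_id"],
                "metal": metal,
                "concentration_mgkg": dl if censored else value,
                "censored": bool(censored),
            })
    return ConcentrationTable(pd.DataFrame(rows))


def _smooth_noise(rng, n_channels: int, sd: float, scale_nm: float,
                  step_nm: float, size: int) -> np.ndarray:
    """Spectrally correlated noise: white noise Gaussian-smoothed along wavelength."""
    if sd <= 0:
        return np.zeros((size, n_channels))
    from scipy.ndimage import gaussian_filter1d
    white = rng.standard_normal((size, n_channels))
    sigma_ch = scale_nm / step_nm
    smooth = gaussian_filter1d(white, sigma=sigma_ch, axis=1, mode="reflect")
    smooth /= smooth.std(axis=1, keepdims=True).clip(1e-12)
    return sd * smooth


def generate_dataset(design: DesignSpec | None = None,
                     response: StressResponseModel | None = None,
                     noise: NoiseModel | None = None,
                     grid: WavelengthGrid | None = None,
                     ) -> tuple[SpectralLibrary, ConcentrationTable]:
    """Simulate the full experiment: leaf spectra plus concentration assay.

    Returns a leaf-level :class:`SpectralLibrary` (one spectrum per
    leaf) and the pot-level :class:`ConcentrationTable`.  Output is a
    deterministic function of ``noise.seed``.
    """
    design = design or default_design()
    response = response or default_response()
    noise = noise or default_noise()
    grid = grid or canonical_grid()
    wl = grid.channels
    rng = np.random.default_rng(noise.seed)

    base = baseline_reflectance(grid)
    pots = design.pot_table()
    gains = _band_gains(rng, response, design.metals, len(pots))

    # Pot-level stressed spectra
    pot_spectra = np.tile(base, (len(pots), 1))
    for i, pot in pots.iterrows():
        dose = pot["dose"]
        if pot["metal"] == "none" or dose == 0:
            continue
        m = pot["metal"]
        pot_spectra[i] += response.broadband_per_dose * dose
        for j, centre in enumerate(response.sensitive_bands[m]):
            bump = np.exp(-0.5 * ((wl - centre) / response.band_sigma_nm) ** 2)
            pot_spectra[i] += (response.band_amplitude_per_dose * dose
                               * gains[m][i, j] * bump)

    # Leaf-level spectra = pot spectrum + correlated noise + UV-blue noise
    n_leaves = design.leaves_per_pot
    meta_rows = []
    leaf_spectra = np.repeat(pot_spectra, n_leaves, axis=0)
    leaf_spectra += _smooth_noise(rng, len(wl), noise.smooth_sd,
                                  noise.smooth_scale_nm, grid.step_nm,
                                  len(leaf_spectra))
    if noise.uv_blue_sd > 0:
        uv_mask = wl <= 400.0
        leaf_spectra[:, uv_mask] += noise.uv_blue_sd * rng.standard_normal(
            (len(leaf_spectra), int(uv_mask.sum())))
    np.clip(leaf_spectra, 0.0, 1.0, out=leaf_spectra)

    for _, pot in pots.iterrows():
        for leaf in range(1, n_leaves + 1):
            meta_rows.append({
                "sample_id": f"{pot['pot_id']}_leaf{leaf}",
                "pot_id": pot["pot_id"],
                "metal": pot["metal"],
                "level": pot["level"],
                "replicate": pot["replicate"],
                "leaf": leaf,
            })
    library = SpectralLibrary(grid, leaf_spectra, pd.DataFrame(meta_rows))
    concentrations = generate_concentrations(design, response, noise)
    return library, concentrations
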