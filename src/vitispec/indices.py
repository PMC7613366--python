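"""Registry of the 32 vegetation spectral indices and feature-table computation.

Each index is a band-arithmetic recipe over reflectances ``R(nm)`` and
inclusive window means ``W(lo, hi)``.  Formulas are implemented exactly
as tabulated in the study protocol this package follows, including two
printed forms that differ from the wider literature:

* ``mNDVI705`` defaults to (R750 + R705)/(R750 + R705 - 2 R445); the
  common literature numerator (R750 - R705) is available via
  ``compute_index(..., mndvi705_variant="literature")``.
* ``SIPI`` is (R445 - R800)/(R680 - R800), algebraically equal to the
  conventional (R800 - R445)/(R800 - R680).

Division by zero yields a non-finite value that downstream code flags;
it never raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .spectra import SpectralLibrary, Spectrum

__all__ = [
    "IndexDefinition",
    "index_registry",
    "index_names",
    "compute_index",
    "compute_feature_table",
    "nonfinite_flags",
]


@dataclass(frozen=True)
class IndexDefinition:
    """A named band-arithmetic recipe.

    ``scaling`` classifies behaviour under multiplying the spectrum by
    c > 0: "ratio" indices are invariant, "linear" ones scale by c,
    "affine" ones (additive constant in the formula) are neither.
    """

    name: str
    formula: str
    func: Callable  # (R, W) -> float
    bands: frozenset  # wavelengths (nm) and (lo, hi) windows used
    scaling: str  # ratio | linear | affine


def _defs() -> list[IndexDefinition]:
    d = []

    def add(name, formula, func, bands, scaling):
        d.append(IndexDefinition(name, formula, func, frozenset(bands), scaling))

    add("CAI", "0.5*(R2000 + R2200) - R2100",
        lambda R, W: 0.5 * (R(2000) + R(2200)) - R(2100),
        {2000, 2200, 2100}, "linear")
    add("MSI", "R1600/R820", lambda R, W: R(1600) / R(820), {1600, 820}, "ratio")
    add("NDWI", "(R860 - R1240)/(R860 + R1240)",
        lambda R, W: (R(860) - R(1240)) / (R(860) + R(1240)),
        {860, 1240}, "ratio")
    add("DWSI", "(R802 + R547)/(R1657 + R682)",
        lambda R, W: (R(802) + R(547)) / (R(1657) + R(682)),
        {802, 547, 1657, 682}, "ratio")
    add("RATIO975", "2*W(960,990)/(W(920,940) + W(1090,1110))",
        lambda R, W: 2 * W(960, 990) / (W(920, 940) + W(1090, 1110)),
        {(960, 990), (920, 940), (1090, 1110)}, "ratio")
    add("RATIO975_2", "2*W(1180,1220)/(W(1090,1110) + W(1265,1285))",
        lambda R, W: 2 * W(1180, 1220) / (W(1090, 1110) + W(1265, 1285)),
        {(1180, 1220), (1090, 1110), (1265, 1285)}, "ratio")
    add("LCI", "(R850 - R710)/(R850 + R680)",
        lambda R, W: (R(850) - R(710)) / (R(850) + R(680)),
        {850, 710, 680}, "ratio")
    add("DattA", "(R780 - R710)/(R780 - R680)",
        lambda R, W: (R(780) - R(710)) / (R(780) - R(680)),
        {780, 710, 680}, "ratio")
    add("mNDVI705", "(R750 + R705)/(R750 + R705 - 2*R445)",
        lambda R, W: (R(750) + R(705)) / (R(750) + R(705) - 2 * R(445)),
        {750, 705, 445}, "ratio")
    add("SGB", "(R750 - R445)/(R705 - R445)",
        lambda R, W: (R(750) - R(445)) / (R(705) - R(445)),
        {750, 705, 445}, "ratio")
    add("SIPI", "(R445 - R800)/(R680 - R800)",
        lambda R, W: (R(445) - R(800)) / (R(680) - R(800)),
        {445, 800, 680}, "ratio")
    add("SR", "R774/R677", lambda R, W: R(774) / R(677), {774, 677}, "ratio")
    add("R550", "R550", lambda R, W: R(550), {550}, "linear")
    add("R680", "R680", lambda R, W: R(680), {680}, "linear")
    add("WI", "R900/R970", lambda R, W: R(900) / R(970), {900, 970}, "ratio")
    add("GM1", "R750/R550", lambda R, W: R(750) / R(550), {750, 550}, "ratio")
    add("GM2", "R750/R700", lambda R, W: R(750) / R(700), {750, 700}, "ratio")
    add("Lic1", "(R800 - R680)/(R800 + R680)",
        lambda R, W: (R(800) - R(680)) / (R(800) + R(680)),
        {800, 680}, "ratio")
    add("Lic2", "R440/R690", lambda R, W: R(440) / R(690), {440, 690}, "ratio")
    add("Lic3", "R440/R740", lambda R, W: R(440) / R(740), {440, 740}, "ratio")
    add("SRPI", "R430/R680", lambda R, W: R(430) / R(680), {430, 680}, "ratio")
    add("NPQI", "(R415 - R435)/(R415 + R435)",
        lambda R, W: (R(415) - R(435)) / (R(415) + R(435)),
        {415, 435}, "ratio")
    add("NPCI", "(R680 - R430)/(R680 + R430)",
        lambda R, W: (R(680) - R(430)) / (R(680) + R(430)),
        {680, 430}, "ratio")
    add("GI", "R554/R677", lambda R, W: R(554) / R(677), {554, 677}, "ratio")
    add("WI1180", "R900/R1180", lambda R, W: R(900) / R(1180),
        {900, 1180}, "ratio")
    add("NDVI", "(R831 - R667)/(R831 + R667)",
        lambda R, W: (R(831) - R(667)) / (R(831) + R(667)),
        {831, 667}, "ratio")
    add("CI", "R760/R695", lambda R, W: R(760) / R(695), {760, 695}, "ratio")
    add("VOG", "R740/R720", lambda R, W: R(740) / R(720), {740, 720}, "ratio")
    add("CRI", "R800*(1/R520 - 1/R550)",
        lambda R, W: R(800) * (1 / R(520) - 1 / R(550)),
        {800, 520, 550}, "ratio")
    add("PRI1", "(R531 - R570)/(R531 + R570)",
        lambda R, W: (R(531) - R(570)) / (R(531) + R(570)),
        {531, 570}, "ratio")
    add("PRI2", "1.5*(R830 - R660)/(R830 - R660 + 0.5)",
        lambda R, W: 1.5 * (R(830) - R(660)) / (R(830) - R(660) + 0.5),
        {830, 660}, "affine")
    add("PRI3", "(R539 - R570)/(R539 + R570)",
        lambda R, W: (R(539) - R(570)) / (R(539) + R(570)),
        {539, 570}, "ratio")
    return d


_REGISTRY: dict[str, IndexDefinition] = {x.name: x for x in _defs()}
assert len(_REGISTRY) == 32

_MNDVI705_LITERATURE = IndexDefinition(
    "mNDVI705", "(R750 - R705)/(R750 + R705 - 2*R445)",
    lambda R, W: (R(750) - R(705)) / (R(750) + R(705) - 2 * R(445)),
    frozenset({750, 705, 445}), "ratio")


def index_registry() -> list[IndexDefinition]:
    """The 32 index definitions, in tabulated order."""
    return list(_REGISTRY.values())


def index_names() -> list[str]:
    return list(_REGISTRY)


def compute_index(spectrum: Spectrum, name: str, *,
                  mndvi705_variant: str = "printed") -> float:
    """Evaluate one index on a spectrum.

    Window terms are arithmetic means over the inclusive window on the
    spectrum's grid.  A zero denominator yields inf/nan (flagged by
    :func:`nonfinite_flags`), never an exception.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown index {name!r}; registry has {index_names()}")
    definition = _REGISTRY[name]
    if name == "mNDVI705" and mndvi705_variant == "literature":
        definition = _MNDVI705_LITERATURE
    elif name == "mNDVI705" and mndvi705_variant != "printed":
        raise ValueError(f"unknown mNDVI705 variant {mndvi705_variant!r}")

    wl = spectrum.grid.channels
    refl = spectrum.reflectance

    def R(nm):
        return refl[spectrum.grid.index_of(nm)]

    def W(lo, hi):
        mask = (wl >= lo) & (wl <= hi)
        return float(refl[mask].mean())

    with np.errstate(divide="ignore", invalid="ignore"):
        return float(definition.func(R, W))


def compute_feature_table(library: SpectralLibrary, **kwargs) -> pd.DataFrame:
    """All 32 indices for every sample: rows = samples, columns = indices.

    Non-finite entries (zero denominators) are kept in place; use
    :func:`nonfinite_flags` to locate them.
    """
    if len(library) == 0:
        raise ValueError("empty spectral library")
    rows = {}
    for spectrum in library:
        rows[spectrum.sample_id] = {
            name: compute_index(spectrum, name, **kwargs)
            for name in index_names()
        }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=index_names())
    table.index.name = "sample_id"
    return table


def nonfinite_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of flagged (non-finite) feature-table entries."""
    return ~np.isfinite(table)
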