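"""Catalogue of the 21 environmental predictors used for the breeding model.

Two topographic variables plus 19 bioclimatic ones (the WorldClim "bio"
family under short codes). The catalogue fixes a canonical ordering that is
used as the deterministic tie-break throughout screening, and records for
each variable:

* ``factor`` -- "topography" or "climate"; only climate variables may be
  perturbed in future scenarios (topography is held fixed when projecting).
* ``kind`` -- the marginal family the synthetic generator draws from:
  ``"nonneg"`` variables (precipitation amounts, altitude, slope,
  coefficients of variation) get a log-normal marginal so support stays
  non-negative; ``"real"`` variables (temperatures, indices) get a Gaussian
  marginal.
* ``loc``/``scale`` -- location and spread of the synthetic marginal, chosen
  to be plausible for a Western-Palearctic-plus-North-Africa study window
  (units: m, degrees, deg C, mm, %, as per ``units``).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Variable:
    code: str
    name: str
    units: str
    factor: str  # "topography" | "climate"
    kind: str    # "nonneg" | "real"
    loc: float
    scale: float


VARIABLES: tuple[Variable, ...] = (
    Variable("Alti", "Altitude", "m", "topography", "nonneg", 400.0, 0.7),
    Variable("Slope", "Slope", "degrees", "topography", "nonneg", 2.5, 0.8),
    Variable("Tmean", "Annual mean temperature", "degC", "climate", "real", 12.0, 8.0),
    Variable("Rtday", "Mean diurnal temperature range", "degC", "climate", "real", 10.0, 2.5),
    Variable("Isot", "Isothermality", "%", "climate", "real", 35.0, 8.0),
    Variable("Season", "Temperature seasonality", "sd*100", "climate", "nonneg", 600.0, 0.4),
    Variable("Tmax", "Maximum temperature of warmest month", "degC", "climate", "real", 28.0, 7.0),
    Variable("Tmin", "Minimum temperature of coldest month", "degC", "climate", "real", -2.0, 9.0),
    Variable("Rtan", "Temperature annual range", "degC", "climate", "real", 30.0, 8.0),
    Variable("Twet", "Mean temperature of wettest quarter", "degC", "climate", "real", 8.0, 8.0),
    Variable("Tdry", "Mean temperature of driest quarter", "degC", "climate", "real", 18.0, 8.0),
    Variable("Twarm", "Mean temperature of warmest quarter", "degC", "climate", "real", 21.0, 7.0),
    Variable("Tcold", "Mean temperature of coldest quarter", "degC", "climate", "real", 3.0, 9.0),
    Variable("Prec", "Annual precipitation", "mm", "climate", "nonneg", 500.0, 0.55),
    Variable("Pmax", "Precipitation of wettest month", "mm", "climate", "nonneg", 80.0, 0.55),
    Variable("Pmin", "Precipitation of driest month", "mm", "climate", "nonneg", 12.0, 0.9),
    Variable("Cvp", "Precipitation seasonality", "cv", "climate", "nonneg", 40.0, 0.5),
    Variable("Pwet", "Precipitation of wettest quarter", "mm", "climate", "nonneg", 210.0, 0.55),
    Variable("Pdry", "Precipitation of driest quarter", "mm", "climate", "nonneg", 45.0, 0.9),
    Variable("Pwarm", "Precipitation of warmest quarter", "mm", "climate", "nonneg", 60.0, 0.5),
    Variable("Pcold", "Precipitation of coldest quarter", "mm", "climate", "nonneg", 150.0, 0.55),
)

CODES: tuple[str, ...] = tuple(v.code for v in VARIABLES)
CATALOGUE_ORDER: dict[str, int] = {v.code: i for i, v in enumerate(VARIABLES)}
TOPOGRAPHIC: frozenset[str] = frozenset(v.code for v in VARIABLES if v.factor == "topography")
CLIMATIC: frozenset[str] = frozenset(v.code for v in VARIABLES if v.factor == "climate")


def by_code(code: str) -> Variable:
    for v in VARIABLES:
        if v.code == code:
            return v
    raise KeyError(f"unknown variable code: {code!r}")
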