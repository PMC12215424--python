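"""The 22-indicator tourism-urbanization evaluation system.

Three subsystems: tourism industry (T1–T6), urbanization (U1–U9) and
eco-environment (E1–E7, PSR-framed).  Each indicator carries a direction:
"+" means larger is better for tourism-urbanization development, "−" marks
pressure indicators (industrial SO₂, wastewater, particulates) where larger
is worse.  Baselines are plausible municipal magnitudes in each indicator's
printed unit and are used only by the synthetic panel generator; trends are
per-decade growth factors emulating 2000→2020 yearbook dynamics.
"""

from __future__ import annotations

import pandas as pd

TOURISM, URBAN, ECO = "tourism", "urbanization", "eco"

# code: (name/unit, direction, subsystem, baseline, per-decade trend factor)
_TABLE = {
    "T1": ("Tourism Foreign Exchange Income / 10^4 USD", "+", TOURISM, 8.0e3, 1.6),
    "T2": ("Domestic Tourism Income / 10^8 CNY", "+", TOURISM, 1.2e2, 1.7),
    "T3": ("Inbound Tourist Arrivals / 10^4 persons", "+", TOURISM, 2.5e1, 1.5),
    "T4": ("Domestic Tourist Arrivals / 10^4 persons", "+", TOURISM, 2.5e3, 1.6),
    "T5": ("Comprehensive Tourism Benefit Revenue / 10^8 CNY", "+", TOURISM, 1.5e2, 1.7),
    "T6": ("Tourism Revenue share of GDP / %", "+", TOURISM, 8.0, 1.15),
    "U1": ("Urban Disposable Income per capita / CNY", "+", URBAN, 1.8e4, 1.5),
    "U2": ("Secondary+Tertiary Output share of GDP / %", "+", URBAN, 8.0e1, 1.05),
    "U3": ("Urbanization rate / %", "+", URBAN, 4.5e1, 1.2),
    "U4": ("Secondary+Tertiary Employment share / %", "+", URBAN, 7.0e1, 1.1),
    "U5": ("Higher-education Students / persons", "+", URBAN, 8.0e4, 1.4),
    "U6": ("Retail Sales per capita / CNY", "+", URBAN, 1.5e4, 1.5),
    "U7": ("Hospital Beds per 10^4 people", "+", URBAN, 4.5e1, 1.2),
    "U8": ("Road Area per capita / m^2", "+", URBAN, 1.2e1, 1.25),
    "U9": ("Built-up share of Urban Land / %", "+", URBAN, 1.0e1, 1.3),
    "E1": ("Industrial SO2 Emissions / t", "-", ECO, 4.0e4, 0.7),
    "E2": ("Industrial Wastewater Discharge / t", "-", ECO, 6.0e6, 0.75),
    "E3": ("Industrial Particulate Emissions / t", "-", ECO, 2.0e4, 0.7),
    "E4": ("Park & Green Space per capita / m^2", "+", ECO, 1.1e1, 1.25),
    "E5": ("Built-up Greening Coverage / %", "+", ECO, 3.8e1, 1.1),
    "E6": ("Industrial Waste Utilization Rate / %", "+", ECO, 7.5e1, 1.1),
    "E7": ("Household Garbage Treatment Rate / %", "+", ECO, 8.5e1, 1.1),
}

INDICATOR_CODES: tuple[str, ...] = tuple(_TABLE)

INDICATORS = pd.DataFrame(
    [(code, *row) for code, row in _TABLE.items()],
    columns=["indicator_code", "name", "direction", "subsystem",
             "baseline", "decade_trend"],
).set_index("indicator_code")

DIRECTIONS: dict[str, str] = INDICATORS["direction"].to_dict()
SUBSYSTEMS: dict[str, str] = INDICATORS["subsystem"].to_dict()


def subsystem_codes(subsystem: str) -> list[str]:
    """Indicator codes belonging to one subsystem, in schema order."""
    return [c for c, s in SUBSYSTEMS.items() if s == subsystem]
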