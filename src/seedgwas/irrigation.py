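"""Evapotranspiration and irrigation-scheduling arithmetic.

The well-watered treatment of a field trial is scheduled from pan
evaporation: a class-A pan reading ``E_pan`` (mm) is scaled by a pan
coefficient ``K_pan`` to the reference evapotranspiration ``ET_0``, a
monthly crop coefficient ``K_C`` converts that to crop evapotranspiration
``ET_C``, and the water volume follows from the standard identity that
1 mm of depth over 1 ha is 10 m^3.

Two ET_0 paths are deliberately exposed: :func:`et0_from_pan` (the pan
formula) and a direct ``et_0`` argument to :func:`crop_et` /
:func:`month_schedule`, because published schedules sometimes tabulate a
fixed ET_0 that the pan formula does not reproduce.  Nothing here forces
one through the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "IrrigationMonth",
    "et0_from_pan",
    "crop_et",
    "water_schedule",
    "month_schedule",
    "month_table",
    "DEFAULT_MONTHS",
    "DEFAULT_PLOT_AREA_M2",
    "DEFAULT_DISCHARGE_M3H",
]

#: Cultivated plot area (m^2) of the default schedule. The trial text also
#: quotes a 1400 m^2 cultivation area; pass ``plot_area`` to override.
DEFAULT_PLOT_AREA_M2 = 1377.0

#: Water discharge of the irrigation outlet (m^3/h).
DEFAULT_DISCHARGE_M3H = 10.8

#: Monthly (month, ET_0 mm, K_C) defaults of the spring schedule.
DEFAULT_MONTHS = [
    ("March", 40.0, 0.92),
    ("April", 40.0, 1.33),
    ("May", 40.0, 1.154),
    ("June", 40.0, 0.58),
]


@dataclass
class IrrigationMonth:
    """One month of the irrigation schedule, all quantities non-negative."""

    month: str
    et_0: float            # reference evapotranspiration, mm
    k_c: float             # crop coefficient, dimensionless
    et_c: float            # crop evapotranspiration, mm
    water_per_ha: float    # m^3/ha
    plot_area: float       # m^2
    plot_water: float      # m^3 for the plot
    discharge: float       # m^3/h
    duration: float        # irrigation time, h

    def as_row(self) -> dict:
        return {
            "month": self.month,
            "ET_0_mm": self.et_0,
            "K_C": self.k_c,
            "ET_C_mm": round(self.et_c, 1),
            "water_per_ha_m3": round(self.water_per_ha, 0),
            "plot_water_m3": round(self.plot_water, 2),
            "discharge_m3h": self.discharge,
            "duration_h": round(self.duration, 2),
        }


def et0_from_pan(e_pan: float, k_pan: float = 0.8) -> float:
    """Reference evapotranspiration from pan evaporation: ET_0 = E_pan * K_pan.

    ``k_pan`` is the pan coefficient, typically around 0.8 for a class-A pan.
    """
    if e_pan < 0:
        raise ValueError(f"pan evaporation must be >= 0, got {e_pan}")
    if not 0 < k_pan <= 1.5:
        raise ValueError(f"pan coefficient must be in (0, 1.5], got {k_pan}")
    return e_pan * k_pan


def crop_et(k_c: float, et_0: float) -> float:
    """Crop evapotranspiration ET_C = K_C * ET_0 (mm)."""
    if k_c < 0 or et_0 < 0:
        raise ValueError("crop coefficient and ET_0 must be >= 0")
    return k_c * et_0


def water_schedule(
    et_c: float,
    plot_area: float = DEFAULT_PLOT_AREA_M2,
    discharge: float = DEFAULT_DISCHARGE_M3H,
) -> tuple[float, float, float]:
    """Water volume and irrigation time for one month.

    Returns ``(water_per_ha, plot_water, duration)``: 10 m^3/ha per mm of
    ET_C depth, scaled to the plot area, divided by the outlet discharge.
    """
    if et_c < 0:
        raise ValueError("ET_C must be >= 0")
    if plot_area <= 0:
        raise ValueError("plot area must be > 0")
    if discharge <= 0:
        raise ValueError("discharge must be > 0")
    water_per_ha = et_c * 10.0
    plot_water = water_per_ha * plot_area / 10_000.0
    duration = plot_water / discharge
    return water_per_ha, plot_water, duration


def month_schedule(
    month: str,
    et_0: float,
    k_c: float,
    plot_area: float = DEFAULT_PLOT_AREA_M2,
    discharge: float = DEFAULT_DISCHARGE_M3H,
) -> IrrigationMonth:
    """Full scheduling arithmetic for one month."""
    et_c = crop_et(k_c, et_0)
    per_ha, plot_water, duration = water_schedule(et_c, plot_area, discharge)
    return IrrigationMonth(
        month=month,
        et_0=et_0,
        k_c=k_c,
        et_c=et_c,
        water_per_ha=per_ha,
        plot_area=plot_area,
        plot_water=plot_water,
        discharge=discharge,
        duration=duration,
    )


def month_table(
    months=None,
    plot_area: float = DEFAULT_PLOT_AREA_M2,
    discharge: float = DEFAULT_DISCHARGE_M3H,
) -> pd.DataFrame:
    """Schedule table for a sequence of ``(month, ET_0, K_C)`` triples.

    Defaults to the March-June spring schedule. Reported columns are rounded
    the way irrigation tables print them (ET_C to 1 dp, volumes to 2 dp,
    duration to 2 dp).
    """
    if months is None:
        months = DEFAULT_MONTHS
    rows = [
        month_schedule(m, et0, kc, plot_area, discharge).as_row()
        for m, et0, kc in months
    ]
    return pd.DataFrame(rows)
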