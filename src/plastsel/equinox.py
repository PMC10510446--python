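"""Vernal-equinox dates and conversion of calendar dates to equinox-relative days.

Flowering dates are expressed as days after the March (vernal) equinox so that
phenology is comparable across leap and common years.  Equinox instants are
computed from the standard astronomical polynomial-plus-periodic-terms
approximation (accurate to well under an hour over 1000-3000 CE, i.e. exact at
day resolution for any practical use here); a user-supplied ``year -> date``
table overrides the computed dates when provided.
"""

from __future__ import annotations

import datetime as dt
import math
from functools import lru_cache

__all__ = ["vernal_equinox", "to_equinox_day", "EquinoxLookupError"]


class EquinoxLookupError(KeyError):
    """Raised when a year is missing from a user-supplied equinox table."""


# Periodic correction terms: amplitude, phase (deg), rate (deg / Julian century).
_PERIODIC_TERMS = (
    (485, 324.96, 1934.136),
    (203, 337.23, 32964.467),
    (199, 342.08, 20.186),
    (182, 27.85, 445267.112),
    (156, 73.14, 45036.886),
    (136, 171.52, 22518.443),
    (77, 222.54, 65928.934),
    (74, 296.72, 3034.906),
    (70, 243.58, 9037.513),
    (58, 119.81, 33718.147),
    (52, 297.17, 150.678),
    (50, 21.02, 2281.226),
    (45, 247.54, 29929.562),
    (44, 325.15, 31555.956),
    (29, 60.93, 4443.417),
    (18, 155.12, 67555.328),
    (17, 288.79, 4562.452),
    (16, 198.04, 62894.029),
    (14, 199.76, 31436.921),
    (12, 95.39, 14577.848),
    (12, 287.11, 31931.756),
    (12, 320.81, 34777.259),
    (9, 227.73, 1222.114),
    (8, 15.45, 16859.074),
)

_JD_UNIX_EPOCH = 2440587.5  # JD of 1970-01-01T00:00 UTC


@lru_cache(maxsize=None)
def vernal_equinox(year: int) -> dt.date:
    """UTC calendar date of the March equinox for ``year`` (1000-3000 CE)."""
    if not 1000 <= year <= 3000:
        raise ValueError(f"equinox approximation valid for 1000-3000 CE, got {year}")
    y = (year - 2000) / 1000.0
    jde0 = (
        2451623.80984
        + 365242.37404 * y
        + 0.05169 * y**2
        - 0.00411 * y**3
        - 0.00057 * y**4
    )
    t = (jde0 - 2451545.0) / 36525.0
    w = math.radians(35999.373 * t - 2.47)
    dlam = 1 + 0.0334 * math.cos(w) + 0.0007 * math.cos(2 * w)
    s = sum(a * math.cos(math.radians(b + c * t)) for a, b, c in _PERIODIC_TERMS)
    jde = jde0 + (0.00001 * s) / dlam
    # TT -> UTC offset (~1 min) is far below day resolution; ignored.
    instant = dt.datetime(1970, 1, 1) + dt.timedelta(days=jde - _JD_UNIX_EPOCH)
    return instant.date()


def to_equinox_day(date: dt.date, equinox_table: dict[int, dt.date] | None = None) -> int:
    """Convert a calendar date to integer days after the vernal equinox.

    The equinox day itself maps to 0; dates before the equinox are negative.
    ``equinox_table`` (year -> equinox date) overrides the computed equinox;
    a missing year in a supplied table raises :class:`EquinoxLookupError`.
    """
    if isinstance(date, dt.datetime):
        date = date.date()
    if equinox_table is not None:
        try:
            eq = equinox_table[date.year]
        except KeyError:
            raise EquinoxLookupError(
                f"year {date.year} missing from supplied equinox table"
            ) from None
    else:
        eq = vernal_equinox(date.year)
    return (date - eq).days
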