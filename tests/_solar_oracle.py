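"""Independent solar-position oracle (Michalsky 1988, Astronomical Almanac
algorithm), used only to cross-check the package's ephemeris."""

import math
from datetime import datetime, timezone


def michalsky_position(lat: float, lon: float, when: datetime) -> tuple[float, float]:
    """(altitude, azimuth) in degrees; azimuth clockwise from north."""
    when = when.astimezone(timezone.utc)
    hour = when.hour + when.minute / 60.0 + when.second / 3600.0
    doy = when.timetuple().tm_yday
    delta = when.year - 1949
    leap = delta // 4
    jd = 32916.5 + delta * 365 + leap + doy + hour / 24.0
    time = jd - 51545.0
    mnlong = (280.460 + 0.9856474 * time) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * time) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * time)
    ra = math.atan2(math.cos(oblqec) * math.sin(eclong), math.cos(eclong)) % (2 * math.pi)
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))
    gmst = (6.697375 + 0.0657098242 * time + hour) % 24.0
    lmst = math.radians(15.0 * ((gmst + lon / 15.0) % 24.0))
    ha = lmst - ra
    ha = (ha + math.pi) % (2 * math.pi) - math.pi
    latr = math.radians(lat)
    el = math.asin(
        math.sin(dec) * math.sin(latr) + math.cos(dec) * math.cos(latr) * math.cos(ha)
    )
    az = math.degrees(
        math.atan2(
            -math.cos(dec) * math.sin(ha),
            math.sin(dec) * math.cos(latr) - math.cos(dec) * math.sin(latr) * math.cos(ha),
        )
    ) % 360.0
    return math.degrees(el), az
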