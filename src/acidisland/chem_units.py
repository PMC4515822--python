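"""Precipitation-chemistry arithmetic.

Unit conventions used throughout the package:

* concentrations are volume-weighted means (VWM) in ueq L-1;
* annual deposition fluxes are in keq ha-1 yr-1;
* precipitation is in mm yr-1;
* pH is the negative decadal logarithm of H+ activity, so
  H+ [ueq L-1] = 10**(6 - pH).

The flux conversion constant follows from dimensional analysis: 1 mm of
water over 1 ha is 1e4 L, so a concentration of C ueq L-1 delivered by
P mm yr-1 deposits C*P*1e4 ueq ha-1 yr-1 = C*P*1e-5 keq ha-1 yr-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError

logger = logging.getLogger(__name__)

#: ueq->keq and L/mm/ha bookkeeping collapse to a single factor.
FLUX_FACTOR = 1e-5


class Ion(str, Enum):
    H = "H"
    SO4 = "SO4"
    NO3 = "NO3"
    NH4 = "NH4"


class Kind(str, Enum):
    CONCENTRATION = "concentration"
    FLUX = "flux"


@dataclass(frozen=True)
class IonQuantity:
    """A single measured or derived quantity for one ion.

    ``kind`` fixes the units: ueq L-1 for concentrations,
    keq ha-1 yr-1 for fluxes.
    """

    ion: Ion
    value: float
    kind: Kind

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError(f"{self.ion.value} {self.kind.value} must be >= 0")


@dataclass(frozen=True)
class SummaryStats:
    """Geometric-mean summary of one (ion, kind, medium) cell."""

    geometric_mean: float
    n: int
    ion: Ion | None = None
    kind: Kind | None = None
    medium: str | None = None


def ph_to_h(ph: float) -> float:
    """Convert pH to H+ concentration in ueq L-1.

    Strictly decreasing; pH 6 maps to exactly 1 ueq L-1.
    """
    if not (0.0 < ph < 14.0):
        raise DomainError(f"pH {ph!r} outside (0, 14)")
    return 10.0 ** (6.0 - ph)


def h_to_ph(h: float) -> float:
    """Inverse of :func:`ph_to_h`: H+ in ueq L-1 back to pH."""
    if not h > 0.0:
        raise DomainError(f"H+ concentration must be > 0, got {h!r}")
    return 6.0 - math.log10(h)


def volume_weighted_mean(samples: Sequence[tuple[float, float]]) -> float:
    """Volume-weighted mean concentration, sum(v_i c_i) / sum(v_i).

    ``samples`` is a sequence of (volume, concentration) pairs; volumes may
    be in any common unit (L, mm of water, ...) since the result is
    invariant under rescaling all volumes by a constant.
    """
    if len(samples) == 0:
        raise DomainError("volume_weighted_mean needs at least one sample")
    v = np.asarray([s[0] for s in samples], dtype=float)
    c = np.asarray([s[1] for s in samples], dtype=float)
    if np.any(v <= 0):
        raise DomainError("all volumes must be > 0")
    if np.any(c < 0):
        raise DomainError("all concentrations must be >= 0")
    return float(np.sum(v * c) / np.sum(v))


def volume_weighted_ph(
    samples: Sequence[tuple[float, float]], mode: str = "h_activity"
) -> float:
    """Volume-weighted mean pH of event samples.

    mode="h_activity" (default) converts each pH to H+ activity, volume
    weights the activities, and converts back — the chemically meaningful
    average. mode="ph" volume-weights the pH values directly. Pipelines
    record which mode produced their per-site values.
    """
    if mode == "h_activity":
        h_samples = [(v, ph_to_h(ph)) for v, ph in samples]
        return h_to_ph(volume_weighted_mean(h_samples))
    if mode == "ph":
        for _, ph in samples:
            if not (0.0 < ph < 14.0):
                raise DomainError(f"pH {ph!r} outside (0, 14)")
        return volume_weighted_mean(samples)
    raise DomainError(f"unknown pH averaging mode {mode!r}")


def conc_to_flux(conc: float, precip: float) -> float:
    """Annual deposition flux from a VWM concentration and precipitation.

    F [keq ha-1 yr-1] = C [ueq L-1] * P [mm yr-1] * 1e-5. Linear in both
    arguments.
    """
    if conc < 0:
        raise DomainError("concentration must be >= 0")
    if not precip > 0:
        raise DomainError("precipitation must be > 0")
    return conc * precip * FLUX_FACTOR


def geometric_mean(values: Iterable[float]) -> SummaryStats:
    """Geometric mean exp(mean(ln x)) of the strictly positive values.

    Non-positive values cannot enter a geometric mean; they are excluded
    with a logged warning and ``n`` reduced accordingly (no pseudo-count
    is added).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    bad = int(np.sum(arr <= 0))
    if bad:
        logger.warning("geometric_mean: excluding %d non-positive value(s)", bad)
        arr = arr[arr > 0]
    if arr.size == 0:
        raise DomainError("geometric mean needs at least one positive value")
    return SummaryStats(
        geometric_mean=float(np.exp(np.mean(np.log(arr)))), n=int(arr.size)
    )


def summarize(records, ion: Ion, kind: Kind, medium) -> SummaryStats:
    """Geometric-mean summary for one (ion, kind, medium) cell of a site table.

    ``records`` is an iterable of SiteRecords already carrying derived
    fluxes where kind=FLUX is requested (see the pipeline). For ion=H with
    kind=CONCENTRATION the summary is taken over the reported site pH
    values as-is: site pH is already an aggregated quantity, and summaries
    across sites use it without re-transforming to activities.
    """
    medium_value = getattr(medium, "value", medium)
    vals: list[float] = []
    for rec in records:
        if getattr(rec.medium, "value", rec.medium) != medium_value:
            continue
        v = _extract(rec, ion, kind)
        if v is not None:
            vals.append(v)
    if not vals:
        raise DomainError(
            f"no usable values for {ion.value}/{kind.value}/{medium_value}"
        )
    base = geometric_mean(vals)
    return SummaryStats(
        geometric_mean=base.geometric_mean,
        n=base.n,
        ion=ion,
        kind=kind,
        medium=medium_value,
    )


def _extract(rec, ion: Ion, kind: Kind) -> float | None:
    if ion is Ion.H:
        if rec.ph is None:
            return None
        if kind is Kind.CONCENTRATION:
            return rec.ph  # summary statistic over reported site pH
        return conc_to_flux(ph_to_h(rec.ph), rec.precipitation)
    conc = {
        Ion.SO4: rec.conc_so4,
        Ion.NO3: rec.conc_no3,
        Ion.NH4: rec.conc_nh4,
    }[ion]
    if conc is None:
        return None
    if kind is Kind.CONCENTRATION:
        return conc
    return conc_to_flux(conc, rec.precipitation)
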