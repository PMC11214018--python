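"""Physical environment of the bay: tides, light, patches, and eelgrass.

The model bay is a grid of 500 x 500 m intertidal patches, each with a fixed
shore elevation (metres relative to mean lower low water, mllw) and a stock of
rooted eelgrass (g dry mass m^-2) with a shoot length (m).  A fixed fraction
of the rooted stock is present as detached, floating eelgrass.  Water depth
over a patch is tidal height minus patch elevation; rooted eelgrass is
edible when the patch is exposed or when the canopy top is within neck reach
(default 0.4 m) of the water surface, while floating eelgrass is edible at
any tidal stage.

Time runs in 1-h steps over a single non-breeding season, 1 August to
15 May.  Dates are day indices with origin 1 August (day 0); 15 May is day
287, so a season spans 288 days = 6912 hourly steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Season time index: day 0 = 1 Aug, day 287 = 15 May (non-leap calendar).

_MONTH_OFFSETS = {8: 0, 9: 31, 10: 61, 11: 92, 12: 122,
                  1: 153, 2: 184, 3: 212, 4: 243, 5: 273}

N_DAYS = 288
N_STEPS = N_DAYS * 24

SUBSITES = ("BahiaFalsa", "EastBay", "BackBay")


def day_index(month: int, day: int) -> int:
    """Day index with origin 1 August for a date inside the simulated window."""
    if month not in _MONTH_OFFSETS:
        raise ValueError(f"month {month} outside the 1 Aug - 15 May window")
    d = _MONTH_OFFSETS[month] + day - 1
    if not 0 <= d < N_DAYS:
        raise ValueError(f"date {month}-{day} outside the simulated window")
    return d


JAN_SURVEY_DAY = day_index(1, 15)   # eelgrass survey anchor, 15 January


@dataclass
class Patch:
    """One 500 x 500 m cell of the bay.

    ``jan_biomass`` / ``jan_shoot`` anchor the within-season trajectory to the
    January survey value; ``rooted_biomass`` / ``shoot_length`` are the current
    state and ``cum_depletion`` the cumulative grazing offtake (g m^-2).
    """

    id: str
    subsite: str
    elevation: float                    # m relative to mllw
    jan_biomass: float                  # g m^-2 dry mass at 15 Jan
    jan_shoot: float                    # m at 15 Jan
    area: float = 250_000.0             # m^2
    rooted_biomass: float = field(default=None)  # type: ignore[assignment]
    shoot_length: float = field(default=None)    # type: ignore[assignment]
    cum_depletion: float = 0.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("patch area must be positive")
        if self.jan_biomass < 0 or self.jan_shoot < 0:
            raise ValueError("January biomass and shoot length must be >= 0")
        if self.rooted_biomass is None:
            self.rooted_biomass = self.jan_biomass
        if self.shoot_length is None:
            self.shoot_length = self.jan_shoot


@dataclass
class EelgrassParams:
    """Food value and within-season dynamics of eelgrass.

    energy_content : kJ per g dry mass.
    digestibility : proportion of ingested energy assimilated, in [0, 1].
    floating_fraction : floating pool as a fixed proportion of rooted biomass.
    *_node_ratios : multiplicative trajectory values at (1 Aug, 15 Jan,
        15 May), anchored so 15 Jan equals the scenario January value.
    """

    energy_content: float = 16.0
    digestibility: float = 0.55
    floating_fraction: float = 0.05
    biomass_node_ratios: tuple[float, float, float] = (1.6, 1.0, 1.3)
    shoot_node_ratios: tuple[float, float, float] = (1.4, 1.0, 1.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.digestibility <= 1.0:
            raise ValueError("digestibility must lie in [0, 1]")
        if not 0.0 <= self.floating_fraction <= 1.0:
            raise ValueError("floating_fraction must lie in [0, 1]")

    _NODE_DAYS = (0.0, float(JAN_SURVEY_DAY), float(N_DAYS - 1))

    def biomass_factor(self, day) -> np.ndarray | float:
        return np.interp(day, self._NODE_DAYS, self.biomass_node_ratios)

    def shoot_factor(self, day) -> np.ndarray | float:
        return np.interp(day, self._NODE_DAYS, self.shoot_node_ratios)


@dataclass
class TideSeries:
    """Hourly tidal heights (m relative to mllw) covering the season.

    The scenario sea-level anomaly is an offset added uniformly to every step.
    """

    heights: np.ndarray
    sea_level_offset: float = 0.0
    start_day: int = 0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)

    @property
    def adjusted(self) -> np.ndarray:
        return self.heights + self.sea_level_offset

    @classmethod
    def from_harmonics(
        cls,
        n_hours: int = N_STEPS,
        mean_level: float = 0.8,
        amplitudes: tuple[float, float, float] = (0.58, 0.23, 0.33),
        phases: tuple[float, float, float] = (0.0, 0.7, 1.4),
        periods: tuple[float, float, float] = (12.4206012, 12.0, 23.9344696),
        sea_level_offset: float = 0.0,
    ) -> "TideSeries":
        """Synthesize a semidiurnal-dominant tide as an M2 + S2 + K1 sum."""
        t = np.arange(n_hours, dtype=float)
        h = np.full(n_hours, mean_level)
        for amp, phase, period in zip(amplitudes, phases, periods):
            h += amp * np.cos(2.0 * np.pi * t / period - phase)
        return cls(heights=h, sea_level_offset=sea_level_offset)


@dataclass
class LightCalendar:
    """Day/night and lunar state for every hourly step.

    A night step counts as moonlit when the moon's illuminated fraction is at
    least ``moonlit_threshold`` (default 0.5).
    """

    is_day: np.ndarray          # (n_steps,) bool
    moon_fraction: np.ndarray   # (n_steps,) in [0, 1]
    moonlit_night: np.ndarray   # (n_steps,) bool

    @classmethod
    def build(
        cls,
        n_days: int = N_DAYS,
        day_start_hour: int = 6,
        day_end_hour: int = 18,
        synodic_period: float = 29.530588,
        full_moon_day: float = 10.0,
        moonlit_threshold: float = 0.5,
    ) -> "LightCalendar":
        steps = np.arange(n_days * 24)
        hour = steps % 24
        day = steps // 24
        is_day = (hour >= day_start_hour) & (hour < day_end_hour)
        moon = 0.5 * (1.0 + np.cos(2.0 * np.pi * (day - full_moon_day) / synodic_period))
        moonlit = (~is_day) & (moon >= moonlit_threshold)
        return cls(is_day=is_day, moon_fraction=moon, moonlit_night=moonlit)


# ---------------------------------------------------------------------------
# Operations


def water_depth(tide_height: float, elevation: float):
    """Water depth over a patch: tidal height minus shore elevation.

    Negative depth means the patch is exposed.
    """
    return tide_height - elevation


def rooted_available(depth, shoot_length, max_reach: float = 0.4):
    """Whether rooted eelgrass is edible: patch exposed, or canopy top within
    neck reach of the surface (depth - shoot_length <= max_reach)."""
    depth = np.asarray(depth, dtype=float)
    shoot = np.asarray(shoot_length, dtype=float)
    out = (depth <= 0.0) | (depth - shoot <= max_reach)
    return bool(out) if out.ndim == 0 else out


def floating_biomass(rooted_biomass, floating_fraction: float = 0.05):
    """Floating (detached) eelgrass as a fixed proportion of rooted biomass."""
    return floating_fraction * np.asarray(rooted_biomass, dtype=float) \
        if np.ndim(rooted_biomass) else floating_fraction * rooted_biomass


def seasonal_update(patch: Patch, day: int, params: EelgrassParams) -> Patch:
    """Advance a patch to ``day``'s point on the within-season trajectory.

    The trajectory is multiplicative and anchored so that on 15 January, with
    no grazing, the patch holds exactly its January survey biomass and shoot
    length.  Grazing offtake accumulated so far is preserved.
    """
    if not 0 <= day < N_DAYS:
        raise ValueError(f"day {day} outside the 1 Aug - 15 May window")
    baseline = float(params.biomass_factor(day)) * patch.jan_biomass
    patch.rooted_biomass = max(0.0, baseline - patch.cum_depletion)
    patch.shoot_length = max(0.0, float(params.shoot_factor(day)) * patch.jan_shoot)
    return patch


def deplete(patch: Patch, consumed_dry_mass: float) -> Patch:
    """Remove grazed dry mass (g) from a patch's rooted stock, floored at 0."""
    if consumed_dry_mass < 0:
        raise ValueError("consumed mass must be >= 0")
    removed = min(consumed_dry_mass / patch.area, patch.rooted_biomass)
    patch.rooted_biomass -= removed
    patch.cum_depletion += removed
    return patch
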