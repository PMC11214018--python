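"""Flock state, energetics, and rate-maximizing diet choice.

Brant are simulated as flocks of 100 identical birds (super-individuals).
Each bird carries an energy store, the fat reserve expressed in kJ:

    energy_store = (body_mass - lean_mass) * fat_energy_density

Hourly intake while feeding follows a capped Holling type-II functional
response of the edible biomass density B (g m^-2):

    intake = min(max_intake, a * B / (1 + a * h * B))        [g dry h^-1]

and assimilated energy is intake * energy_content * digestibility.  Each hour
a flock moves to the (patch, resource) pair - rooted or floating eelgrass -
that maximizes its assimilation rate.  Birds meet a seasonally dependent
requirement (kJ h^-1) from assimilation, drawing down the store when intake
falls short; the store is capped at a date-dependent target and a store that
falls to zero kills the flock (starvation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import (EelgrassParams, Patch, day_index, rooted_available,
                          floating_biomass, water_depth)

FLOCK_TYPES = ("fall_migrant", "winter_resident", "spring_migrant")

ROOTED, FLOATING = 0, 1


def _default_requirement() -> dict:
    return {"fall": 40.0, "winter": 45.0, "spring": 50.0}


def _default_target_nodes() -> tuple:
    # (day, kJ per bird): flat through fall/winter, pre-migratory ramp to
    # 15 Apr then hold.  13720 kJ = 400 g of fat tissue at 34.3 kJ/g.
    return ((0, 7000.0), (136, 7000.0), (198, 8500.0),
            (257, 13720.0), (287, 13720.0))


def _default_arrival_mass() -> dict:
    return {"fall_migrant": 1300.0, "winter_resident": 1250.0,
            "spring_migrant": 1200.0}


def _default_windows() -> dict:
    # first/last arrival day (inclusive) per flock type
    return {
        "fall_migrant": (day_index(9, 1), day_index(11, 15)),
        "winter_resident": (day_index(10, 15), day_index(12, 15)),
        "spring_migrant": (day_index(2, 16), day_index(3, 31)),
    }


@dataclass
class EnergeticsParams:
    """All bird-side parameters of the model.

    Rates are per bird.  ``attack_rate`` (a, m^2 h^-1) and ``handling_time``
    (h, h g^-1) parameterize the type-II functional response, capped at
    ``max_intake`` (g h^-1).  Winter residents and spring migrants depart once
    the date has reached their departure day AND the store has reached
    ``departure_store``; fall migrants leave after ``fall_stay_days`` days
    regardless of condition.
    """

    requirement_by_season: dict = field(default_factory=_default_requirement)
    target_store_nodes: tuple = field(default_factory=_default_target_nodes)
    fat_energy_density: float = 34.3        # kJ per g of fat tissue
    lean_mass: float = 1100.0               # g per bird
    max_reach: float = 0.4                  # m, foraging depth from surface
    attack_rate: float = 0.8                # a
    handling_time: float = 0.025            # h
    max_intake: float = 30.0                # g dry h^-1 cap
    departure_day_winter: int = day_index(3, 1)
    departure_day_spring: int = day_index(4, 1)
    departure_store: float = 12000.0        # kJ per bird
    fall_stay_days: int = 11
    arrival_mass_by_type: dict = field(default_factory=_default_arrival_mass)
    arrival_windows: dict = field(default_factory=_default_windows)
    fall_population: int = 10000            # birds passing through in fall
    spring_population: int = 10000          # birds passing through in spring
    flock_size: int = 100                   # birds per super-individual
    night_foraging: str = "moonlit"         # "never" | "moonlit" | "always"

    def __post_init__(self) -> None:
        for v in (self.attack_rate, self.handling_time, self.max_intake,
                  self.fat_energy_density, self.departure_store):
            if v < 0:
                raise ValueError("rates and stores must be >= 0")
        if self.fall_stay_days <= 0:
            raise ValueError("fall_stay_days must be positive")

    def target_store(self, day) -> np.ndarray | float:
        days = [n[0] for n in self.target_store_nodes]
        vals = [n[1] for n in self.target_store_nodes]
        return np.interp(day, days, vals)

    def store_from_mass(self, body_mass: float) -> float:
        return (body_mass - self.lean_mass) * self.fat_energy_density

    def mass_from_store(self, store) -> np.ndarray | float:
        return self.lean_mass + np.asarray(store) / self.fat_energy_density \
            if np.ndim(store) else self.lean_mass + store / self.fat_energy_density


@dataclass
class Flock:
    """A super-individual of ``n_birds`` identical brant."""

    id: int
    type: str
    arrival_day: int
    body_mass: float                 # g per bird
    lean_mass: float = 1100.0
    energy_store: float = field(default=None)  # type: ignore[assignment]
    n_birds: int = 100
    status: str = "pending"          # pending -> present -> departed | dead
    current_patch: str | None = None

    def __post_init__(self) -> None:
        if self.type not in FLOCK_TYPES:
            raise ValueError(f"unknown flock type {self.type!r}")
        if self.energy_store is None:
            # default density 34.3 kJ/g used only when constructed bare;
            # the engine always builds flocks through EnergeticsParams
            self.energy_store = (self.body_mass - self.lean_mass) * 34.3


# ---------------------------------------------------------------------------
# Operations


def intake_rate(available_biomass, params: EnergeticsParams):
    """Per-bird intake (g dry h^-1): capped Holling type-II response."""
    b = np.asarray(available_biomass, dtype=float)
    a, h = params.attack_rate, params.handling_time
    rate = a * b / (1.0 + a * h * b)
    rate = np.minimum(rate, params.max_intake)
    return float(rate) if rate.ndim == 0 else rate


def assimilation_rate(intake, energy_content: float, digestibility: float):
    """Energy assimilated (kJ h^-1) from an intake of g dry mass h^-1."""
    return intake * energy_content * digestibility


def feeding_permitted(is_day: bool, moonlit_night: bool,
                      params: EnergeticsParams) -> bool:
    """Feeding happens by day and (with identical intake parameters) on
    moonlit nights; on dark nights birds roost by default."""
    if is_day:
        return True
    if params.night_foraging == "always":
        return True
    if params.night_foraging == "moonlit":
        return moonlit_night
    return False


def best_patch_resource(rooted_b: np.ndarray, floating_b: np.ndarray,
                        rooted_avail: np.ndarray,
                        params: EnergeticsParams) -> tuple[int, int] | None:
    """Argmax of intake rate over (patch, resource) pairs on raw arrays.

    Floating eelgrass is available at every tidal stage.  Because energy
    content and digestibility are common factors, maximizing intake rate
    maximizes assimilation rate.  Ties break to the lowest patch index, and
    rooted before floating within a patch.  Returns None when no pair offers
    a positive rate.
    """
    best_rate, best = 0.0, None
    for p in range(len(rooted_b)):
        if rooted_avail[p] and rooted_b[p] > 0.0:
            r = intake_rate(rooted_b[p], params)
            if r > best_rate:
                best_rate, best = r, (p, ROOTED)
        if floating_b[p] > 0.0:
            r = intake_rate(floating_b[p], params)
            if r > best_rate:
                best_rate, best = r, (p, FLOATING)
    return best


def choose_patch_resource(flock: Flock, patches: list[Patch], tide_height: float,
                          params: EnergeticsParams,
                          eelgrass: EelgrassParams) -> tuple[Patch, str] | None:
    """Pick the patch and resource (rooted/floating) maximizing assimilation.

    Availability is evaluated at the given tidal height for each patch.
    """
    rooted = np.array([p.rooted_biomass for p in patches])
    floating = floating_biomass(rooted, eelgrass.floating_fraction)
    avail = np.array([
        rooted_available(water_depth(tide_height, p.elevation),
                         p.shoot_length, params.max_reach)
        for p in patches
    ])
    hit = best_patch_resource(rooted, floating, avail, params)
    if hit is None:
        return None
    idx, res = hit
    return patches[idx], ("rooted" if res == ROOTED else "floating")


def step_energy(flock: Flock, assimilated: float, requirement: float,
                target_store: float, params: EnergeticsParams) -> Flock:
    """One hour of energy accounting for a present flock.

    store <- min(target, store + assimilated - requirement); a store that
    falls to (or below) zero marks the flock dead of starvation.  Body mass
    tracks the store exactly.
    """
    store = flock.energy_store + assimilated - requirement
    if store <= 0.0:
        flock.energy_store = 0.0
        flock.status = "dead"
    else:
        flock.energy_store = min(store, target_store)
    flock.body_mass = params.mass_from_store(flock.energy_store)
    return flock


def starvation_hours(store: float, requirement: float) -> int:
    """Closed-form hours until death for a flock with zero intake."""
    return int(np.ceil(store / requirement))
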