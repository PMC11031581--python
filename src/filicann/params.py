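"""Domain types and canonical parameter sets.

The model describes a strictly territorial, filially cannibalistic predator
(the damsel bug *Nabis pseudoferus* feeding on *Spodoptera exigua* larvae and,
facultatively, on its own nymphs).  Two groups of parameters exist:

``ForagingParameters``
    everything that enters the prey-preference-dependent Holling type II
    functional/numerical response — prey availability, handling and searching
    times (minutes), attack-success probabilities and conversion coefficients
    (new hatched nymphs per consumed prey item).

``LifeHistoryConfig``
    the discrete time axis — 5-day steps, foraging minutes per step, stage
    durations, maternal reproductive lifespan, migration lag and the length of
    the reproductive season.

Cohort indexing convention, used everywhere in the package: six cohorts,

    1–2  egg (two steps to hatch)
    3    nymphs N1–N2      (cannibalizable, success probability k3)
    4    nymphs N3–N4      (cannibalizable, k4)
    5    nymphs N5         (cannibalizable, k5)
    6    young adult female migrating to her own territory

Some schedule tabulations compress this: they write e(tau) for the two egg steps,
number the three cannibalizable nymph classes 1–3, and write a(tau) for the
migrating adult.  That compressed notation maps onto cohorts 1–2, 3–5 and 6
respectively; the 6-cohort indexing is the only one used internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class ParameterError(ValueError):
    """Raised when a parameter field violates its domain constraint."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class ForagingParameters:
    """Parameters of the prey-preference-dependent numerical response.

    Attributes
    ----------
    y : float
        Heterospecific prey available per territory (a count; constant over
        time and identical across territories).
    b : float
        New hatched nymphs produced per consumed heterospecific prey.
    tau_a : float
        Handling time of a conspecific nymph, minutes.
    tau_b : float
        Handling time of a heterospecific prey, minutes.
    tau_s : float
        Searching time per prey encounter, minutes.
    k3, k4, k5 : float
        Probability that a maternal attack on a cohort-3/4/5 nymph succeeds.
    a3, a4, a5 : float
        New hatched nymphs produced per consumed cohort-3/4/5 nymph.
    """

    y: float
    b: float
    tau_a: float
    tau_b: float
    tau_s: float
    k3: float
    k4: float
    k5: float
    a3: float
    a4: float
    a5: float

    def __post_init__(self):
        _validate_foraging(self)

    @property
    def k(self) -> tuple[float, float, float]:
        return (self.k3, self.k4, self.k5)

    @property
    def a(self) -> tuple[float, float, float]:
        return (self.a3, self.a4, self.a5)


@dataclass(frozen=True)
class LifeHistoryConfig:
    """Time discretization and life-history schedule.

    One step is ``unit_days`` days (default 5).  The female forages
    ``activity_minutes_per_unit`` minutes per step (default 4800 = 16 h/day of
    daylight activity over 5 days).  An egg needs ``egg_units`` steps to
    hatch; each of the three cannibalizable nymph classes lasts
    ``nymph_stage_units`` steps; the mother lays eggs and forages for
    ``maternal_reproductive_units`` steps (her reproductive lifespan L) and
    then dies; a matured daughter spends ``migration_units`` steps finding her
    own territory; the reproductive season is ``season_units`` steps long
    (default 50 steps = 250 days, March to October).
    """

    unit_days: int = 5
    activity_minutes_per_unit: int = 4800
    egg_units: int = 2
    nymph_stage_units: int = 1
    maternal_reproductive_units: int = 7
    migration_units: int = 1
    season_units: int = 50

    def __post_init__(self):
        _validate_life_history(self)

    @property
    def maturation_units(self) -> int:
        """Steps from laying to leaving the natal territory (egg + 3 nymph classes)."""
        return self.egg_units + 3 * self.nymph_stage_units

    @property
    def founding_lag(self) -> int:
        """Steps from a cohort's laying age to that daughter founding her own
        territory: maturation, the departure step, then migration."""
        return self.maturation_units + self.migration_units


@dataclass(frozen=True)
class PreyPreference:
    """The decision variables: probability of attacking an encountered prey.

    ``p_a`` applies to conspecific nymphs (the cannibalism rate), ``p_b`` to
    heterospecific prey.
    """

    p_a: float
    p_b: float

    def __post_init__(self):
        for name in ("p_a", "p_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(name, f"must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class CohortState:
    """Counts of the six cohorts at one time step.

    Counts are non-negative reals: the recursion is deterministic and tracks
    expected values, not integer individuals.
    """

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    c5: float = 0.0
    c6: float = 0.0

    def __post_init__(self):
        for name in ("c1", "c2", "c3", "c4", "c5", "c6"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(name, f"cohort count must be >= 0, got {v!r}")

    @property
    def nymphs(self) -> tuple[float, float, float]:
        """The cannibalizable cohorts (3, 4, 5)."""
        return (self.c3, self.c4, self.c5)


def _validate_foraging(fp: ForagingParameters) -> None:
    if fp.y < 0:
        raise ParameterError("y", f"prey availability must be >= 0, got {fp.y!r}")
    for name in ("tau_a", "tau_b", "tau_s"):
        v = getattr(fp, name)
        if not v > 0:
            raise ParameterError(name, f"time must be > 0 minutes, got {v!r}")
    for name in ("k3", "k4", "k5"):
        v = getattr(fp, name)
        if not (0.0 <= v <= 1.0):
            raise ParameterError(name, f"probability must lie in [0, 1], got {v!r}")
    for name in ("b", "a3", "a4", "a5"):
        v = getattr(fp, name)
        if v < 0:
            raise ParameterError(name, f"conversion coefficient must be >= 0, got {v!r}")


def _validate_life_history(lh: LifeHistoryConfig) -> None:
    for f in dataclasses.fields(lh):
        v = getattr(lh, f.name)
        if not isinstance(v, int) or isinstance(v, bool) or v <= 0:
            raise ParameterError(f.name, f"must be a positive integer, got {v!r}")
    minimum = lh.egg_units + 3 * lh.nymph_stage_units + lh.migration_units
    if lh.season_units < minimum:
        raise ParameterError(
            "season_units",
            f"must be >= egg_units + 3 nymph stages + migration_units = {minimum}, "
            f"got {lh.season_units}",
        )


def validate_parameters(
    fp: ForagingParameters, lh: LifeHistoryConfig
) -> tuple[ForagingParameters, LifeHistoryConfig]:
    """Check every invariant of a parameter pair; return it unchanged.

    Raises :class:`ParameterError` naming the offending field.  Idempotent:
    the dataclasses validate on construction, so this re-runs the same checks.
    """
    _validate_foraging(fp)
    _validate_life_history(lh)
    return fp, lh


# ---------------------------------------------------------------------------
# canonical parameter sets (shipped as packaged JSON fixtures)

def _load_fixture(name: str) -> tuple[ForagingParameters, LifeHistoryConfig]:
    with resources.files("filicann.data").joinpath(name).open() as fh:
        return parameters_from_dict(json.load(fh))


def real_parameters() -> tuple[ForagingParameters, LifeHistoryConfig]:
    """The laboratory-estimated parameter set for *N. pseudoferus* preying on
    *S. exigua*, with the default life-history configuration."""
    return _load_fixture("real.json")


def illustrative_parameters() -> tuple[ForagingParameters, LifeHistoryConfig]:
    """The illustrative parameter set in which conspecific nymphs are more
    valuable food than heterospecific prey (cheap to handle, rich in eggs)."""
    return _load_fixture("illustrative.json")


# ---------------------------------------------------------------------------
# flat key-value (JSON) round-trip

def parameters_to_dict(fp: ForagingParameters, lh: LifeHistoryConfig) -> dict:
    d = dataclasses.asdict(fp)
    d.update(dataclasses.asdict(lh))
    return d


def parameters_from_dict(d: dict) -> tuple[ForagingParameters, LifeHistoryConfig]:
    fp_names = {f.name for f in dataclasses.fields(ForagingParameters)}
    lh_names = {f.name for f in dataclasses.fields(LifeHistoryConfig)}
    unknown = set(d) - fp_names - lh_names
    if unknown:
        raise ParameterError(sorted(unknown)[0], "unknown parameter key")
    fp = ForagingParameters(**{k: float(v) for k, v in d.items() if k in fp_names})
    lh = LifeHistoryConfig(**{k: v for k, v in d.items() if k in lh_names})
    return fp, lh


def save_parameters(path: str | Path, fp: ForagingParameters, lh: LifeHistoryConfig) -> None:
    Path(path).write_text(json.dumps(parameters_to_dict(fp, lh), indent=2) + "\n")


def load_parameters(path: str | Path) -> tuple[ForagingParameters, LifeHistoryConfig]:
    return parameters_from_dict(json.loads(Path(path).read_text()))
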