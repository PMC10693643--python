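"""Clean-split demographic model: parameters, priors and the event timeline.

Two populations (labelled CAB and MOZ after the cohorts they emulate)
descend from a single ancestral population.  Moving backwards in time each
branch starts at its present-day diploid size and shrinks/grows
exponentially so that it reaches its split-generation size exactly at the
split; at the split the branches merge, and at a fixed older generation the
ancestral population changes instantaneously to a fixed diploid size.  The
model deliberately has no migration: a clean split is a lower bound for the
separation time of two populations that may in truth have exchanged
migrants while diverging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np


class InvalidParameterError(ValueError):
    """A demographic parameter violates its domain constraints."""


class ConfigError(ValueError):
    """A prior or configuration document is malformed."""


POP_CAB = "CAB"
POP_MOZ = "MOZ"
POP_ANCESTRAL = "ANC"

#: Canonical order of the five free parameters everywhere in the package
#: (reference tables, posterior summaries, CLI output).
PARAM_NAMES = (
    "n_cab_present",
    "n_cab_split",
    "n_moz_present",
    "n_moz_split",
    "gen_split",
)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed quantities of the clean-split model.

    ``n_ancestral_fixed`` and ``gen_ancestral_change`` pin the deep history
    (the ancestral population changes instantaneously to 12,000 diploids at
    generation 7586, after a published composite model of African human
    history) so that only recent parameters are free.  ``mutation_rate`` is
    the human per-bp per-generation rate used throughout;
    ``generation_time_years`` converts generations to years BP at reporting
    time only.
    """

    n_ancestral_fixed: float = 12_000.0
    gen_ancestral_change: float = 7586.0
    mutation_rate: float = 1.25e-8
    generation_time_years: float = 27.0

    def __post_init__(self) -> None:
        if self.gen_ancestral_change <= 0:
            raise InvalidParameterError("gen_ancestral_change must be > 0")
        if self.n_ancestral_fixed <= 0:
            raise InvalidParameterError("n_ancestral_fixed must be > 0")


@dataclass(frozen=True)
class SplitModelParams:
    """The five free parameters of the clean-split model.

    Sizes are diploid effective sizes; ``gen_split`` is the number of
    generations before present at which the two populations merge into the
    ancestral population (time runs backwards, present = 0).
    """

    n_cab_present: float
    n_cab_split: float
    n_moz_present: float
    n_moz_split: float
    gen_split: float

    def validate(self, constants: ModelConstants | None = None) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")
        if constants is not None and not self.gen_split < constants.gen_ancestral_change:
            raise InvalidParameterError(
                f"gen_split ({self.gen_split}) must be < gen_ancestral_change "
                f"({constants.gen_ancestral_change})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "SplitModelParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))


def growth_rate(n_present: float, n_split: float, gen_split: float) -> float:
    """Per-generation exponential rate of a branch, ``log(N/N')/T_split``.

    Positive when the population grew forwards in time toward the present.
    Backwards in time the branch size at time ``t`` is ``N * exp(-alpha*t)``,
    which equals ``N'`` at ``t = gen_split``.
    """
    for name, value in (("n_present", n_present), ("n_split", n_split), ("gen_split", gen_split)):
        if not (math.isfinite(value) and value > 0):
            raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")
    return math.log(n_present / n_split) / gen_split


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

_PRIOR_KINDS = ("uniform", "loguniform")


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: uniform or log-uniform over (low, high)."""

    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in _PRIOR_KINDS:
            raise ConfigError(f"unknown prior kind {self.kind!r}; expected one of {_PRIOR_KINDS}")
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ConfigError("prior bounds must be finite")
        if not self.low < self.high:
            raise ConfigError(f"prior requires low < high, got [{self.low}, {self.high}]")
        if self.kind == "loguniform" and self.low <= 0:
            raise ConfigError("log-uniform prior requires low > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        return 10.0 ** rng.uniform(math.log10(self.low), math.log10(self.high), size=n)


def default_priors(constants: ModelConstants | None = None) -> dict[str, Prior]:
    """Default priors: log-uniform sizes over [100, 100000] diploids, uniform
    split time over [10, 7000] generations (kept below the fixed ancestral
    event).  These are wide, weakly informative ranges spanning plausible
    recent human effective sizes and Holocene split times; override them via
    config when the analysis calls for different ranges."""
    constants = constants or ModelConstants()
    size_prior = Prior("loguniform", 100.0, 100_000.0)
    upper = min(7000.0, constants.gen_ancestral_change - 1.0)
    return {
        "n_cab_present": size_prior,
        "n_cab_split": size_prior,
        "n_moz_present": size_prior,
        "n_moz_split": size_prior,
        "gen_split": Prior("uniform", 10.0, upper),
    }


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter priors for the five free parameters."""

    priors: dict[str, Prior] = field(default_factory=default_priors)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.priors)
        if missing:
            raise ConfigError(f"priors missing for parameters: {sorted(missing)}")
        extra = set(self.priors) - set(PARAM_NAMES)
        if extra:
            raise ConfigError(f"priors given for unknown parameters: {sorted(extra)}")

    def validate_against(self, constants: ModelConstants) -> None:
        if self.priors["gen_split"].high >= constants.gen_ancestral_change:
            raise ConfigError(
                "gen_split prior upper bound must be < gen_ancestral_change "
                f"({constants.gen_ancestral_change})"
            )

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    @classmethod
    def from_dict(cls, doc: dict) -> "PriorSpec":
        priors = {}
        for name, entry in doc.items():
            if not isinstance(entry, dict):
                raise ConfigError(f"prior for {name!r} must be a mapping")
            unknown = set(entry) - {"kind", "low", "high"}
            if unknown:
                raise ConfigError(f"prior for {name!r} has unknown keys {sorted(unknown)}")
            try:
                priors[name] = Prior(entry["kind"], float(entry["low"]), float(entry["high"]))
            except KeyError as exc:
                raise ConfigError(f"prior for {name!r} missing key {exc}") from exc
        return cls(priors)

    def to_dict(self) -> dict:
        return {name: asdict(p) for name, p in self.priors.items()}


def sample_prior(prior: PriorSpec, n: int, seed: int) -> list[SplitModelParams]:
    """Draw ``n`` independent parameter sets from the prior, reproducibly."""
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    columns = {name: prior[name].sample(rng, n) for name in PARAM_NAMES}
    return [
        SplitModelParams(**{name: float(columns[name][i]) for name in PARAM_NAMES})
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimelineEvent:
    time: float
    description: str


@dataclass(frozen=True)
class DemographyTimeline:
    """Backwards-in-time event list of the clean-split model.

    Three epochs: (0, gen_split) with two exponentially changing branches;
    (gen_split, gen_ancestral_change) a single ancestral deme sized as the
    sum of the two merging branch sizes; beyond gen_ancestral_change the
    fixed ancestral size.
    """

    params: SplitModelParams
    constants: ModelConstants
    alpha_cab: float
    alpha_moz: float
    events: tuple[TimelineEvent, ...]

    @property
    def n_ancestral_merge(self) -> float:
        return self.params.n_cab_split + self.params.n_moz_split

    def branch_size(self, pop: str, t: float) -> float:
        """Diploid size of ``pop`` at backwards time ``t`` (generations)."""
        p, c = self.params, self.constants
        if t < 0:
            raise InvalidParameterError("t must be >= 0")
        if t >= c.gen_ancestral_change:
            return c.n_ancestral_fixed
        if t > p.gen_split:  # at the split itself the branch sizes still apply
            return self.n_ancestral_merge
        if pop == POP_CAB:
            return p.n_cab_present * math.exp(-self.alpha_cab * t)
        if pop == POP_MOZ:
            return p.n_moz_present * math.exp(-self.alpha_moz * t)
        raise InvalidParameterError(f"unknown population {pop!r} before the split")

    def to_msprime(self):
        """Materialise as an :class:`msprime.Demography`."""
        import msprime

        p, c = self.params, self.constants
        dem = msprime.Demography()
        dem.add_population(name=POP_CAB, initial_size=p.n_cab_present, growth_rate=self.alpha_cab)
        dem.add_population(name=POP_MOZ, initial_size=p.n_moz_present, growth_rate=self.alpha_moz)
        dem.add_population(name=POP_ANCESTRAL, initial_size=self.n_ancestral_merge)
        dem.add_population_split(time=p.gen_split, derived=[POP_CAB, POP_MOZ], ancestral=POP_ANCESTRAL)
        dem.add_population_parameters_change(
            time=c.gen_ancestral_change, population=POP_ANCESTRAL,
            initial_size=c.n_ancestral_fixed, growth_rate=0.0,
        )
        dem.sort_events()
        return dem


def build_timeline(
    params: SplitModelParams, constants: ModelConstants | None = None
) -> DemographyTimeline:
    """Assemble the three-epoch timeline from free parameters and constants."""
    constants = constants or ModelConstants()
    params.validate(constants)
    alpha_cab = growth_rate(params.n_cab_present, params.n_cab_split, params.gen_split)
    alpha_moz = growth_rate(params.n_moz_present, params.n_moz_split, params.gen_split)
    events = (
        TimelineEvent(0.0, "present: CAB and MOZ at their present-day sizes"),
        TimelineEvent(params.gen_split, "split: CAB and MOZ merge into the ancestral population"),
        TimelineEvent(
            constants.gen_ancestral_change,
            f"ancestral size change to {constants.n_ancestral_fixed:g} diploids",
        ),
    )
    return DemographyTimeline(params, constants, alpha_cab, alpha_moz, events)
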