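"""Piecewise-constant demographic models and parameter derivations.

A :class:`DemographicModel` is a list of named populations with initial
sizes and a time-ordered event list (instantaneous size changes, pastward
population splits, migration-rate changes).  Time is measured in
generations before sampling, with 0 = the present; events are sorted
ascending into the past.  Population sizes are step functions of time
(only instantaneous changes — no growth epochs).

A model may carry a mutation-rate override: the rate a demographic model
was inferred under supersedes the species default when that model is
simulated, so simulated diversity matches the data the model came from.
There is deliberately no recombination-rate override; the QC module flags
recombination-rate inconsistencies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Citation, Contig, ValidationReport

__all__ = [
    "SizeChange",
    "Split",
    "MigrationChange",
    "DemographicModel",
    "derive_Ne_from_theta",
    "rate_discrepancy_percent",
    "rate_discrepancy_rounded",
    "population_size_at",
    "effective_mutation_rate",
    "generations_to_years",
    "validate_model",
    "constant_size_model",
]


@dataclass(frozen=True)
class SizeChange:
    """Instantaneous size change of one population at ``time`` gens ago.

    Looking pastward, the population has size ``new_size`` from ``time``
    until the next older event.
    """

    time: float
    population: str
    new_size: float


@dataclass(frozen=True)
class Split:
    """Pastward merge: lineages in ``derived`` move into ``ancestral``.

    Forwards in time this is the founding of ``derived`` from
    ``ancestral`` at ``time`` generations ago.
    """

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class MigrationChange:
    """Set the (backwards) migration rate source -> dest from ``time`` on.

    ``rate`` is per lineage per generation: the rate at which a lineage
    currently in ``source`` jumps to ``dest`` tracing pastward.
    """

    time: float
    source: str
    dest: str
    rate: float


@dataclass(frozen=True)
class DemographicModel:
    id: str
    populations: tuple
    initial_sizes: dict
    events: tuple = ()
    initial_migration: dict = field(default_factory=dict)  # (src, dst) -> rate
    mutation_rate_override: float | None = None
    citations: tuple = ()
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.time))
        )

    def size_function(self, population: str):
        """Step function for one population: list of (time, size) epochs.

        Returns epochs as (start_time_ago, size), ascending pastward; the
        size at query time t is that of the last epoch with start <= t.
        """
        if population not in self.populations:
            raise ValueError(f"unknown population {population!r}")
        steps = [(0.0, float(self.initial_sizes[population]))]
        for ev in self.events:
            if isinstance(ev, SizeChange) and ev.population == population:
                steps.append((float(ev.time), float(ev.new_size)))
        return steps


# ---------------------------------------------------------------------------
# derivations and audits

def derive_Ne_from_theta(theta: float, mu: float) -> float:
    """Invert theta = 4*mu*Ne for the effective population size.

    ``theta`` is per-site mean nucleotide diversity; ``mu`` the per-bp,
    per-generation mutation rate.  Returns the unrounded Ne; any rounding
    (e.g. to a catalog default) is the caller's documented choice.
    """
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return theta / (4.0 * mu)


def rate_discrepancy_percent(rate_a: float, rate_b: float) -> float:
    """Percent by which ``rate_a`` exceeds ``rate_b``: (a/b - 1) * 100."""
    if rate_b <= 0:
        raise ValueError(f"reference rate must be > 0, got {rate_b}")
    return (rate_a / rate_b - 1.0) * 100.0


def rate_discrepancy_rounded(rate_a: float, rate_b: float) -> int:
    """Integer-percent convenience form (round-half-to-even)."""
    return round(rate_discrepancy_percent(rate_a, rate_b))


def population_size_at(model: DemographicModel, pop: str, t: float) -> float:
    """Population size ``t`` generations ago.

    The size function is piecewise constant with half-open epochs
    [t_event, t_next): exactly at an event time the older (pastward) size
    applies.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    for ev in model.events:
        if isinstance(ev, Split) and ev.derived == pop and t >= ev.time:
            raise ValueError(
                f"population {pop!r} is not extant at time {t} "
                f"(merged into {ev.ancestral!r} at {ev.time})"
            )
    size = None
    for start, value in model.size_function(pop):
        if start <= t:
            size = value
        else:
            break
    return size


def effective_mutation_rate(model: DemographicModel, contig: Contig) -> float:
    """Mutation rate to simulate under: the model's override, else the contig's."""
    if model.mutation_rate_override is not None:
        return model.mutation_rate_override
    if contig.mutation_rate is not None:
        return contig.mutation_rate
    raise ValueError("neither model override nor contig mutation rate present")


def generations_to_years(t: float, generation_time: float) -> float:
    """Convert a time in generations to years."""
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    return t * generation_time


def constant_size_model(Ne: float, population: str = "pop0") -> DemographicModel:
    """Single population of constant size Ne at all times (the catalog
    default used when no demographic model is specified)."""
    if Ne <= 0:
        raise ValueError(f"Ne must be > 0, got {Ne}")
    return DemographicModel(
        id=f"constant_{population}",
        populations=(population,),
        initial_sizes={population: float(Ne)},
    )


# ---------------------------------------------------------------------------
# validation

def validate_model(model: DemographicModel) -> ValidationReport:
    """Collect invariant violations: positive sizes, known populations,
    non-negative rates/times, and a single root after the oldest split."""
    report = ValidationReport()
    pops = set(model.populations)
    if len(pops) != len(model.populations):
        report.add(f"{model.id}: duplicate population names")
    for pop in model.populations:
        if pop not in model.initial_sizes:
            report.add(f"{model.id}: population {pop!r} has no initial size")
        elif model.initial_sizes[pop] <= 0:
            report.add(
                f"{model.id}: initial size of {pop!r} must be > 0, "
                f"got {model.initial_sizes[pop]}"
            )
    for (src, dst), rate in model.initial_migration.items():
        if src not in pops or dst not in pops:
            report.add(f"{model.id}: migration between unknown populations "
                       f"({src!r} -> {dst!r})")
        if rate < 0:
            report.add(f"{model.id}: negative migration rate {src}->{dst}")
    merged = set()
    for ev in model.events:
        if ev.time < 0:
            report.add(f"{model.id}: event at negative time {ev.time}")
        if isinstance(ev, SizeChange):
            if ev.population not in pops:
                report.add(f"{model.id}: size change for unknown population "
                           f"{ev.population!r}")
            if ev.new_size <= 0:
                report.add(f"{model.id}: size change of {ev.population!r} to "
                           f"non-positive size {ev.new_size}")
        elif isinstance(ev, Split):
            for name in (ev.derived, ev.ancestral):
                if name not in pops:
                    report.add(f"{model.id}: split references unknown "
                               f"population {name!r}")
            if ev.derived in merged:
                report.add(f"{model.id}: population {ev.derived!r} merged twice")
            if ev.derived == ev.ancestral:
                report.add(f"{model.id}: population {ev.derived!r} splits "
                           "from itself")
            merged.add(ev.derived)
        elif isinstance(ev, MigrationChange):
            for name in (ev.source, ev.dest):
                if name not in pops:
                    report.add(f"{model.id}: migration change references "
                               f"unknown population {name!r}")
            if ev.rate < 0:
                report.add(f"{model.id}: negative migration rate in change "
                           f"at t={ev.time}")
    roots = pops - merged
    if pops and len(roots) != 1:
        report.add(
            f"{model.id}: expected a single root population after the oldest "
            f"split, found {len(roots)}: {sorted(roots)}"
        )
    if model.mutation_rate_override is not None and model.mutation_rate_override <= 0:
        report.add(f"{model.id}: non-positive mutation_rate_override")
    return report
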