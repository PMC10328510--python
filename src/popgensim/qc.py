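"""Quality control by comparison.

Catalog entries are QC'd by having a second maintainer independently
re-implement the model from the primary literature and then mechanically
comparing the two specifications field by field.  This module implements
that comparison, plus rate-consistency audits between a species' default
rates and the rates a demographic model was inferred under (the kind of
mismatch a mutation-rate override exists to resolve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .catalog import Species
from .demography import (
    DemographicModel,
    MigrationChange,
    SizeChange,
    Split,
    rate_discrepancy_percent,
    rate_discrepancy_rounded,
)

__all__ = [
    "DiscrepancyReport",
    "AuditWarning",
    "compare_models",
    "audit_rate_consistency",
]

DEFAULT_RTOL = 1e-6  # citable constants are transcribed, not computed


@dataclass(frozen=True)
class Discrepancy:
    path: str  # dot-separated, machine-parsable locator
    value_a: object
    value_b: object
    relative_difference: float | None  # None for structural mismatches


@dataclass
class DiscrepancyReport:
    entries: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.entries

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "entries": [
                {
                    "path": e.path,
                    "value_a": e.value_a,
                    "value_b": e.value_b,
                    "relative_difference": e.relative_difference,
                }
                for e in self.entries
            ],
        }


def _close(a: float, b: float, rtol: float) -> bool:
    return math.isclose(a, b, rel_tol=rtol, abs_tol=0.0)


def _rel_diff(a: float, b: float) -> float:
    denom = max(abs(a), abs(b))
    return abs(a - b) / denom if denom > 0 else 0.0


def _event_key(ev):
    if isinstance(ev, SizeChange):
        return ("size_change", ev.population)
    if isinstance(ev, Split):
        return ("split", ev.derived, ev.ancestral)
    if isinstance(ev, MigrationChange):
        return ("migration_change", ev.source, ev.dest)
    return ("unknown",)


def compare_models(
    a: DemographicModel, b: DemographicModel, rtol: float = DEFAULT_RTOL
) -> DiscrepancyReport:
    """Field-by-field comparison of two independently specified models.

    Numeric fields are compared with relative tolerance ``rtol``;
    structural mismatches (differing population sets, unmatched events, an
    override present on one side only) are always reported.  Events are
    aligned by (type, populations involved) and then paired in time order
    within each group.
    """
    if rtol <= 0:
        raise ValueError("rtol must be > 0")
    report = DiscrepancyReport()

    def check(path, va, vb):
        if not _close(va, vb, rtol):
            report.entries.append(Discrepancy(path, va, vb, _rel_diff(va, vb)))

    pops_a, pops_b = set(a.populations), set(b.populations)
    for pop in sorted(pops_a - pops_b):
        report.entries.append(
            Discrepancy(f"populations.{pop}", "present", "absent", None)
        )
    for pop in sorted(pops_b - pops_a):
        report.entries.append(
            Discrepancy(f"populations.{pop}", "absent", "present", None)
        )
    for pop in sorted(pops_a & pops_b):
        check(
            f"initial_sizes.{pop}",
            float(a.initial_sizes[pop]),
            float(b.initial_sizes[pop]),
        )

    keys_a = {}
    keys_b = {}
    for ev in a.events:
        keys_a.setdefault(_event_key(ev), []).append(ev)
    for ev in b.events:
        keys_b.setdefault(_event_key(ev), []).append(ev)
    for key in sorted(set(keys_a) | set(keys_b)):
        group_a = keys_a.get(key, [])
        group_b = keys_b.get(key, [])
        label = ".".join(str(k) for k in key)
        for i, (ea, eb) in enumerate(zip(group_a, group_b)):
            prefix = f"events.{label}.{i}"
            check(f"{prefix}.time", float(ea.time), float(eb.time))
            if isinstance(ea, SizeChange):
                check(f"{prefix}.new_size", float(ea.new_size), float(eb.new_size))
            elif isinstance(ea, MigrationChange):
                check(f"{prefix}.rate", float(ea.rate), float(eb.rate))
        for i in range(min(len(group_a), len(group_b)), max(len(group_a), len(group_b))):
            side_a = "present" if i < len(group_a) else "absent"
            side_b = "present" if i < len(group_b) else "absent"
            report.entries.append(
                Discrepancy(f"events.{label}.{i}", side_a, side_b, None)
            )

    mig_keys = set(a.initial_migration) | set(b.initial_migration)
    for src, dst in sorted(mig_keys):
        check(
            f"initial_migration.{src}.{dst}",
            float(a.initial_migration.get((src, dst), 0.0)),
            float(b.initial_migration.get((src, dst), 0.0)),
        )

    oa, ob = a.mutation_rate_override, b.mutation_rate_override
    if (oa is None) != (ob is None):
        report.entries.append(
            Discrepancy(
                "mutation_rate_override",
                "absent" if oa is None else oa,
                "absent" if ob is None else ob,
                None,
            )
        )
    elif oa is not None:
        check("mutation_rate_override", float(oa), float(ob))
    return report


@dataclass(frozen=True)
class AuditWarning:
    parameter: str  # "mutation_rate" or "recombination_rate"
    assumed: float  # rate the model's inference assumed
    species_value: float  # the species catalog default
    percent: float  # signed discrepancy, species vs assumed
    rounded_percent: int
    resolved: bool  # True if a model override fixes the mismatch

    def message(self) -> str:
        status = "resolved by model override" if self.resolved else "unresolved"
        return (
            f"{self.parameter}: species default {self.species_value:g} vs "
            f"inference assumption {self.assumed:g}: "
            f"{self.rounded_percent}% discrepancy; {status}"
        )


def _species_rate(sp: Species, attr: str) -> float:
    """Representative species-level rate: the most common per-chromosome
    value, preferring non-zero rates (mitochondria carry rate 0)."""
    values = [getattr(c, attr) for c in sp.chromosomes]
    nonzero = [v for v in values if v > 0]
    pool = nonzero if nonzero else values
    best = max(set(pool), key=lambda v: (pool.count(v), -v))
    return best


def audit_rate_consistency(
    model: DemographicModel,
    sp: Species,
    inference_assumptions: dict,
) -> list:
    """Compare species default rates with the rates a model assumed.

    ``inference_assumptions`` may contain ``mutation_rate`` and/or
    ``recombination_rate`` — the rates the model's inference used.  A
    mutation-rate mismatch can be resolved by a model-level override (and
    the warning notes whether this model carries one matching the assumed
    rate); a recombination-rate mismatch cannot, since models carry no
    recombination-rate override, and is always unresolved.
    """
    warnings = []
    if "mutation_rate" in inference_assumptions:
        assumed = float(inference_assumptions["mutation_rate"])
        species_mu = _species_rate(sp, "mutation_rate")
        if not _close(species_mu, assumed, DEFAULT_RTOL):
            override = model.mutation_rate_override
            resolved = override is not None and _close(
                override, assumed, DEFAULT_RTOL
            )
            warnings.append(
                AuditWarning(
                    parameter="mutation_rate",
                    assumed=assumed,
                    species_value=species_mu,
                    percent=rate_discrepancy_percent(species_mu, assumed),
                    rounded_percent=rate_discrepancy_rounded(species_mu, assumed),
                    resolved=resolved,
                )
            )
    if "recombination_rate" in inference_assumptions:
        assumed = float(inference_assumptions["recombination_rate"])
        species_r = _species_rate(sp, "recombination_rate")
        if not _close(species_r, assumed, DEFAULT_RTOL):
            warnings.append(
                AuditWarning(
                    parameter="recombination_rate",
                    assumed=assumed,
                    species_value=species_r,
                    percent=rate_discrepancy_percent(assumed, species_r),
                    rounded_percent=rate_discrepancy_rounded(assumed, species_r),
                    resolved=False,
                )
            )
    return warnings
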