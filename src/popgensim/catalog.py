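"""Species catalog: citable genome parameters and simulation-ready contigs.

The catalog is the curated layer of the simulator: each :class:`Species`
bundles a genome structure (chromosomes with per-chromosome mutation and
recombination rates, and optionally gene-conversion parameters), a default
effective population size, a generation time, and the citations that justify
every number.  Catalogs are plain structured text (YAML) so that parameter
choices are reviewable; unknown keys are hard errors to catch typos in
citable constants.

Only parameters with a documented published source are embedded as
built-ins.  Chromosome lengths are never embedded; they come from
``chrom.sizes`` / ``.fai`` files or from the catalog file itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Citation",
    "Chromosome",
    "Species",
    "Contig",
    "Catalog",
    "ValidationReport",
    "CITATION_REASONS",
    "load_catalog",
    "serialize_catalog",
    "validate_species",
    "make_contig",
    "assemble_pseudochromosomes",
    "builtin_catalog",
]

CATALOG_SCHEMA_VERSION = 1

CITATION_REASONS = frozenset(
    {
        "assembly",
        "mutation_rate",
        "recombination_rate",
        "gene_conversion",
        "demographic_model",
        "generation_time",
        "population_size",
    }
)


class CatalogError(ValueError):
    """Raised for malformed catalog text or invalid catalog queries."""


@dataclass(frozen=True)
class Citation:
    """A published source backing one or more catalog parameters."""

    authors: str
    year: int
    doi_or_url: str
    reasons: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "reasons", frozenset(self.reasons))
        unknown = self.reasons - CITATION_REASONS
        if unknown:
            raise CatalogError(f"unknown citation reason tags: {sorted(unknown)}")


@dataclass(frozen=True)
class Chromosome:
    """One chromosome (or scaffold/pseudo-chromosome) of a species genome.

    ``recombination_rate`` is the crossover rate per bp per generation,
    except when ``non_crossover_only`` is set (bacterial/archaeal mode), in
    which case it is the initiation rate of a non-crossover (homologous
    recombination) tract and ``gene_conversion_length`` gives the mean tract
    length.
    """

    id: str
    length: int | None  # bp; None = supplied at contig time
    mutation_rate: float
    recombination_rate: float
    gene_conversion_fraction: float | None = None
    gene_conversion_length: float | None = None
    non_crossover_only: bool = False


@dataclass(frozen=True)
class Species:
    """A catalog entry: genome structure plus citable species parameters."""

    id: str
    name: str
    chromosomes: tuple
    generation_time: float  # years per generation
    default_Ne: float  # individuals
    ploidy: int = 2
    citations: tuple = ()

    def chromosome(self, chromosome_id: str) -> Chromosome:
        for chrom in self.chromosomes:
            if chrom.id == chromosome_id:
                return chrom
        raise CatalogError(
            f"species {self.id!r} has no chromosome {chromosome_id!r}"
        )


@dataclass(frozen=True)
class Contig:
    """A simulation-ready genomic interval.

    Rates are copied from the source chromosome unless explicitly
    overridden.  ``rate_map`` is a :class:`popgensim.ratemap.RateMap`;
    for chromosomes with a scalar rate it is a single-interval map.
    """

    species_id: str
    chromosome_id: str
    length: int
    mutation_rate: float
    rate_map: "object"  # RateMap
    gene_conversion_fraction: float | None = None
    gene_conversion_length: float | None = None
    non_crossover_only: bool = False
    ploidy: int = 2


@dataclass
class ValidationReport:
    """List of human-readable invariant violations; empty means valid."""

    violations: list = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.passed

    def __iter__(self):
        return iter(self.violations)


Catalog = dict  # species_id -> Species


# ---------------------------------------------------------------------------
# validation

def validate_species(sp: Species) -> ValidationReport:
    """Check every type invariant of a species entry.

    Violations are collected into the report rather than raised, so a
    reviewer sees all problems at once.
    """
    report = ValidationReport()
    if sp.default_Ne <= 0:
        report.add(f"{sp.id}: default_Ne must be > 0, got {sp.default_Ne}")
    if sp.generation_time <= 0:
        report.add(
            f"{sp.id}: generation_time must be > 0, got {sp.generation_time}"
        )
    if sp.ploidy not in (1, 2):
        report.add(f"{sp.id}: ploidy must be 1 or 2, got {sp.ploidy}")
    if len(sp.id) != 6:
        report.add(f"{sp.id}: species id must be a 6-character code")
    seen = set()
    for chrom in sp.chromosomes:
        if chrom.id in seen:
            report.add(f"{sp.id}: duplicate chromosome id {chrom.id!r}")
        seen.add(chrom.id)
        _validate_chromosome(sp.id, chrom, report)
    for cit in sp.citations:
        if not cit.reasons:
            report.add(f"{sp.id}: citation {cit.authors!r} has no reason tags")
        if cit.year <= 1900:
            report.add(f"{sp.id}: citation {cit.authors!r} has year <= 1900")
    return report


def _validate_chromosome(species_id: str, chrom: Chromosome, report: ValidationReport):
    tag = f"{species_id}.{chrom.id}"
    if chrom.length is not None and chrom.length < 1:
        report.add(f"{tag}: length must be >= 1, got {chrom.length}")
    if chrom.mutation_rate < 0:
        report.add(f"{tag}: negative mutation rate {chrom.mutation_rate}")
    if chrom.recombination_rate < 0:
        report.add(f"{tag}: negative recombination rate {chrom.recombination_rate}")
    frac = chrom.gene_conversion_fraction
    if frac is not None:
        if not (0.0 <= frac < 1.0):
            report.add(
                f"{tag}: gene_conversion_fraction must be in [0, 1), got {frac}"
            )
        if chrom.gene_conversion_length is None:
            report.add(
                f"{tag}: gene_conversion_fraction set without gene_conversion_length"
            )
    if chrom.non_crossover_only and chrom.gene_conversion_length is None:
        report.add(
            f"{tag}: non_crossover_only requires gene_conversion_length "
            "(mean tract length)"
        )
    if chrom.gene_conversion_length is not None and chrom.gene_conversion_length < 1:
        report.add(
            f"{tag}: gene_conversion_length must be >= 1 bp, "
            f"got {chrom.gene_conversion_length}"
        )


# ---------------------------------------------------------------------------
# catalog file format

_SPECIES_KEYS = {
    "name",
    "generation_time",
    "default_Ne",
    "ploidy",
    "chromosomes",
    "citations",
}
_CHROM_KEYS = {
    "id",
    "length",
    "mutation_rate",
    "recombination_rate",
    "gene_conversion_fraction",
    "gene_conversion_length",
    "non_crossover_only",
}
_CITATION_KEYS = {"authors", "year", "doi_or_url", "reasons"}
_MANDATORY_SPECIES = {"name", "generation_time", "default_Ne", "chromosomes"}
_MANDATORY_CHROM = {"id", "mutation_rate", "recombination_rate"}


def load_catalog(config_text: str) -> Catalog:
    """Parse catalog text (YAML schema, version 1) into a species map.

    Unknown keys anywhere in the document are errors, not warnings: catalog
    values are citable constants and a typo must not silently vanish.
    Every loaded species must pass :func:`validate_species`.
    """
    doc = yaml.safe_load(config_text)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise CatalogError("catalog document must be a mapping")
    version = doc.pop("schema_version", CATALOG_SCHEMA_VERSION)
    if version != CATALOG_SCHEMA_VERSION:
        raise CatalogError(f"unsupported catalog schema_version {version}")
    entries = doc.pop("species", [])
    if doc:
        raise CatalogError(f"unknown top-level keys: {sorted(doc)}")
    catalog: Catalog = {}
    for entry in entries:
        sp = _parse_species(entry)
        if sp.id in catalog:
            raise CatalogError(f"duplicate species id {sp.id!r}")
        report = validate_species(sp)
        if not report:
            raise CatalogError(
                f"invalid species {sp.id!r}: " + "; ".join(report.violations)
            )
        catalog[sp.id] = sp
    return catalog


def _parse_species(entry: dict) -> Species:
    if not isinstance(entry, dict):
        raise CatalogError("each species entry must be a mapping")
    entry = dict(entry)
    sp_id = entry.pop("id", None)
    if sp_id is None:
        raise CatalogError("species entry missing mandatory field 'id'")
    missing = _MANDATORY_SPECIES - entry.keys()
    if missing:
        raise CatalogError(
            f"species {sp_id!r} missing mandatory field(s): {sorted(missing)}"
        )
    unknown = entry.keys() - _SPECIES_KEYS
    if unknown:
        raise CatalogError(f"species {sp_id!r}: unknown key(s) {sorted(unknown)}")
    chroms = tuple(_parse_chromosome(sp_id, c) for c in entry["chromosomes"])
    citations = tuple(_parse_citation(sp_id, c) for c in entry.get("citations", []))
    return Species(
        id=str(sp_id),
        name=str(entry["name"]),
        chromosomes=chroms,
        generation_time=float(entry["generation_time"]),
        default_Ne=float(entry["default_Ne"]),
        ploidy=int(entry.get("ploidy", 2)),
        citations=citations,
    )


def _parse_chromosome(sp_id, entry: dict) -> Chromosome:
    entry = dict(entry)
    missing = _MANDATORY_CHROM - entry.keys()
    if missing:
        raise CatalogError(
            f"species {sp_id!r} chromosome missing mandatory field(s): "
            f"{sorted(missing)}"
        )
    unknown = entry.keys() - _CHROM_KEYS
    if unknown:
        raise CatalogError(
            f"species {sp_id!r} chromosome {entry.get('id')!r}: "
            f"unknown key(s) {sorted(unknown)}"
        )
    length = entry.get("length")
    gcf = entry.get("gene_conversion_fraction")
    gcl = entry.get("gene_conversion_length")
    return Chromosome(
        id=str(entry["id"]),
        length=None if length is None else int(length),
        mutation_rate=float(entry["mutation_rate"]),
        recombination_rate=float(entry["recombination_rate"]),
        gene_conversion_fraction=None if gcf is None else float(gcf),
        gene_conversion_length=None if gcl is None else float(gcl),
        non_crossover_only=bool(entry.get("non_crossover_only", False)),
    )


def _parse_citation(sp_id, entry: dict) -> Citation:
    entry = dict(entry)
    missing = _CITATION_KEYS - entry.keys()
    if missing:
        raise CatalogError(
            f"species {sp_id!r} citation missing field(s): {sorted(missing)}"
        )
    unknown = entry.keys() - _CITATION_KEYS
    if unknown:
        raise CatalogError(
            f"species {sp_id!r} citation: unknown key(s) {sorted(unknown)}"
        )
    return Citation(
        authors=str(entry["authors"]),
        year=int(entry["year"]),
        doi_or_url=str(entry["doi_or_url"]),
        reasons=frozenset(entry["reasons"]),
    )


def serialize_catalog(catalog: Catalog) -> str:
    """Emit catalog text that :func:`load_catalog` reparses to an equal catalog."""
    entries = []
    for sp in catalog.values():
        chroms = []
        for c in sp.chromosomes:
            d = {
                "id": c.id,
                "mutation_rate": c.mutation_rate,
                "recombination_rate": c.recombination_rate,
            }
            if c.length is not None:
                d["length"] = c.length
            if c.gene_conversion_fraction is not None:
                d["gene_conversion_fraction"] = c.gene_conversion_fraction
            if c.gene_conversion_length is not None:
                d["gene_conversion_length"] = c.gene_conversion_length
            if c.non_crossover_only:
                d["non_crossover_only"] = True
            chroms.append(d)
        cits = [
            {
                "authors": c.authors,
                "year": c.year,
                "doi_or_url": c.doi_or_url,
                "reasons": sorted(c.reasons),
            }
            for c in sp.citations
        ]
        entry = {
            "id": sp.id,
            "name": sp.name,
            "generation_time": sp.generation_time,
            "default_Ne": sp.default_Ne,
            "ploidy": sp.ploidy,
            "chromosomes": chroms,
        }
        if cits:
            entry["citations"] = cits
        entries.append(entry)
    return yaml.safe_dump(
        {"schema_version": CATALOG_SCHEMA_VERSION, "species": entries},
        sort_keys=False,
    )


# ---------------------------------------------------------------------------
# contigs

def make_contig(
    sp: Species,
    chromosome_id: str,
    length_override: int | None = None,
    mutation_rate_override: float | None = None,
    rate_map=None,
) -> Contig:
    """Build a simulation-ready contig from one chromosome of a species.

    The contig inherits the chromosome's rates and gene-conversion
    parameters unless explicitly overridden.  A zero-recombination
    chromosome (e.g. a mitochondrial genome) yields an all-zero rate map.
    """
    from .ratemap import RateMap

    chrom = sp.chromosome(chromosome_id)
    if length_override is not None:
        if length_override < 1:
            raise CatalogError("length_override must be >= 1")
        if chrom.length is not None and length_override > chrom.length:
            raise CatalogError(
                f"length_override {length_override} exceeds chromosome "
                f"{chromosome_id!r} length {chrom.length}"
            )
        length = length_override
    elif chrom.length is not None:
        length = chrom.length
    else:
        raise CatalogError(
            f"chromosome {chromosome_id!r} has no embedded length; "
            "supply length_override (e.g. from a chrom.sizes file)"
        )
    if rate_map is None:
        rate_map = RateMap.uniform(length, chrom.recombination_rate)
    elif rate_map.total_length != length:
        raise CatalogError("rate_map length does not match contig length")
    return Contig(
        species_id=sp.id,
        chromosome_id=chrom.id,
        length=length,
        mutation_rate=(
            chrom.mutation_rate
            if mutation_rate_override is None
            else mutation_rate_override
        ),
        rate_map=rate_map,
        gene_conversion_fraction=chrom.gene_conversion_fraction,
        gene_conversion_length=chrom.gene_conversion_length,
        non_crossover_only=chrom.non_crossover_only,
        ploidy=sp.ploidy,
    )


# ---------------------------------------------------------------------------
# pseudo-chromosome assembly

def assemble_pseudochromosomes(
    contig_lengths: list[int], target_lengths: list[int]
) -> tuple[list[list[int]], list[str]]:
    """Group unplaced contigs into pseudo-chromosomes near target lengths.

    Uses first-fit-decreasing bin packing: contigs are considered longest
    first and placed into the group whose remaining capacity (target minus
    current sum) best accommodates them; ties break on input order, making
    the grouping deterministic.  Every contig is assigned; if the total
    exceeds all targets, overflow groups are still produced and a warning
    is returned.

    Returns ``(groups, warnings)`` where ``groups[j]`` lists the input
    indices assigned to target ``j`` (groups ordered as the targets).
    """
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("all contig lengths must be positive")
    if any(t <= 0 for t in target_lengths):
        raise ValueError("all target lengths must be positive")
    if contig_lengths and not target_lengths:
        raise ValueError("no target lengths given for nonempty contig list")
    groups: list[list[int]] = [[] for _ in target_lengths]
    sums = [0] * len(target_lengths)
    warnings: list[str] = []
    # longest first; stable on input order for equal lengths
    order = sorted(range(len(contig_lengths)), key=lambda i: -contig_lengths[i])
    for i in order:
        length = contig_lengths[i]
        # first group with room left; else the group with most remaining capacity
        best = None
        for j, target in enumerate(target_lengths):
            if sums[j] + length <= target:
                best = j
                break
        if best is None:
            best = max(
                range(len(target_lengths)),
                key=lambda j: (target_lengths[j] - sums[j], -j),
            )
            warnings.append(
                f"contig {i} (length {length}) overflows target {best} "
                f"({target_lengths[best]} bp)"
            )
        groups[best].append(i)
        sums[best] += length
    for g in groups:
        g.sort()
    return groups, warnings


# ---------------------------------------------------------------------------
# built-in entries: only parameters with a published, citable source

#: Placeholder for species fields with no citable published value embedded
#: here.  Any simulation that depends on such a field must override it; the
#: value 1.0 is deliberately implausible rather than a guess.
PLACEHOLDER = 1.0


def builtin_catalog() -> Catalog:
    """The embedded species entries.

    Each entry carries only parameters with a documented published source;
    chromosome lengths are deliberately absent (supply them via
    chrom.sizes/.fai).  Fields for which no citable value is embedded are
    set to :data:`PLACEHOLDER` (or 0.0 for rates) and must be overridden by
    the caller — e.g. the DroMel crossover rate, for which only the
    gene-conversion fraction and tract length are the citable parameters.
    """
    anogam = Species(
        id="AnoGam",
        name="Anopheles gambiae",
        chromosomes=tuple(
            # mutation rate borrowed from D. melanogaster (Dipteran proxy);
            # crossover rate 0.0 = placeholder, supply a map or override
            Chromosome(id=cid, length=None, mutation_rate=3.5e-9,
                       recombination_rate=0.0)
            for cid in ("2L", "2R", "3L", "3R", "X")
        ),
        generation_time=1 / 11,
        default_Ne=1e6,  # theta/(4 mu) = 1.07e6, rounded down to one million
        ploidy=2,
        citations=(
            Citation("Keightley et al.", 2014, "doi:10.1101/gr.170233.113",
                     frozenset({"mutation_rate"})),
            Citation("Miles et al. (Ag1000G)", 2017, "doi:10.1038/nature24995",
                     frozenset({"population_size", "demographic_model",
                                "generation_time"})),
        ),
    )
    bostau_chroms = tuple(
        Chromosome(id=str(i), length=None, mutation_rate=1.2e-8,
                   recombination_rate=9.26e-9)
        for i in range(1, 30)
    ) + (
        Chromosome(id="X", length=None, mutation_rate=1.2e-8,
                   recombination_rate=9.26e-9),
        Chromosome(id="MT", length=None, mutation_rate=1.2e-8,
                   recombination_rate=0.0),
    )
    bostau = Species(
        id="BosTau",
        name="Bos taurus",
        chromosomes=bostau_chroms,
        generation_time=5.0,
        default_Ne=6.2e4,  # ancestral estimate; a detailed model is preferred
        ploidy=2,
        citations=(
            Citation("Rosen et al. (ARS-UCD1.2)", 2020,
                     "doi:10.1093/gigascience/giaa021",
                     frozenset({"assembly"})),
            Citation("Harland et al.", 2017, "doi:10.1101/079863",
                     frozenset({"mutation_rate"})),
            Citation("Ma et al.", 2015, "doi:10.1371/journal.pgen.1005387",
                     frozenset({"recombination_rate"})),
            Citation("MacLeod et al.", 2013, "doi:10.1093/molbev/mst125",
                     frozenset({"population_size", "demographic_model",
                                "generation_time"})),
        ),
    )
    esccol = Species(
        id="EscCol",
        name="Escherichia coli",
        chromosomes=(
            Chromosome(
                id="chromosome",
                length=None,
                mutation_rate=0.0,  # placeholder: supply your own
                recombination_rate=8.9e-11,  # tract-initiation rate
                gene_conversion_length=542.0,
                non_crossover_only=True,
            ),
        ),
        generation_time=PLACEHOLDER,
        default_Ne=PLACEHOLDER,
        ploidy=1,
        citations=(
            Citation("Wielgoss et al.", 2013, "doi:10.1073/pnas.1219574110",
                     frozenset({"recombination_rate", "gene_conversion"})),
            Citation("Didelot et al.", 2012, "doi:10.1093/gbe/evs051",
                     frozenset({"gene_conversion", "recombination_rate"})),
        ),
    )
    dromel = Species(
        id="DroMel",
        name="Drosophila melanogaster",
        chromosomes=tuple(
            # crossover rate 0.0 is a placeholder: callers must supply a map
            # or an override; gc fraction/tract are the citable parameters
            Chromosome(id=cid, length=None, mutation_rate=3.5e-9,
                       recombination_rate=0.0,
                       gene_conversion_fraction=0.83,
                       gene_conversion_length=518.0)
            for cid in ("2L", "2R", "3L", "3R", "X")
        ),
        generation_time=PLACEHOLDER,
        default_Ne=PLACEHOLDER,
        ploidy=2,
        citations=(
            Citation("Keightley et al.", 2014, "doi:10.1101/gr.170233.113",
                     frozenset({"mutation_rate"})),
            Citation("Comeron et al.", 2012, "doi:10.1371/journal.pgen.1002905",
                     frozenset({"gene_conversion"})),
        ),
    )
    return {sp.id: sp for sp in (anogam, bostau, esccol, dromel)}


def with_length(sp: Species, chromosome_id: str, length: int) -> Species:
    """Return a copy of the species with one chromosome's length filled in."""
    chroms = tuple(
        replace(c, length=length) if c.id == chromosome_id else c
        for c in sp.chromosomes
    )
    return replace(sp, chromosomes=chroms)
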