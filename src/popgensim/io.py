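"""Readers and writers for the standard formats the simulator touches.

Internal coordinates are 0-based half-open; VCF is 1-based.  That
conversion is localized here and nowhere else.
"""

from __future__ import annotations

import yaml

from .catalog import Citation, ValidationReport
from .demography import (
    DemographicModel,
    MigrationChange,
    SizeChange,
    Split,
)
from .engine import MarginalTree
from .mutation import VariantTable
from .ratemap import RateMap

__all__ = [
    "read_chrom_sizes",
    "read_hapmap_map",
    "write_vcf",
    "write_newick",
    "load_model",
    "serialize_model",
]

CM_PER_MB_TO_PER_BP = 1e-8  # 1 cM/Mb = 1e-8 crossovers per bp per generation


class FormatError(ValueError):
    pass


def read_chrom_sizes(text: str) -> dict:
    """Parse chrom.sizes (2-column TSV) or FASTA-index .fai text.

    A .fai has 5+ columns; only name and length (columns 1-2) are used.
    Returns a name -> length mapping; malformed lines raise with the line
    number.
    """
    sizes = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"line {lineno}: expected at least 2 tab-separated columns"
            )
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise FormatError(
                f"line {lineno}: length {fields[1]!r} is not an integer"
            ) from None
        if length <= 0:
            raise FormatError(f"line {lineno}: non-positive length {length}")
        if name in sizes:
            raise FormatError(f"line {lineno}: duplicate sequence name {name!r}")
        sizes[name] = length
    return sizes


def read_hapmap_map(text: str, contig_length: int) -> RateMap:
    """Parse a HapMap-style genetic map into a per-bp RateMap.

    Expected columns: chromosome, position (bp), rate (cM/Mb), cumulative
    map position (cM); a header line is tolerated.  The rate on row i
    applies from that row's position to the next row's; positions before
    the first map point take the first interval's rate and positions
    after the last point take the last rate (flanking-interval
    extension).  Breakpoints are clipped to [0, contig_length).
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 columns")
        try:
            pos = int(fields[1])
            rate = float(fields[2])
        except ValueError:
            if not rows and lineno <= 2:
                continue  # header
            raise FormatError(f"line {lineno}: malformed row") from None
        if rate < 0:
            raise FormatError(f"line {lineno}: negative rate {rate}")
        rows.append((pos, rate))
    if not rows:
        raise FormatError("genetic map contains no data rows")
    positions = [p for p, _ in rows]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise FormatError("genetic map positions must be strictly increasing")

    breakpoints = [0]
    rates = []
    for i, (pos, rate) in enumerate(rows):
        per_bp = rate * CM_PER_MB_TO_PER_BP
        if i == 0:
            # [0, next) takes the first interval's rate
            rates.append(per_bp)
        else:
            if pos < contig_length and pos > breakpoints[-1]:
                breakpoints.append(pos)
                rates.append(per_bp)
            elif pos >= contig_length:
                break
    breakpoints.append(contig_length)
    return RateMap(breakpoints, rates)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(
    v: VariantTable,
    sample_names: list,
    contig_id: str = "1",
    contig_length: int | None = None,
    diploid: bool = False,
) -> str:
    """Render a VariantTable as minimal VCF 4.2 text.

    One haploid GT column per sampled sequence by default; with
    ``diploid=True`` consecutive sequences are paired as phased diploid
    genotypes (sample i gets sequences 2i and 2i+1).  ALT alleles are
    listed in first-appearance (mutation-table) order; POS is the internal
    0-based position + 1.
    """
    n_seq = v.haplotypes.shape[0] if v.num_sites else len(sample_names) * (
        2 if diploid else 1
    )
    if diploid:
        if n_seq % 2 != 0:
            raise ValueError("diploid output needs an even number of sequences")
        if len(sample_names) != n_seq // 2:
            raise ValueError(
                f"expected {n_seq // 2} sample names, got {len(sample_names)}"
            )
    elif len(sample_names) != n_seq:
        raise ValueError(
            f"expected {n_seq} sample names, got {len(sample_names)}"
        )
    lines = [
        "##fileformat=VCFv4.2",
        "##source=popgensim",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contig_length is not None:
        lines.append(f"##contig=<ID={contig_id},length={contig_length}>")
    else:
        lines.append(f"##contig=<ID={contig_id}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    for site in range(v.num_sites):
        ref = v.ancestral_states[site]
        alts = v.alleles(site)
        # alleles actually observed but absent from the ALT list (e.g. a
        # derived state reverted everywhere) still need an index if present
        observed = set(v.haplotypes[:, site])
        for state in sorted(observed - {ref} - set(alts)):
            alts.append(state)
        allele_index = {ref: 0}
        allele_index.update({a: i + 1 for i, a in enumerate(alts)})
        codes = [allele_index[s] for s in v.haplotypes[:, site]]
        if diploid:
            gts = [
                f"{codes[2 * i]}|{codes[2 * i + 1]}"
                for i in range(len(sample_names))
            ]
        else:
            gts = [str(c) for c in codes]
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{contig_id}\t{v.positions[site] + 1}\t.\t{ref}\t{alt_field}"
            "\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: MarginalTree, precision: int = 6) -> str:
    """Render a marginal tree as Newick, branch lengths in generations.

    Leaves are named ``s<node id>``; internal nodes are unnamed.  A
    single-leaf tree degenerates to ``s0:0.0;``.
    """
    if not tree.parent:
        (leaf,) = tree.samples
        return f"s{leaf}:0.0;"
    kids = tree.children()

    def render(node):
        blen = tree.branch_length(node)
        if node in kids:
            inner = ",".join(render(c) for c in kids[node])
            return f"({inner}):{blen:.{precision}g}"
        return f"s{node}:{blen:.{precision}g}"

    inner = ",".join(render(c) for c in kids[tree.root])
    return f"({inner});"


# ---------------------------------------------------------------------------
# demographic-model files

_MODEL_KEYS = {
    "id",
    "description",
    "populations",
    "initial_sizes",
    "initial_migration",
    "events",
    "mutation_rate_override",
    "citations",
}


def load_model(text: str) -> DemographicModel:
    """Parse a demographic-model file (YAML schema).

    Events are mappings with a ``type`` of ``size_change``, ``split`` or
    ``migration_change`` plus the fields of that event type.  Unknown keys
    are errors.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FormatError("model document must be a mapping")
    unknown = doc.keys() - _MODEL_KEYS
    if unknown:
        raise FormatError(f"unknown model key(s): {sorted(unknown)}")
    for key in ("id", "populations", "initial_sizes"):
        if key not in doc:
            raise FormatError(f"model missing mandatory field {key!r}")
    events = []
    for i, ev in enumerate(doc.get("events", [])):
        ev = dict(ev)
        kind = ev.pop("type", None)
        try:
            if kind == "size_change":
                events.append(
                    SizeChange(
                        time=float(ev.pop("time")),
                        population=str(ev.pop("population")),
                        new_size=float(ev.pop("new_size")),
                    )
                )
            elif kind == "split":
                events.append(
                    Split(
                        time=float(ev.pop("time")),
                        derived=str(ev.pop("derived")),
                        ancestral=str(ev.pop("ancestral")),
                    )
                )
            elif kind == "migration_change":
                events.append(
                    MigrationChange(
                        time=float(ev.pop("time")),
                        source=str(ev.pop("source")),
                        dest=str(ev.pop("dest")),
                        rate=float(ev.pop("rate")),
                    )
                )
            else:
                raise FormatError(f"event {i}: unknown type {kind!r}")
        except KeyError as exc:
            raise FormatError(f"event {i}: missing field {exc}") from None
        if ev:
            raise FormatError(f"event {i}: unknown key(s) {sorted(ev)}")
    migration = {}
    for entry in doc.get("initial_migration", []):
        migration[(str(entry["source"]), str(entry["dest"]))] = float(
            entry["rate"]
        )
    citations = tuple(
        Citation(
            authors=str(c["authors"]),
            year=int(c["year"]),
            doi_or_url=str(c["doi_or_url"]),
            reasons=frozenset(c["reasons"]),
        )
        for c in doc.get("citations", [])
    )
    override = doc.get("mutation_rate_override")
    return DemographicModel(
        id=str(doc["id"]),
        populations=tuple(str(p) for p in doc["populations"]),
        initial_sizes={
            str(k): float(val) for k, val in doc["initial_sizes"].items()
        },
        events=tuple(events),
        initial_migration=migration,
        mutation_rate_override=None if override is None else float(override),
        citations=citations,
        description=str(doc.get("description", "")),
    )


def serialize_model(model: DemographicModel) -> str:
    """Emit model text that :func:`load_model` reparses equivalently."""
    events = []
    for ev in model.events:
        if isinstance(ev, SizeChange):
            events.append(
                {"type": "size_change", "time": ev.time,
                 "population": ev.population, "new_size": ev.new_size}
            )
        elif isinstance(ev, Split):
            events.append(
                {"type": "split", "time": ev.time, "derived": ev.derived,
                 "ancestral": ev.ancestral}
            )
        elif isinstance(ev, MigrationChange):
            events.append(
                {"type": "migration_change", "time": ev.time,
                 "source": ev.source, "dest": ev.dest, "rate": ev.rate}
            )
    doc = {
        "id": model.id,
        "populations": list(model.populations),
        "initial_sizes": dict(model.initial_sizes),
    }
    if model.description:
        doc["description"] = model.description
    if events:
        doc["events"] = events
    if model.initial_migration:
        doc["initial_migration"] = [
            {"source": s, "dest": d, "rate": r}
            for (s, d), r in model.initial_migration.items()
        ]
    if model.mutation_rate_override is not None:
        doc["mutation_rate_override"] = model.mutation_rate_override
    if model.citations:
        doc["citations"] = [
            {"authors": c.authors, "year": c.year, "doi_or_url": c.doi_or_url,
             "reasons": sorted(c.reasons)}
            for c in model.citations
        ]
    return yaml.safe_dump(doc, sort_keys=False)
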