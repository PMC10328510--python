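"""Structured-coalescent ancestry simulator.

Simulates the genealogy of a sample of sequences backwards in time under a
piecewise-constant demographic model, with three recombination-class
processes layered on Hudson-style ancestral-material tracking:

* **crossover recombination** under a genomic rate map: a lineage splits at
  a breakpoint into left and right parental lineages;
* **gene conversion** (eukaryotic non-crossover recombination): a short
  tract, geometric in length, is transferred; the lineage splits into
  tract and non-tract parents.  The gene-conversion initiation rate is
  derived from the crossover rate and the configured fraction ``f`` of
  recombination events that are conversions, as ``r * f / (1 - f)`` —
  the crossover rate itself is not reduced;
* **bacterial non-crossover recombination**: crossovers are disabled and
  the chromosome's recombination rate is interpreted directly as the
  initiation rate of a recombined tract.

Each live lineage carries a sorted list of disjoint ancestral segments,
each mapped to an output node and annotated with the number of sampled
genomes beneath it.  Common-ancestor events merge two lineages; where
their material overlaps a new node is created and edges recorded, and a
segment ancestral to the whole sample is retired.  The result is a
node/edge table encoding every marginal tree (no unary nodes), plus an
event log supporting rate audits (e.g. the drawn gene-conversion fraction).

Rate conventions: the pairwise coalescence rate within a population of
size ``N`` is ``1 / (ploidy * N)`` per generation — ``1/(2N)`` for
diploids, so that expected pairwise diversity is ``4*N*mu``, and ``1/N``
for haploids/bacteria.  Waiting times are competitive exponentials,
redrawn at every demographic-event boundary (valid by memorylessness).
Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import Contig
from .demography import (
    DemographicModel,
    MigrationChange,
    SizeChange,
    Split,
    validate_model,
)

__all__ = [
    "Genealogy",
    "EventLog",
    "MarginalTree",
    "gc_initiation_rate",
    "sample_tract_length",
    "simulate_ancestry",
    "marginal_tree",
]

# totals of per-lineage rates are maintained incrementally; refresh exactly
# from the per-lineage caches every this-many events to kill float drift
_REFRESH_INTERVAL = 512


# ---------------------------------------------------------------------------
# small parameter helpers

def gc_initiation_rate(crossover_rate: float, fraction: float) -> float:
    """Gene-conversion initiation rate implied by the conversion fraction.

    If a fraction ``f`` of recombination-class events are conversions and
    crossovers occur at ``r`` per bp per generation, conversions initiate
    at ``r * f / (1 - f)`` per bp per generation (e.g. f = 0.83 gives an
    83:17 event ratio).  The crossover rate is unchanged.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    return crossover_rate * fraction / (1.0 - fraction)


def sample_tract_length(mean: float, rng: np.random.Generator) -> int:
    """Draw a conversion-tract length, geometric on {1, 2, ...}.

    The geometric distribution is the memoryless discrete choice for a
    process specified only by its average tract length; success
    probability 1/mean gives expectation exactly ``mean``.
    """
    if mean < 1:
        raise ValueError(f"mean tract length must be >= 1, got {mean}")
    return int(rng.geometric(1.0 / mean))


# ---------------------------------------------------------------------------
# output containers

@dataclass
class Genealogy:
    """Node/edge tables encoding all marginal trees of a simulated sample.

    ``node_times[i]`` is the age (generations ago) of node ``i``; samples
    are nodes ``0 .. n-1`` at time 0.  Each edge ``(parent, child, left,
    right)`` states that ``parent`` is the immediate ancestor of ``child``
    on the genomic interval ``[left, right)``.
    """

    node_times: list
    edges_parent: list
    edges_child: list
    edges_left: list
    edges_right: list
    samples: list
    contig_length: int

    @property
    def num_nodes(self) -> int:
        return len(self.node_times)

    @property
    def num_edges(self) -> int:
        return len(self.edges_parent)

    def breakpoints(self) -> list:
        """Sorted positions at which the marginal tree may change,
        including 0 and the contig length."""
        pts = {0, self.contig_length}
        pts.update(self.edges_left)
        pts.update(self.edges_right)
        return sorted(p for p in pts if 0 <= p <= self.contig_length)


@dataclass
class EventLog:
    """Counts and timestamped records of engine events.

    ``*_drawn`` counts every event the competing-rates machinery fired;
    ``*_effective`` counts only those that actually split ancestral
    material.  Sampled gene-conversion tract lengths are kept for rate
    audits.
    """

    coalescence: int = 0
    common_ancestor: int = 0  # includes merges with no overlapping material
    crossover_drawn: int = 0
    crossover_effective: int = 0
    gc_drawn: int = 0
    gc_effective: int = 0
    migration: int = 0
    tract_lengths: list = field(default_factory=list)
    records: list = field(default_factory=list)  # (time, event type)

    def counts(self) -> dict:
        return {
            "coalescence": self.coalescence,
            "common_ancestor": self.common_ancestor,
            "crossover_drawn": self.crossover_drawn,
            "crossover_effective": self.crossover_effective,
            "gc_drawn": self.gc_drawn,
            "gc_effective": self.gc_effective,
            "migration": self.migration,
        }

    def to_tsv(self) -> str:
        lines = ["event\tcount"]
        lines += [f"{k}\t{v}" for k, v in self.counts().items()]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ancestry tracking

@dataclass
class _Segment:
    """Half-open interval of ancestral material carried by a lineage."""

    left: int
    right: int
    node: int  # output node this material belongs to
    nsamp: int  # sampled genomes beneath it

    def copy(self):
        return _Segment(self.left, self.right, self.node, self.nsamp)


class _Lineage:
    __slots__ = ("population", "segments", "cross_mass", "gc_rate")

    def __init__(self, population, segments):
        self.population = population
        self.segments = segments
        self.cross_mass = 0.0
        self.gc_rate = 0.0

    @property
    def span(self):
        return self.segments[0].left, self.segments[-1].right


def _split_at(segments, b):
    """Split material strictly before / from position b."""
    left, right = [], []
    for seg in segments:
        if seg.right <= b:
            left.append(seg)
        elif seg.left >= b:
            right.append(seg)
        else:
            left.append(_Segment(seg.left, b, seg.node, seg.nsamp))
            right.append(_Segment(b, seg.right, seg.node, seg.nsamp))
    return left, right


def _split_tract(segments, start, end):
    """Split material inside / outside the tract [start, end)."""
    inside, outside = [], []
    for seg in segments:
        if seg.right <= start or seg.left >= end:
            outside.append(seg)
            continue
        if seg.left < start:
            outside.append(_Segment(seg.left, start, seg.node, seg.nsamp))
        inside.append(
            _Segment(max(seg.left, start), min(seg.right, end), seg.node, seg.nsamp)
        )
        if seg.right > end:
            outside.append(_Segment(end, seg.right, seg.node, seg.nsamp))
    return inside, outside


def _squash(segments):
    """Merge adjacent segments with identical node and sample count."""
    out = []
    for seg in segments:
        if (
            out
            and out[-1].right == seg.left
            and out[-1].node == seg.node
            and out[-1].nsamp == seg.nsamp
        ):
            out[-1].right = seg.right
        else:
            out.append(seg)
    return out


class _Simulator:
    def __init__(self, samples, contig, model, seed, gene_conversion):
        report = validate_model(model)
        if not report:
            raise ValueError(
                "invalid demographic model: " + "; ".join(report.violations)
            )
        for pop, count in samples.items():
            if pop not in model.populations:
                raise ValueError(f"unknown sample population {pop!r}")
            if count < 1:
                raise ValueError(f"sample count for {pop!r} must be >= 1")
        if contig.length < 1:
            raise ValueError("contig length must be >= 1")
        self.contig = contig
        self.model = model
        self.L = contig.length
        self.ploidy = contig.ploidy
        self.rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(0,))
        )
        self.log = EventLog()

        # recombination-class configuration
        self.rate_map = contig.rate_map
        if contig.non_crossover_only:
            if contig.gene_conversion_length is None:
                raise ValueError(
                    "non_crossover_only requires a mean tract length"
                )
            # recombination rate is the tract-initiation rate
            self.gc_rate_per_bp = float(contig.rate_map.total_mass) / self.L
            self.gc_mean_tract = float(contig.gene_conversion_length)
            self.crossover_on = False
            self.gc_on = True
        elif gene_conversion:
            if (
                contig.gene_conversion_fraction is None
                or contig.gene_conversion_length is None
            ):
                raise ValueError(
                    "gene conversion requested but the contig has no "
                    "gene_conversion_fraction / gene_conversion_length"
                )
            mean_cross = contig.rate_map.total_mass / self.L
            self.gc_rate_per_bp = gc_initiation_rate(
                mean_cross, contig.gene_conversion_fraction
            )
            self.gc_mean_tract = float(contig.gene_conversion_length)
            self.crossover_on = True
            self.gc_on = True
        else:
            self.gc_rate_per_bp = 0.0
            self.gc_mean_tract = None
            self.crossover_on = True
            self.gc_on = False

        # initial lineages: one per sampled genome, one segment spanning
        # the whole contig
        self.n_total = sum(samples.values())
        node = 0
        self.node_times = []
        self.ep, self.ec, self.el, self.er = [], [], [], []
        self.lineages = {}
        self.by_pop = {p: [] for p in model.populations}
        self._next_lineage_id = 0
        self.total_cross = 0.0
        self.total_gc = 0.0
        for pop in model.populations:
            for _ in range(samples.get(pop, 0)):
                self.node_times.append(0.0)
                lin = _Lineage(pop, [_Segment(0, self.L, node, 1)])
                self._add_lineage(lin)
                node += 1
        self.samples = list(range(node))

        # demographic state
        self.sizes = {p: float(s) for p, s in model.initial_sizes.items()}
        self.migration = dict(model.initial_migration)
        self.pop_alive = {p: True for p in model.populations}
        self.pending = list(model.events)  # already time-sorted

    # -- lineage bookkeeping ------------------------------------------------

    def _lineage_rates(self, lin):
        left, right = lin.span
        cross = self.rate_map.mass(left, right) if self.crossover_on else 0.0
        gc = self.gc_rate_per_bp * (right - left) if self.gc_on else 0.0
        return cross, gc

    def _add_lineage(self, lin):
        lid = self._next_lineage_id
        self._next_lineage_id += 1
        lin.cross_mass, lin.gc_rate = self._lineage_rates(lin)
        self.lineages[lid] = lin
        self.by_pop[lin.population].append(lid)
        self.total_cross += lin.cross_mass
        self.total_gc += lin.gc_rate
        return lid

    def _remove_lineage(self, lid):
        lin = self.lineages.pop(lid)
        self.by_pop[lin.population].remove(lid)
        self.total_cross -= lin.cross_mass
        self.total_gc -= lin.gc_rate
        return lin

    def _refresh_totals(self):
        self.total_cross = sum(l.cross_mass for l in self.lineages.values())
        self.total_gc = sum(l.gc_rate for l in self.lineages.values())

    # -- demographic events -------------------------------------------------

    def _apply_demographic(self, ev):
        if isinstance(ev, SizeChange):
            self.sizes[ev.population] = float(ev.new_size)
        elif isinstance(ev, MigrationChange):
            self.migration[(ev.source, ev.dest)] = float(ev.rate)
        elif isinstance(ev, Split):
            # pastward: lineages in the derived population move to the
            # ancestral one; the derived population ceases to exist
            moved = list(self.by_pop[ev.derived])
            for lid in moved:
                lin = self.lineages[lid]
                self.by_pop[ev.derived].remove(lid)
                lin.population = ev.ancestral
                self.by_pop[ev.ancestral].append(lid)
            self.pop_alive[ev.derived] = False
            # incoming/outgoing migration involving a dead population stops
            for key in list(self.migration):
                if ev.derived in key:
                    self.migration[key] = 0.0

    # -- event kernels ------------------------------------------------------

    def _merge(self, lin_a, lin_b, t):
        """Common-ancestor event: merge two lineages at time t."""
        a, b = lin_a.segments, lin_b.segments
        out = []
        pieces = []  # (left, right, child_node, child_node2, count)
        i = j = 0
        sa = a[i].copy() if a else None
        sb = b[j].copy() if b else None
        while sa is not None and sb is not None:
            if sa.left > sb.left:
                sa, sb = sb, sa
                a, b = b, a
                i, j = j, i
            # sa starts first (or tied)
            if sa.right <= sb.left:
                out.append(sa)
                i += 1
                sa = a[i].copy() if i < len(a) else None
                continue
            if sa.left < sb.left:
                out.append(_Segment(sa.left, sb.left, sa.node, sa.nsamp))
                sa.left = sb.left
            r = min(sa.right, sb.right)
            pieces.append((sa.left, r, sa.node, sb.node, sa.nsamp + sb.nsamp))
            if sa.right > r:
                sa.left = r
            else:
                i += 1
                sa = a[i].copy() if i < len(a) else None
            if sb.right > r:
                sb.left = r
            else:
                j += 1
                sb = b[j].copy() if j < len(b) else None
        while sa is not None:
            out.append(sa)
            i += 1
            sa = a[i].copy() if i < len(a) else None
        while sb is not None:
            out.append(sb)
            j += 1
            sb = b[j].copy() if j < len(b) else None

        self.log.common_ancestor += 1
        if pieces:
            parent = len(self.node_times)
            self.node_times.append(t)
            self.log.coalescence += 1
            self.log.records.append((t, "coalescence"))
            # record edges, squashing contiguous pieces per child
            edge_buf = {}
            for left, right, na, nb, cnt in pieces:
                for child in (na, nb):
                    key = child
                    if key in edge_buf and edge_buf[key][-1][1] == left:
                        edge_buf[key][-1] = (edge_buf[key][-1][0], right)
                    else:
                        edge_buf.setdefault(key, []).append((left, right))
                if cnt < self.n_total:
                    out.append(_Segment(left, right, parent, cnt))
            for child, intervals in edge_buf.items():
                for left, right in intervals:
                    self.ep.append(parent)
                    self.ec.append(child)
                    self.el.append(left)
                    self.er.append(right)
        out.sort(key=lambda s: s.left)
        return _squash(out)

    def _do_coalescence(self, pop, t):
        ids = self.by_pop[pop]
        k = len(ids)
        ai = int(self.rng.integers(k))
        bi = int(self.rng.integers(k - 1))
        if bi >= ai:
            bi += 1
        lid_a, lid_b = ids[ai], ids[bi]
        lin_a = self._remove_lineage(lid_a)
        lin_b = self._remove_lineage(lid_b)
        merged = self._merge(lin_a, lin_b, t)
        if merged:
            self._add_lineage(_Lineage(pop, merged))

    def _pick_weighted_lineage(self, attr):
        ids = list(self.lineages.keys())
        weights = np.array(
            [getattr(self.lineages[lid], attr) for lid in ids], dtype=float
        )
        total = weights.sum()
        u = self.rng.random() * total
        idx = int(np.searchsorted(np.cumsum(weights), u, side="right"))
        return ids[min(idx, len(ids) - 1)]

    def _do_crossover(self, t):
        self.log.crossover_drawn += 1
        self.log.records.append((t, "crossover"))
        lid = self._pick_weighted_lineage("cross_mass")
        lin = self.lineages[lid]
        left, right = lin.span
        b = self.rate_map.sample_position(left, right, self.rng.random())
        seg_l, seg_r = _split_at(lin.segments, b)
        if not seg_l or not seg_r:
            return  # drawn but ineffective: nothing split
        self.log.crossover_effective += 1
        pop = lin.population
        self._remove_lineage(lid)
        self._add_lineage(_Lineage(pop, seg_l))
        self._add_lineage(_Lineage(pop, seg_r))

    def _do_gene_conversion(self, t):
        self.log.gc_drawn += 1
        self.log.records.append((t, "gene_conversion"))
        lid = self._pick_weighted_lineage("gc_rate")
        lin = self.lineages[lid]
        left, right = lin.span
        start = int(left + self.rng.integers(right - left))
        tract = sample_tract_length(self.gc_mean_tract, self.rng)
        self.log.tract_lengths.append(tract)
        end = min(start + tract, right)  # truncated at the span end
        inside, outside = _split_tract(lin.segments, start, end)
        if not inside or not outside:
            return  # ineffective: tract misses material or covers it all
        self.log.gc_effective += 1
        pop = lin.population
        self._remove_lineage(lid)
        self._add_lineage(_Lineage(pop, inside))
        self._add_lineage(_Lineage(pop, outside))

    def _do_migration(self, pop, t):
        self.log.migration += 1
        self.log.records.append((t, "migration"))
        ids = self.by_pop[pop]
        lid = ids[int(self.rng.integers(len(ids)))]
        dests = [
            (dst, rate)
            for (src, dst), rate in self.migration.items()
            if src == pop and rate > 0
        ]
        dests.sort()
        total = sum(rate for _, rate in dests)
        u = self.rng.random() * total
        acc = 0.0
        dest = dests[-1][0]
        for name, rate in dests:
            acc += rate
            if u < acc:
                dest = name
                break
        lin = self.lineages[lid]
        self.by_pop[pop].remove(lid)
        lin.population = dest
        self.by_pop[dest].append(lid)

    # -- main loop ----------------------------------------------------------

    def run(self):
        t = 0.0
        steps = 0
        while self.lineages:
            steps += 1
            if steps % _REFRESH_INTERVAL == 0:
                self._refresh_totals()
            # per-population coalescence and migration rates
            coal = []
            mig = []
            for pop in self.model.populations:
                k = len(self.by_pop[pop])
                if k == 0:
                    continue
                size = self.sizes[pop]
                if size <= 0:
                    raise RuntimeError(
                        f"population {pop!r} has zero size at time {t} "
                        "while hosting lineages"
                    )
                if k >= 2:
                    coal.append(
                        (pop, k * (k - 1) / 2.0 / (self.ploidy * size))
                    )
                out_rate = sum(
                    rate
                    for (src, _), rate in self.migration.items()
                    if src == pop
                )
                if out_rate > 0:
                    mig.append((pop, k * out_rate))
            total_cross = max(self.total_cross, 0.0)
            total_gc = max(self.total_gc, 0.0)
            total = (
                sum(r for _, r in coal)
                + sum(r for _, r in mig)
                + total_cross
                + total_gc
            )
            t_next = self.pending[0].time if self.pending else None
            if total <= 0:
                if t_next is None:
                    raise RuntimeError(
                        "no events possible but lineages remain "
                        "(disconnected populations?)"
                    )
                t = max(t, t_next)
                self._apply_pending(t)
                continue
            wait = self.rng.exponential(1.0 / total)
            if t_next is not None and t + wait >= t_next:
                # advance to the boundary and redraw (memorylessness)
                t = t_next
                self._apply_pending(t)
                continue
            t += wait
            # competitive choice; fixed priority order breaks float ties
            u = self.rng.random() * total
            acc = 0.0
            chosen = None
            for pop, rate in coal:
                acc += rate
                if u < acc:
                    chosen = ("coal", pop)
                    break
            if chosen is None:
                for pop, rate in mig:
                    acc += rate
                    if u < acc:
                        chosen = ("migration", pop)
                        break
            if chosen is None and u < acc + total_cross:
                chosen = ("crossover", None)
            if chosen is None:
                chosen = ("gc", None)
            kind, pop = chosen
            if kind == "coal":
                self._do_coalescence(pop, t)
            elif kind == "migration":
                self._do_migration(pop, t)
            elif kind == "crossover":
                self._do_crossover(t)
            else:
                self._do_gene_conversion(t)
        genealogy = Genealogy(
            node_times=self.node_times,
            edges_parent=self.ep,
            edges_child=self.ec,
            edges_left=self.el,
            edges_right=self.er,
            samples=self.samples,
            contig_length=self.L,
        )
        return genealogy, self.log

    def _apply_pending(self, t):
        while self.pending and self.pending[0].time <= t:
            self._apply_demographic(self.pending.pop(0))


def simulate_ancestry(
    samples: dict,
    contig: Contig,
    model: DemographicModel,
    seed: int,
    gene_conversion: bool = False,
):
    """Simulate the genealogy of a sample on a contig under a model.

    Parameters
    ----------
    samples
        Map population name -> number of sampled genomes (haploid
        sequences) at time 0.
    contig
        The genomic interval to simulate, carrying the crossover rate map
        and optional gene-conversion parameters.
    model
        Piecewise-constant demographic model; must validate.
    seed
        Root seed.  Ancestry uses a named substream so that mutation
        layering (a separate substream of the same root) is reproducible
        independent of event interleaving.
    gene_conversion
        Enable eukaryotic gene conversion (off by default; it carries a
        substantial computational cost).  Ignored for bacterial-mode
        contigs, where non-crossover recombination is the only
        recombination class and is always on.

    Returns
    -------
    (Genealogy, EventLog)
        Fully deterministic given the inputs and seed.
    """
    if sum(samples.values()) == 1:
        # degenerate single-genome sample: one node, no edges
        (pop,) = [p for p, c in samples.items() if c == 1]
        if pop not in model.populations:
            raise ValueError(f"unknown sample population {pop!r}")
        return (
            Genealogy(
                node_times=[0.0],
                edges_parent=[],
                edges_child=[],
                edges_left=[],
                edges_right=[],
                samples=[0],
                contig_length=contig.length,
            ),
            EventLog(),
        )
    sim = _Simulator(samples, contig, model, seed, gene_conversion)
    return sim.run()


# ---------------------------------------------------------------------------
# marginal trees

@dataclass
class MarginalTree:
    """Rooted tree at one genomic position, branch lengths in generations."""

    parent: dict  # child node -> parent node
    node_times: dict  # node -> time (generations ago)
    samples: list
    root: int

    def children(self) -> dict:
        kids = {}
        for c, p in self.parent.items():
            kids.setdefault(p, []).append(c)
        for v in kids.values():
            v.sort()
        return kids

    def branch_length(self, node: int) -> float:
        if node == self.root:
            return 0.0
        return self.node_times[self.parent[node]] - self.node_times[node]

    def path_to_root(self, node: int) -> list:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def tmrca(self, a: int, b: int) -> float:
        anc_a = set(self.path_to_root(a))
        node = b
        while node not in anc_a:
            node = self.parent[node]
        return self.node_times[node]

    def leaves_below(self, node: int) -> list:
        kids = self.children()
        stack, out = [node], []
        while stack:
            x = stack.pop()
            if x in kids:
                stack.extend(kids[x])
            else:
                out.append(x)
        return sorted(out)


def marginal_tree(g: Genealogy, position: int) -> MarginalTree:
    """The genealogical tree over all samples at one genomic position."""
    if not (0 <= position < g.contig_length):
        raise ValueError(
            f"position {position} outside [0, {g.contig_length})"
        )
    parent = {}
    for p, c, l, r in zip(
        g.edges_parent, g.edges_child, g.edges_left, g.edges_right
    ):
        if l <= position < r:
            parent[c] = p
    times = {}
    for node in list(parent) + list(parent.values()) + list(g.samples):
        times[node] = g.node_times[node]
    if len(g.samples) == 1:
        return MarginalTree(
            parent={}, node_times=times, samples=list(g.samples),
            root=g.samples[0],
        )
    node = g.samples[0]
    while node in parent:
        node = parent[node]
    return MarginalTree(
        parent=parent, node_times=times, samples=list(g.samples), root=node
    )
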