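"""Discrete-site Jukes–Cantor mutation layered onto a genealogy.

Mutations fall on edges as a Poisson process with mass
``mu * (edge genomic span in bp) * (branch length in generations)`` and
land on an integer site within the edge's interval, at a uniform time on
the branch.  Sites are finite and discrete, so recurrent mutation is
possible and a site may segregate more than two alleles; colliding
mutations are retained, never rejected.

The derived state of each mutation is uniform over the three nucleotides
other than the state immediately above it on the lineage (the Jukes–Cantor
kernel); the ancestral state of each site is uniform over {A, C, G, T}
(the JC stationary distribution), or fixed to 'A' for deterministic
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Genealogy, marginal_tree

__all__ = ["Mutation", "VariantTable", "throw_mutations", "genotypes"]

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Mutation:
    site: int  # index into VariantTable.sites
    edge: int  # index into the genealogy's edge table
    node: int  # child node of that edge (lineage carrying the mutation)
    time: float  # generations ago
    derived_state: str


@dataclass
class VariantTable:
    """Sites, mutations, and the resulting sample haplotypes."""

    positions: list  # strictly increasing bp
    ancestral_states: list  # one nucleotide per site
    mutations: list  # of Mutation
    haplotypes: np.ndarray = field(default=None)  # samples x sites, '<U1'

    @property
    def num_sites(self) -> int:
        return len(self.positions)

    def alleles(self, site: int) -> list:
        """Distinct derived alleles at a site, in first-appearance order
        (mutation-table order)."""
        out = []
        for m in self.mutations:
            if m.site == site and m.derived_state not in out:
                if m.derived_state != self.ancestral_states[site]:
                    out.append(m.derived_state)
        return out


def throw_mutations(
    g: Genealogy,
    mu: float,
    seed: int,
    fixed_ancestral_state: str | None = None,
) -> VariantTable:
    """Throw Jukes–Cantor mutations onto a genealogy.

    Uses a dedicated RNG substream (spawn key 1) of the root seed, so the
    mutation layer is reproducible independent of how ancestry events
    interleaved.  ``fixed_ancestral_state`` pins every site's ancestral
    state (deterministic-fixture mode) instead of drawing it uniformly.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    raw = []  # (position, edge index, child node, time)
    for e in range(g.num_edges):
        left = g.edges_left[e]
        right = g.edges_right[e]
        child = g.edges_child[e]
        blen = g.node_times[g.edges_parent[e]] - g.node_times[child]
        mass = mu * (right - left) * blen
        if mass <= 0:
            continue
        count = rng.poisson(mass)
        for _ in range(count):
            pos = int(left + rng.integers(right - left))
            time = g.node_times[child] + rng.random() * blen
            raw.append((pos, e, child, time))

    positions = sorted({pos for pos, *_ in raw})
    site_index = {pos: i for i, pos in enumerate(positions)}
    if fixed_ancestral_state is not None:
        if fixed_ancestral_state not in NUCLEOTIDES:
            raise ValueError("ancestral state must be one of A, C, G, T")
        ancestral = [fixed_ancestral_state] * len(positions)
    else:
        draws = rng.integers(4, size=len(positions))
        ancestral = [NUCLEOTIDES[i] for i in draws]

    # assign derived states oldest-first per site, so each mutation knows
    # the state immediately above it on the lineage
    mutations = []
    by_site = {}
    for pos, e, child, time in raw:
        by_site.setdefault(site_index[pos], []).append((time, e, child))
    placed = {}  # site -> list of (time, node, derived) already assigned
    for site in sorted(by_site):
        pos = positions[site]
        tree = marginal_tree(g, pos)
        placed[site] = []
        for time, e, child in sorted(by_site[site], reverse=True):
            above = _state_above(
                tree, child, time, ancestral[site], placed[site]
            )
            choices = [n for n in NUCLEOTIDES if n != above]
            derived = choices[int(rng.integers(3))]
            mutations.append(Mutation(site, e, child, time, derived))
            placed[site].append((time, child, derived))
    mutations.sort(key=lambda m: (m.site, -m.time))
    table = VariantTable(
        positions=positions, ancestral_states=ancestral, mutations=mutations
    )
    table.haplotypes = genotypes(table, g)
    return table


def _state_above(tree, node, time, ancestral, older):
    """State just above ``time`` on the lineage through ``node``,
    given older mutations already placed at this site."""
    path = set(tree.path_to_root(node))
    best = None
    for m_time, m_node, m_state in older:
        if m_node in path and m_time > time:
            if best is None or m_time < best[0]:
                best = (m_time, m_state)
    return ancestral if best is None else best[1]


def genotypes(v: VariantTable, g: Genealogy) -> np.ndarray:
    """Haplotype matrix (samples x sites) implied by the mutations.

    The state of a sample at a site is the ancestral state modified by
    every mutation on the sample's path to the root at that position,
    applied root-to-tip (the youngest mutation on the path wins).
    """
    n = len(g.samples)
    out = np.empty((n, v.num_sites), dtype="<U1")
    by_site = {}
    for m in v.mutations:
        by_site.setdefault(m.site, []).append(m)
    for site, pos in enumerate(v.positions):
        tree = marginal_tree(g, pos)
        muts = by_site.get(site, [])
        for i, sample in enumerate(g.samples):
            path = set(tree.path_to_root(sample))
            best = None
            for m in muts:
                if m.node in path and (best is None or m.time < best.time):
                    best = m
            out[i, site] = (
                v.ancestral_states[site] if best is None else best.derived_state
            )
    return out
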