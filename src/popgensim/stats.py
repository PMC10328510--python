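"""Summary statistics for simulated variation and engine event logs.

Conventions: nucleotide diversity ``pi`` is per bp over the full contig
length L (not per segregating site); Watterson's estimator is
``S / (a_{n-1} L)`` with ``a_{n-1} = sum_{i=1}^{n-1} 1/i``.  At
multi-allelic sites (possible under discrete-site mutation) each derived
allele contributes its own frequency class to the unfolded SFS, and a
pairwise comparison counts any state difference once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EventLog, Genealogy, marginal_tree

__all__ = [
    "SummaryStats",
    "harmonic_number",
    "summary_stats",
    "branch_diversity",
    "event_summary",
]


@dataclass
class SummaryStats:
    S: int  # segregating (polymorphic) sites
    pi: float  # mean pairwise diversity per bp
    theta_w: float  # Watterson's estimator per bp
    sfs: np.ndarray | None = None  # derived-allele counts by frequency class

    def to_dict(self) -> dict:
        d = {"S": self.S, "pi": self.pi, "theta_w": self.theta_w}
        if self.sfs is not None:
            d["sfs"] = list(int(x) for x in self.sfs)
        return d


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (the Watterson denominator)."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def summary_stats(
    haplotypes: np.ndarray,
    L: int,
    ancestral_states=None,
    folded: bool = False,
) -> SummaryStats:
    """Compute S, pi, Watterson's theta and (optionally) the SFS.

    ``haplotypes`` is a samples x sites matrix of states.  The SFS needs
    per-site ancestral states (e.g. from a fixed-ancestral-state run); it
    is unfolded by default, or folded on request (class i pooled with
    n - i).  With no ancestral states the SFS is omitted.
    """
    haplotypes = np.asarray(haplotypes)
    n, n_sites = haplotypes.shape
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if L < n_sites:
        raise ValueError("L smaller than the number of sites")
    n_pairs = n * (n - 1) // 2
    S = 0
    mismatch_pairs = 0.0
    derived_counts = []  # one entry per derived allele per site
    for j in range(n_sites):
        column = haplotypes[:, j]
        states, counts = np.unique(column, return_counts=True)
        if len(states) < 2:
            continue
        S += 1
        mismatch_pairs += n_pairs - sum(c * (c - 1) // 2 for c in counts)
        if ancestral_states is not None:
            anc = ancestral_states[j]
            for state, count in zip(states, counts):
                if state != anc:
                    derived_counts.append(int(count))
    pi = mismatch_pairs / n_pairs / L
    theta_w = S / (harmonic_number(n - 1) * L)
    sfs = None
    if ancestral_states is not None:
        sfs = np.zeros(n - 1, dtype=np.int64)
        for c in derived_counts:
            if 1 <= c <= n - 1:
                sfs[c - 1] += 1
        if folded:
            folded_sfs = np.zeros(n // 2, dtype=np.int64)
            for i in range(1, n):
                folded_sfs[min(i, n - i) - 1] += sfs[i - 1]
            sfs = folded_sfs
    return SummaryStats(S=S, pi=pi, theta_w=theta_w, sfs=sfs)


def branch_diversity(g: Genealogy, mu: float) -> float:
    """Expected per-bp pairwise diversity given the genealogy.

    Averages ``2 * TMRCA(pair, position) * mu`` over all sample pairs and
    positions — a variance-reduced ("branch mode") counterpart of the
    site-mode pi, with the Poisson mutation noise integrated out.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if mu == 0:
        return 0.0
    samples = g.samples
    n = len(samples)
    if n < 2:
        return 0.0
    pairs = [(samples[i], samples[j]) for i in range(n) for j in range(i + 1, n)]
    breaks = g.breakpoints()
    total = 0.0
    for left, right in zip(breaks[:-1], breaks[1:]):
        tree = marginal_tree(g, left)
        mean_t = np.mean([tree.tmrca(a, b) for a, b in pairs])
        total += 2.0 * mean_t * mu * (right - left)
    return total / g.contig_length


def event_summary(log: EventLog) -> dict:
    """Counts plus derived fractions from an engine event log.

    ``gc_fraction_drawn`` — the fraction of drawn recombination-class
    events that were gene conversions — is present only when at least one
    such event was drawn; it is the quantity audited against a configured
    conversion fraction (e.g. 83:17).
    """
    out = dict(log.counts())
    denom = log.gc_drawn + log.crossover_drawn
    if denom > 0:
        out["gc_fraction_drawn"] = log.gc_drawn / denom
    if log.tract_lengths:
        out["mean_tract_length"] = float(np.mean(log.tract_lengths))
        out["num_tracts"] = len(log.tract_lengths)
    return out
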