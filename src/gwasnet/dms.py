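"""Dense module search on a node-weighted PPI network.

Each gene with a gene-level P-value becomes a network node with weight
z = Phi^{-1}(1 - P).  A module's score is Z_m = sum(z_i) / sqrt(k).
Starting from every background gene as a seed, the search repeatedly
considers all non-members within shortest-path distance d of the module,
adds the candidate giving the largest new score, and accepts the step
only while Z_{m+1} > Z_m (1 + r).  With the default expansion rate
r = 0.1 the score must grow by 10% per added gene, which keeps modules
small and dense in signal.

Candidates at distance 2 are added without their connecting intermediate
node, so a module's induced subgraph may be internally disconnected;
this mirrors the original dense-module-search behaviour and is recorded,
not repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["WeightedNetwork", "weight_network", "Module", "module_score",
           "neighborhood", "expand_module", "search_all_seeds"]

_Z_CLIP = 1e-15


def module_score(z_values: Iterable[float]) -> float:
    z = list(z_values)
    return sum(z) / math.sqrt(len(z))


@dataclass(frozen=True)
class Module:
    """A seed gene with its grown member set and score trace."""

    seed: str
    members: tuple[str, ...]          # sorted, includes seed
    score: float                      # Z_m = sum(z) / sqrt(k)
    trace: tuple[tuple[str, float, float, float], ...] = ()
    # trace entries: (gene added, its z, score before, score after)

    @property
    def k(self) -> int:
        return len(self.members)


class WeightedNetwork:
    """Undirected simple graph over genes carrying z-score node weights.

    The background set is the genes that have both at least one
    interaction and a gene P-value; only edges between background genes
    are kept.  Background genes whose partners all lack P-values remain
    as isolated nodes.
    """

    def __init__(self, adjacency: Mapping[str, set], z: Mapping[str, float],
                 p: Mapping[str, float] | None = None):
        self.adj = {g: set(nb) for g, nb in adjacency.items()}
        self.z = dict(z)
        self.p = dict(p) if p is not None else {}
        for g, nbs in self.adj.items():
            if g in nbs:
                raise ValueError(f"self-loop at {g}")
        if any(not np.isfinite(v) for v in self.z.values()):
            raise ValueError("node weights must be finite")

    @property
    def background(self) -> list[str]:
        return sorted(self.adj)

    @property
    def background_size(self) -> int:
        return len(self.adj)

    @property
    def n_significant(self) -> int:
        """Background genes with gene P < 0.05."""
        return sum(1 for g in self.adj if self.p.get(g, 1.0) < 0.05)

    def neighbors(self, gene: str) -> set:
        return self.adj[gene]


def weight_network(ppi: Sequence[tuple[str, str]],
                   gene_stats: pd.DataFrame) -> WeightedNetwork:
    """Attach gene z-scores to the PPI and restrict to the background set."""
    pmap = dict(zip(gene_stats["gene"], gene_stats["p"]))
    interacting = {g for e in ppi for g in e}
    background = interacting & set(pmap)
    if not background:
        raise ValueError("no gene is present in both the PPI and the gene stats")
    adj: dict[str, set] = {g: set() for g in background}
    for a, b in ppi:
        if a in background and b in background and a != b:
            adj[a].add(b)
            adj[b].add(a)
    z = {g: float(norm.isf(np.clip(pmap[g], _Z_CLIP, 1 - _Z_CLIP)))
         for g in background}
    p = {g: float(pmap[g]) for g in background}
    return WeightedNetwork(adj, z, p)


def neighborhood(net: WeightedNetwork, members: Iterable[str], d: int = 2) -> set:
    """Non-member genes within shortest-path distance d of the member set."""
    members = set(members)
    seen = set(members)
    frontier = members
    out: set = set()
    for _ in range(d):
        frontier = {nb for g in frontier for nb in net.adj[g]} - seen
        out |= frontier
        seen |= frontier
        if not frontier:
            break
    return out


def expand_module(net: WeightedNetwork, seed: str, r: float = 0.1,
                  d: int = 2, max_steps: int = 10_000) -> Module:
    """Greedy expansion from one seed under the (1 + r) growth rule.

    At each step the candidate maximizing the new score (i.e. the one
    with the largest z; ties to the lexicographically smallest gene id)
    is accepted iff Z_{m+1} > Z_m (1 + r).  A singleton module is a valid
    outcome.
    """
    if seed not in net.adj:
        raise KeyError(f"seed {seed!r} not in background")
    members = {seed}
    zsum = net.z[seed]
    score = zsum  # k=1
    trace: list[tuple[str, float, float, float]] = []
    for _ in range(max_steps):
        cand = neighborhood(net, members, d)
        if not cand:
            break
        best_z = max(net.z[g] for g in cand)
        best = min(g for g in cand if net.z[g] == best_z)
        k = len(members)
        new_score = (zsum + best_z) / math.sqrt(k + 1)
        # growth rule Z_{m+1} > Z_m (1 + r); for negative scores the naive
        # product inverts the requirement, so demand a gain of r*|Z_m|
        if new_score > score + r * abs(score):
            members.add(best)
            zsum += best_z
            trace.append((best, best_z, score, new_score))
            score = new_score
        else:
            break
    return Module(seed=seed, members=tuple(sorted(members)),
                  score=score, trace=tuple(trace))


def search_all_seeds(net: WeightedNetwork, r: float = 0.1, d: int = 2
                     ) -> list[Module]:
    """One module per background gene, in deterministic (sorted) seed order.

    Duplicate member sets from different seeds are retained here;
    deduplication happens when modules are merged.
    """
    return [expand_module(net, seed, r=r, d=d) for seed in net.background]
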