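"""Synthetic chronograms, community matrices, and sea-level fixtures.

Trees are grown forward in time from the two lineages of the root split
under a (possibly time-varying) pure-birth process.  Time-varying rates
use Ogata thinning with the family's supremum over the simulated span as
the bound, which is exact because the lineage count is constant between
accepted events.  Community matrices are assembled over a tree under
four rules that emulate the competing explanations for community
phylogenetic structure: neutral sampling, habitat filtering on a
Brownian trait (clustering), limiting similarity (dispersion), and
recent allopatry (young sister species confined to disjoint sites).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, SimulationError
from .rates import SeaLevelIntervals
from .tree import Chronogram

__all__ = [
    "simulate_yule_tree",
    "simulate_conditioned_tree",
    "simulate_communities",
    "sea_level_fixture",
]

_T_INDEXED_FAMILIES = ("constant", "logistic")


class _SimNode:
    __slots__ = ("birth", "children", "end")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list["_SimNode"] = []
        self.end: Optional[float] = None


def _emit_newick(founders: list[_SimNode], duration: float) -> str:
    counter = [0]

    def rec(node: _SimNode, parent_time: float) -> str:
        if not node.children:
            counter[0] += 1
            bl = duration - parent_time
            return f"t{counter[0]}:{bl:.12f}"
        inner = ",".join(rec(c, node.end) for c in node.children)
        bl = node.end - parent_time
        return f"({inner}):{bl:.12f}"

    parts = ",".join(rec(f, 0.0) for f in founders)
    return f"({parts});"


def _split(active: list[_SimNode], rng, t: float) -> None:
    i = int(rng.integers(len(active)))
    node = active[i]
    node.end = t
    c1, c2 = _SimNode(t), _SimNode(t)
    node.children = [c1, c2]
    active[i] = c1
    active.append(c2)


def _grow_duration(model, duration: float, rng) -> list[_SimNode]:
    bound = model.max_rate(duration)
    f1, f2 = _SimNode(0.0), _SimNode(0.0)
    active = [f1, f2]
    t = 0.0
    while bound > 0:
        t = t + rng.exponential(1.0 / (len(active) * bound))
        if t >= duration:
            break
        if rng.uniform() * bound <= model.rate_at(t, duration):
            _split(active, rng, t)
    return [f1, f2]


def _grow_ntips(model, n_tips: int, rng) -> tuple[list[_SimNode], float]:
    if model.family not in _T_INDEXED_FAMILIES:
        raise DomainError(
            "tip-count stopping needs a rate indexed by time since the root "
            "(constant or logistic); age-indexed families require a duration"
        )
    bound = model.max_rate(np.inf)
    if bound <= 0:
        raise SimulationError("rate is zero everywhere; tip target unreachable")
    f1, f2 = _SimNode(0.0), _SimNode(0.0)
    active = [f1, f2]
    t = 0.0
    steps = 0
    while True:
        steps += 1
        if steps > 10**7:
            raise SimulationError("simulation exceeded the step cap")
        t_prop = t + rng.exponential(1.0 / (len(active) * bound))
        if len(active) >= n_tips:
            # depth set by the completed final inter-event interval
            return [f1, f2], t_prop
        t = t_prop
        if rng.uniform() * bound <= model.rate_at(t, np.inf):
            _split(active, rng, t)


def simulate_yule_tree(
    model,
    *,
    duration: Optional[float] = None,
    n_tips: Optional[int] = None,
    seed: Optional[int] = None,
) -> Chronogram:
    """Simulate a reconstructed pure-birth chronogram.

    Exactly one of ``duration`` (tree depth, Myr) or ``n_tips`` must be
    given.  Growth starts from the two root lineages; waiting times are
    exponential at the current total rate N·λ, with thinning against the
    family supremum for time-varying rates.  Deterministic per seed.
    """
    if (duration is None) == (n_tips is None):
        raise DomainError("give exactly one of duration or n_tips")
    rng = np.random.default_rng(seed)
    if n_tips is not None:
        if n_tips < 2:
            raise DomainError("n_tips must be >= 2")
        founders, depth = _grow_ntips(model, int(n_tips), rng)
    else:
        if duration <= 0:
            raise DomainError("duration must be positive")
        founders, depth = _grow_duration(model, float(duration), rng), float(duration)
    return Chronogram.from_newick(_emit_newick(founders, depth))


def simulate_conditioned_tree(
    model,
    n: int,
    root_age: float,
    seed: Optional[int] = None,
    max_attempts: int = 200_000,
) -> Chronogram:
    """Simulate a tree conditioned on exactly ``n`` tips and depth ``root_age``.

    Rejection-samples fixed-duration forward simulations until the tip count
    hits ``n``; raises if the acceptance probability is too low within the
    attempt cap.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        founders = _grow_duration(model, float(root_age), rng)
        n_tips = _count_tips(founders)
        if n_tips == n:
            return Chronogram.from_newick(_emit_newick(founders, float(root_age)))
    raise SimulationError(
        f"no simulation hit n={n} within {max_attempts} attempts; "
        "the rate model is a poor match for this (n, root_age) — revise it"
    )


def _count_tips(founders: list[_SimNode]) -> int:
    total = 0
    stack = list(founders)
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(node.children)
        else:
            total += 1
    return total


# ----------------------------------------------------------------------
# community assembly
# ----------------------------------------------------------------------
def _brownian_traits(tree: Chronogram, rng) -> dict[str, float]:
    """Unit-rate Brownian trait evolved along the tree, root value 0."""
    values: dict = {}
    out: dict[str, float] = {}
    t = tree._tree
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            el = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(0.0, np.sqrt(max(el, 0.0)))
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            out[str(label)] = float(values[node])
    return out


def _weighted_sample_without_replacement(labels, weights, k, rng) -> list:
    """Efraimidis-Spirakis exponential-keys draw, weights > 0."""
    w = np.asarray(weights, dtype=float)
    w = np.where(w > 0, w, 1e-300)
    keys = rng.exponential(1.0, size=len(w)) / w
    order = np.argsort(keys)
    return [labels[i] for i in order[:k]]


def simulate_communities(
    tree: Chronogram,
    n_sites: int,
    richness_per_site: int,
    mode: str = "neutral",
    strength: float = 0.0,
    seed: Optional[int] = None,
    metadata: Optional[pd.DataFrame] = None,
) -> "OccurrenceMatrix":
    """Assemble presence/absence communities on a chronogram.

    Modes
    -----
    neutral
        Uniform sampling without replacement per site.
    filtered
        Habitat filtering: inclusion weights exp(-strength · |trait - site
        optimum|) with a unit-rate Brownian trait; produces phylogenetic
        clustering.  Each site's optimum is the trait of a randomly chosen
        species.
    dispersed
        Limiting similarity: sequential draws rejecting any species whose
        divergence to a resident is below ``strength`` Myr; produces
        phylogenetic dispersion.  Sites may end below target richness.
    recent_allopatry
        Every cherry younger than ``strength`` Myr has its two sister
        species assigned to different sites; remaining richness is filled
        neutrally from species outside those cherries, so no site ever
        holds both members of a sub-threshold cherry.
    """
    from .community import OccurrenceMatrix

    if richness_per_site > tree.n:
        raise DomainError("richness exceeds the number of species on the tree")
    if strength < 0:
        raise DomainError("strength must be >= 0")
    rng = np.random.default_rng(seed)
    species = list(tree.tips)
    sites = [f"site{i + 1}" for i in range(n_sites)]
    pres = pd.DataFrame(0, index=species, columns=sites, dtype=np.int8)

    if mode == "neutral":
        for s in sites:
            chosen = rng.choice(species, size=richness_per_site, replace=False)
            pres.loc[list(chosen), s] = 1
    elif mode == "filtered":
        traits = _brownian_traits(tree, rng)
        tvals = np.array([traits[sp] for sp in species])
        for s in sites:
            optimum = tvals[int(rng.integers(len(species)))]
            w = np.exp(-strength * np.abs(tvals - optimum))
            chosen = _weighted_sample_without_replacement(
                species, w, richness_per_site, rng
            )
            pres.loc[chosen, s] = 1
    elif mode == "dispersed":
        div = tree.divergence_matrix()
        dmat = div.to_numpy()
        idx = {sp: i for i, sp in enumerate(species)}
        for s in sites:
            order = rng.permutation(len(species))
            residents: list[int] = []
            for j in order:
                if len(residents) >= richness_per_site:
                    break
                if all(dmat[j, r] >= strength for r in residents):
                    residents.append(int(j))
            if len(residents) < richness_per_site:
                warnings.warn(
                    f"{s}: only {len(residents)}/{richness_per_site} species "
                    "satisfy the limiting-similarity rule",
                    stacklevel=2,
                )
            pres.iloc[residents, pres.columns.get_loc(s)] = 1
    elif mode == "recent_allopatry":
        if n_sites < 2:
            raise DomainError("recent_allopatry needs at least 2 sites")
        cherries = _young_cherries(tree, strength)
        cherry_species = {sp for pair in cherries for sp in pair}
        for sp1, sp2 in cherries:
            s1, s2 = rng.choice(n_sites, size=2, replace=False)
            pres.loc[sp1, sites[int(s1)]] = 1
            pres.loc[sp2, sites[int(s2)]] = 1
        fill_pool = [sp for sp in species if sp not in cherry_species]
        for s in sites:
            need = richness_per_site - int(pres[s].sum())
            if need <= 0:
                continue
            avail = [sp for sp in fill_pool if pres.loc[sp, s] == 0]
            if need > len(avail):
                warnings.warn(
                    f"{s}: fill pool exhausted at {len(avail)} of {need} needed",
                    stacklevel=2,
                )
                need = len(avail)
            chosen = rng.choice(avail, size=need, replace=False)
            pres.loc[list(chosen), s] = 1
    else:
        raise DomainError(f"unknown assembly mode {mode!r}")

    if metadata is None:
        islands = ["sim_island"] * n_sites
        habitats = ["inner_reef" if i % 2 == 0 else "outer_slope" for i in range(n_sites)]
        metadata = pd.DataFrame(
            {"island": islands, "habitat": habitats}, index=sites
        )
    return OccurrenceMatrix(pres, metadata)


def _young_cherries(tree: Chronogram, max_age: float) -> list[tuple[str, str]]:
    """Sister-species pairs (cherries) with MRCA age below ``max_age``."""
    out = []
    for node in tree._tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids) and tree.node_age(node) < max_age:
            labels = [
                str(k.taxon.label if k.taxon is not None else k.label) for k in kids
            ]
            out.append((labels[0], labels[1]))
    return out


# ----------------------------------------------------------------------
# sea-level fixtures
# ----------------------------------------------------------------------
def sea_level_fixture(style: str = "toy", seed: Optional[int] = None) -> SeaLevelIntervals:
    """High-stand sea-level interval fixtures.

    ``toy`` is a fixed two-interval table; ``cenozoic-like`` draws random
    alternating high/low stands over ages 0-30 Ma, leaving older ages
    low-stand (so few lineages exist there that the covariate would be
    uninformative).
    """
    if style == "toy":
        return SeaLevelIntervals(((20.0, 15.0), (8.0, 3.0)))
    if style == "cenozoic-like":
        rng = np.random.default_rng(seed)
        intervals = []
        age = 30.0
        high = bool(rng.integers(2))
        while age > 0.5:
            span = float(rng.uniform(1.0, 5.0))
            young = max(age - span, 0.0)
            if high:
                intervals.append((age, young))
            age = young
            high = not high
        if not intervals:
            intervals = [(5.0, 2.0)]
        return SeaLevelIntervals(tuple(intervals))
    raise DomainError(f"unknown fixture style {style!r}")
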