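"""Virtual discovery-group generation for bootstrap testing.

Three modalities produce n randomized foreground/background (FG/BG)
assignments with the observed group sizes:

* naive — every species in the pool is equally likely to enter either
  group, sampled without replacement (the plain permutation null);
* phylogeny-restricted — each virtual group preserves the observed
  per-clade composition, randomizing only within clades;
* Brownian motion (BM) — a trait is simulated under BM on the
  phylogeny, the observed trait values are reassigned to species by
  rank-matching the simulation ("permulation"), and the virtual groups
  are taken from the extremes of the permuted trait, mirroring how the
  observed groups sit at the extremes of the real trait.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io import DiscoveryGroups

logger = logging.getLogger("caaskit")

MODALITIES = ("naive", "phylo_restricted", "bm")


@dataclass(frozen=True)
class VirtualDG:
    """One randomized FG/BG assignment."""

    fg: FrozenSet[str]
    bg: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fg", frozenset(self.fg))
        object.__setattr__(self, "bg", frozenset(self.bg))
        if self.fg & self.bg:
            raise ValueError("virtual FG and BG overlap")


@dataclass
class ResampleSet:
    """An ordered collection of virtual discovery groups."""

    assignments: List[VirtualDG]
    modality: str
    seed: int
    pool: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pool = frozenset(self.pool)
        for vdg in self.assignments:
            stray = (vdg.fg | vdg.bg) - self.pool
            if stray:
                raise ValueError(f"assignment uses species outside the pool: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.assignments)

    def __iter__(self):
        return iter(self.assignments)


@dataclass(frozen=True)
class BMParams:
    """Brownian-motion parameters: rate sigma2 (trait variance per unit
    branch length) and the trait value at the root."""

    sigma2: float = 1.0
    root_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")


# ---------------------------------------------------------------------------
# naive modality
# ---------------------------------------------------------------------------

def resample_naive(
    pool: Sequence[str], fg_size: int, bg_size: int, n: int, seed: int
) -> ResampleSet:
    """n uniform FG/BG draws without replacement from the pool."""
    pool = sorted(set(pool))
    if fg_size < 1 or bg_size < 1:
        raise ValueError("group sizes must be >= 1")
    if len(pool) < fg_size + bg_size:
        raise ValueError(
            f"pool of {len(pool)} species cannot host fg_size + bg_size = "
            f"{fg_size + bg_size}"
        )
    if n < 1:
        raise ValueError("number of resamplings must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n):
        perm = rng.permutation(len(pool))
        fg = frozenset(pool[i] for i in perm[:fg_size])
        bg = frozenset(pool[i] for i in perm[fg_size:fg_size + bg_size])
        assignments.append(VirtualDG(fg=fg, bg=bg))
    return ResampleSet(assignments=assignments, modality="naive", seed=seed, pool=frozenset(pool))


# ---------------------------------------------------------------------------
# phylogeny-restricted modality
# ---------------------------------------------------------------------------

def resample_phylo_restricted(
    pool: Sequence[str],
    observed: DiscoveryGroups,
    taxonomy: Mapping[str, str],
    n: int,
    seed: int,
) -> ResampleSet:
    """n draws preserving the observed per-clade FG/BG composition.

    For each clade the virtual FG (BG) receives exactly as many pool
    species of that clade as the observed FG (BG) holds, drawn
    uniformly without replacement; FG and BG never overlap.
    """
    pool = sorted(set(pool))
    if n < 1:
        raise ValueError("number of resamplings must be >= 1")
    unlabeled = sorted((observed.fg | observed.bg) - set(taxonomy))
    if unlabeled:
        raise ValueError(f"discovery-group species without clade labels: {unlabeled}")
    fg_need: Dict[str, int] = {}
    bg_need: Dict[str, int] = {}
    for sp in observed.fg:
        fg_need[taxonomy[sp]] = fg_need.get(taxonomy[sp], 0) + 1
    for sp in observed.bg:
        bg_need[taxonomy[sp]] = bg_need.get(taxonomy[sp], 0) + 1
    clades = sorted(set(fg_need) | set(bg_need))
    members = {
        c: [sp for sp in pool if taxonomy.get(sp) == c] for c in clades
    }
    for c in clades:
        need = fg_need.get(c, 0) + bg_need.get(c, 0)
        if len(members[c]) < need:
            raise ValueError(
                f"clade {c!r}: pool has {len(members[c])} species but the "
                f"observed groups use {need}"
            )
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n):
        fg: List[str] = []
        bg: List[str] = []
        for c in clades:
            take = fg_need.get(c, 0) + bg_need.get(c, 0)
            chosen = rng.choice(len(members[c]), size=take, replace=False)
            picked = [members[c][i] for i in chosen]
            fg.extend(picked[:fg_need.get(c, 0)])
            bg.extend(picked[fg_need.get(c, 0):])
        assignments.append(VirtualDG(fg=frozenset(fg), bg=frozenset(bg)))
    return ResampleSet(
        assignments=assignments, modality="phylo_restricted", seed=seed,
        pool=frozenset(pool),
    )


# ---------------------------------------------------------------------------
# Brownian-motion modality
# ---------------------------------------------------------------------------

def _simulate_bm(tree: dendropy.Tree, params: BMParams, rng: np.random.Generator) -> Dict[str, float]:
    values: Dict[int, float] = {}
    tips: Dict[str, float] = {}
    scale = params.sigma2
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = params.root_value
        else:
            length = node.edge.length
            if length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise ValueError(f"missing branch length above node {label!r}")
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, float(np.sqrt(scale * length))
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return tips


def simulate_bm(tree: dendropy.Tree, params: BMParams, seed: int) -> Dict[str, float]:
    """Simulate one Brownian-motion trait over the tree; returns tip values.

    Each node value is its parent's value plus a Gaussian increment of
    variance sigma2 × branch length; the root takes params.root_value.
    """
    return _simulate_bm(tree, params, np.random.default_rng(seed))


def rank_match_traits(
    simulated: Mapping[str, float],
    observed: Mapping[str, float],
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Permute observed trait values onto species by simulated rank.

    The species with the largest simulated value receives the largest
    observed trait value, and so on — a bijection, so the permuted
    multiset equals the observed multiset exactly.  Ties in the
    simulated values are broken by a seeded shuffle.
    """
    if set(simulated) != set(observed):
        raise ValueError("simulated and observed trait tables name different species")
    species = sorted(simulated)
    if rng is not None:
        order = rng.permutation(len(species))
        species = [species[i] for i in order]
    ranked = sorted(species, key=lambda sp: simulated[sp], reverse=True)
    obs_sorted = sorted(observed.values(), reverse=True)
    return {sp: value for sp, value in zip(ranked, obs_sorted)}


def fg_is_top(observed: DiscoveryGroups, trait: Mapping[str, float]) -> bool:
    """Whether the foreground sits at the top extreme of the trait."""
    fg_mean = float(np.mean([trait[sp] for sp in observed.fg]))
    bg_mean = float(np.mean([trait[sp] for sp in observed.bg]))
    return fg_mean >= bg_mean


def resample_bm(
    tree: dendropy.Tree,
    observed: DiscoveryGroups,
    trait: Mapping[str, float],
    params: BMParams = BMParams(),
    n: int = 1000,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> ResampleSet:
    """n Brownian-motion permulation draws.

    Per iteration: simulate a BM trait on the tree restricted to the
    pool, rank-match the observed trait values onto species, then take
    the virtual FG from the fg_size most-extreme permuted values on the
    side where the observed FG lies (top if mean FG trait >= mean BG
    trait, else bottom) and the virtual BG from the opposite extreme.

    The pool defaults to the tree tips that carry trait values.
    """
    if n < 1:
        raise ValueError("number of resamplings must be >= 1")
    tip_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if pool is None:
        pool = sorted(tip_names & set(trait))
    else:
        pool = sorted(set(pool))
    missing_tips = sorted(set(pool) - tip_names)
    if missing_tips:
        raise ValueError(f"pool species absent from the tree: {missing_tips}")
    missing_trait = sorted(set(pool) - set(trait))
    if missing_trait:
        raise ValueError(f"pool species without trait values: {missing_trait}")
    stray_groups = sorted((observed.fg | observed.bg) - set(pool))
    if stray_groups:
        raise ValueError(f"discovery-group species outside the BM pool: {stray_groups}")
    f, b = observed.fg_size, observed.bg_size
    if len(pool) < f + b:
        raise ValueError("pool smaller than fg_size + bg_size")
    if len(pool) < len(tip_names):
        work_tree = tree.extract_tree_with_taxa_labels(labels=pool)
    else:
        work_tree = tree
    obs_on_pool = {sp: float(trait[sp]) for sp in pool}
    top = fg_is_top(observed, trait)
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n):
        sims = _simulate_bm(work_tree, params, rng)
        permuted = rank_match_traits(sims, obs_on_pool, rng=rng)
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        by_value = sorted(shuffled, key=lambda sp: permuted[sp], reverse=True)
        if top:
            fg = by_value[:f]
            bg = by_value[-b:]
        else:
            fg = by_value[-f:]
            bg = by_value[:b]
        assignments.append(VirtualDG(fg=frozenset(fg), bg=frozenset(bg)))
    return ResampleSet(
        assignments=assignments, modality="bm", seed=seed, pool=frozenset(pool)
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_resamples(resamples: ResampleSet, path) -> None:
    """Write a ResampleSet as TSV: iteration, FG species, BG species."""
    with open(path, "w") as fh:
        fh.write(f"# modality={resamples.modality} seed={resamples.seed}\n")
        fh.write("iteration\tfg\tbg\n")
        for i, vdg in enumerate(resamples.assignments):
            fh.write(f"{i}\t{','.join(sorted(vdg.fg))}\t{','.join(sorted(vdg.bg))}\n")


def read_resamples(path) -> ResampleSet:
    """Read a ResampleSet written by write_resamples."""
    path = Path(path)
    modality, seed = "unknown", -1
    assignments: List[VirtualDG] = []
    pool: set = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("modality="):
                        modality = token.split("=", 1)[1]
                    elif token.startswith("seed="):
                        seed = int(token.split("=", 1)[1])
                continue
            if not line.strip() or line.startswith("iteration\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed resample row {line!r}")
            fg = frozenset(parts[1].split(","))
            bg = frozenset(parts[2].split(","))
            assignments.append(VirtualDG(fg=fg, bg=bg))
            pool |= fg | bg
    if not assignments:
        raise ValueError(f"no resamplings found in {path}")
    return ResampleSet(assignments=assignments, modality=modality, seed=seed, pool=frozenset(pool))
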