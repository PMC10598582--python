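"""Synthetic trees, traits and alignments with planted CAAS columns.

Everything the other modules need for testing is generated here, fully
seeded, so no external data is ever required.  The generators favour
controllability over realism: background columns evolve under a
uniform-exchange amino-acid process (or are drawn iid uniform), not an
empirical substitution matrix.

In *strict* mode, background columns are restricted to the residues
{A..H} and planted foreground/background residues to {I..Y}, and any
background column that would classify as a CAAS for the observed
discovery groups is redrawn.  Under that construction the discovery
scan recovers exactly the planted (position, pattern) set.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .discovery import Pattern, classify_chars
from .io import AMINO_ACIDS, GAP, UNKNOWN, Alignment, DiscoveryGroups
from .resample import BMParams, simulate_bm

#: residues allowed in background columns under strict mode
STRICT_BACKGROUND_ALPHABET = "ACDEFGH"
#: residues allowed for planted FG/BG states under strict mode
STRICT_PLANTED_ALPHABET = "IKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedColumn:
    """A column engineered to classify as a given CAAS pattern."""

    column: int
    pattern: Pattern
    fg_aas: Tuple[str, ...]
    bg_aas: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fg_aas", tuple(self.fg_aas))
        object.__setattr__(self, "bg_aas", tuple(self.bg_aas))
        if set(self.fg_aas) & set(self.bg_aas):
            raise ValueError("planted FG and BG residues must be disjoint")
        n_fg, n_bg = len(set(self.fg_aas)), len(set(self.bg_aas))
        if self.pattern is Pattern.P1 and (n_fg, n_bg) != (1, 1):
            raise ValueError("P1 needs exactly one FG and one BG residue")
        if self.pattern is Pattern.P2 and (n_fg != 1 or n_bg < 2):
            raise ValueError("P2 needs one FG residue and >= 2 BG residues")
        if self.pattern is Pattern.P3 and (n_fg < 2 or n_bg != 1):
            raise ValueError("P3 needs >= 2 FG residues and one BG residue")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic alignment."""

    n_species: int
    n_columns: int
    planted: List[PlantedColumn] = field(default_factory=list)
    background_model: str = "iid_uniform"
    missing_rate: float = 0.0
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.background_model not in ("iid_uniform", "tree_evolved"):
            raise ValueError(f"unknown background model {self.background_model!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        cols = [p.column for p in self.planted]
        if len(cols) != len(set(cols)):
            raise ValueError("planted columns must be distinct")
        for p in self.planted:
            if not 0 <= p.column < self.n_columns:
                raise ValueError(f"planted column {p.column} out of range")
            if self.strict:
                stray = (set(p.fg_aas) | set(p.bg_aas)) - set(STRICT_PLANTED_ALPHABET)
                if stray:
                    raise ValueError(
                        f"strict mode restricts planted residues to "
                        f"{STRICT_PLANTED_ALPHABET}; got {sorted(stray)}"
                    )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def generate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """A seeded Yule (pure-birth) topology with Exp(1) branch lengths.

    Tips are named sp1..spN in left-to-right leaf order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node]
    # pure-birth: split a uniformly chosen extant lineage until n tips exist
    while len(leaves) < n_tips:
        parent = leaves.pop(rng.randrange(len(leaves)))
        left = parent.new_child()
        right = parent.new_child()
        leaves.extend([left, right])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = rng.expovariate(1.0)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i}")
    tree.is_rooted = True
    return tree


def generate_taxonomy(tree: dendropy.Tree) -> Dict[str, str]:
    """Label every tip by the root-child subtree it belongs to (clade1..)."""
    clade_of: Dict[str, str] = {}
    for i, child in enumerate(tree.seed_node.child_nodes(), start=1):
        for leaf in child.leaf_iter():
            clade_of[leaf.taxon.label] = f"clade{i}"
    return clade_of


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _cycle(symbols: Sequence[str], n: int) -> List[str]:
    return [symbols[i % len(symbols)] for i in range(n)]


def _background_column(
    species: Sequence[str],
    model: str,
    alphabet: str,
    tree: Optional[dendropy.Tree],
    rng: np.random.Generator,
) -> Dict[str, str]:
    if model == "iid_uniform":
        draws = rng.choice(list(alphabet), size=len(species))
        return dict(zip(species, draws))
    # tree_evolved: uniform-exchange process at unit rate down the tree
    assert tree is not None
    states: Dict[int, str] = {}
    out: Dict[str, str] = {}
    letters = list(alphabet)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = letters[rng.integers(len(letters))]
        else:
            parent_state = states[id(node.parent_node)]
            t = node.edge.length if node.edge.length is not None else 1.0
            if rng.random() < 1.0 - math.exp(-t):
                states[id(node)] = letters[rng.integers(len(letters))]
            else:
                states[id(node)] = parent_state
        if node.is_leaf():
            out[node.taxon.label] = states[id(node)]
    return out


def generate_alignment(
    spec: FixtureSpec,
    groups: DiscoveryGroups,
    tree: Optional[dendropy.Tree] = None,
) -> Alignment:
    """Build a synthetic alignment with the requested planted CAAS columns.

    Planted columns set the FG/BG residues so the column classifies as
    exactly the requested pattern; species outside the discovery groups
    receive distinct residues drawn from the alphabet left over by the
    planted states.  Background columns follow spec.background_model,
    with missing symbols injected at spec.missing_rate; under
    spec.strict they are redrawn until they carry no CAAS for the
    observed groups.
    """
    rng = np.random.default_rng(spec.seed)
    if tree is not None:
        species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(species) != spec.n_species:
            raise ValueError(
                f"tree has {len(species)} tips but spec.n_species = {spec.n_species}"
            )
    else:
        if spec.background_model == "tree_evolved":
            raise ValueError("tree_evolved background needs a tree")
        species = [f"sp{i}" for i in range(1, spec.n_species + 1)]
    stray = (groups.fg | groups.bg) - set(species)
    if stray:
        raise ValueError(f"discovery-group species not in fixture: {sorted(stray)}")
    fg_sorted = sorted(groups.fg)
    bg_sorted = sorted(groups.bg)
    for p in spec.planted:
        if len(set(p.bg_aas)) > len(bg_sorted) or len(set(p.fg_aas)) > len(fg_sorted):
            raise ValueError(
                f"planted column {p.column}: more residues than group members"
            )
    background_alphabet = (
        STRICT_BACKGROUND_ALPHABET if spec.strict else AMINO_ACIDS
    )
    planted_at = {p.column: p for p in spec.planted}
    columns: List[Dict[str, str]] = []
    for col in range(spec.n_columns):
        if col in planted_at:
            p = planted_at[col]
            column: Dict[str, str] = {}
            for sp, aa in zip(fg_sorted, _cycle(sorted(set(p.fg_aas)), len(fg_sorted))):
                column[sp] = aa
            for sp, aa in zip(bg_sorted, _cycle(sorted(set(p.bg_aas)), len(bg_sorted))):
                column[sp] = aa
            others = [sp for sp in species if sp not in column]
            spare = [
                aa for aa in AMINO_ACIDS
                if aa not in set(p.fg_aas) | set(p.bg_aas)
            ]
            for sp, aa in zip(others, _cycle(spare, len(others))):
                column[sp] = aa
            columns.append(column)
            continue
        for attempt in range(10_000):
            column = _background_column(
                species, spec.background_model, background_alphabet, tree, rng
            )
            if spec.missing_rate > 0:
                for sp in species:
                    if rng.random() < spec.missing_rate:
                        column[sp] = GAP if rng.random() < 0.5 else UNKNOWN
            if not spec.strict:
                break
            pattern = classify_chars(
                [column[sp] for sp in fg_sorted],
                [column[sp] for sp in bg_sorted],
                max_fg_missing=groups.max_fg_missing,
                max_bg_missing=groups.max_bg_missing,
                max_fg_gaps=groups.max_fg_gaps,
                max_bg_gaps=groups.max_bg_gaps,
            )
            if pattern is None:
                break
        else:
            raise RuntimeError(
                f"could not draw a CAAS-free background column {col} "
                f"in 10000 attempts"
            )
        columns.append(column)
    sequences = {
        sp: "".join(columns[col][sp] for col in range(spec.n_columns))
        for sp in species
    }
    return Alignment(id=f"fixture-{spec.seed}", sequences=sequences)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def generate_trait(
    tree: dendropy.Tree,
    groups: DiscoveryGroups,
    gap: float,
    seed: int,
    params: BMParams = BMParams(),
) -> Dict[str, float]:
    """A BM-evolved baseline trait shifted by +gap for FG and -gap for BG.

    With gap = 0 the trait is pure Brownian motion and the groups are
    exchangeable; with gap far above the BM scale the FG species occupy
    exactly the top trait ranks.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    values = simulate_bm(tree, params, seed)
    out = {}
    for sp, v in values.items():
        if sp in groups.fg:
            v += gap
        elif sp in groups.bg:
            v -= gap
        out[sp] = v
    return out
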