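"""Shared fixtures and the independent brute-force CAAS oracle."""
from __future__ import annotations

import itertools
from typing import Dict, Set, Tuple

import numpy as np
import pytest

from caaskit import Alignment, DiscoveryGroups

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(
    seed: int,
    n_species: int,
    n_columns: int,
    alphabet: str = AA20,
    missing_rate: float = 0.0,
) -> Alignment:
    """An iid random alignment for oracle comparisons."""
    rng = np.random.default_rng(seed)
    symbols = list(alphabet)
    seqs: Dict[str, str] = {}
    for i in range(n_species):
        chars = rng.choice(symbols, size=n_columns)
        if missing_rate > 0:
            mask = rng.random(n_columns) < missing_rate
            fill = rng.choice(["-", "X"], size=n_columns)
            chars = np.where(mask, fill, chars)
        seqs[f"sp{i + 1}"] = "".join(chars)
    return Alignment(id=f"rand-{seed}", sequences=seqs)


def brute_force_caas(alignment: Alignment, groups: DiscoveryGroups) -> Set[Tuple[int, str]]:
    """Literal per-column check of the two CAAS conditions.

    Independent of the package's classification code: tests the
    conditions (no shared amino acid between groups; at least one
    group monomorphic) directly on the raw characters, honouring the
    per-group gap/unknown tolerances.
    """
    out: Set[Tuple[int, str]] = set()
    for col in range(alignment.length):
        fg_chars = [alignment.sequences[sp][col] for sp in sorted(groups.fg)]
        bg_chars = [alignment.sequences[sp][col] for sp in sorted(groups.bg)]
        if fg_chars.count("-") > groups.max_fg_gaps:
            continue
        if fg_chars.count("X") > groups.max_fg_missing:
            continue
        if bg_chars.count("-") > groups.max_bg_gaps:
            continue
        if bg_chars.count("X") > groups.max_bg_missing:
            continue
        fg_set = {c for c in fg_chars if c not in "-X"}
        bg_set = {c for c in bg_chars if c not in "-X"}
        if not fg_set or not bg_set or (fg_set & bg_set):
            continue
        if len(fg_set) == 1 and len(bg_set) == 1:
            out.add((col, "P1"))
        elif len(fg_set) == 1:
            out.add((col, "P2"))
        elif len(bg_set) == 1:
            out.add((col, "P3"))
    return out


def all_splits(pool, fg_size, bg_size):
    """Every ordered (FG, BG) assignment drawn without replacement."""
    pool = sorted(pool)
    for fg in itertools.combinations(pool, fg_size):
        rest = [sp for sp in pool if sp not in fg]
        for bg in itertools.combinations(rest, bg_size):
            yield frozenset(fg), frozenset(bg)


@pytest.fixture
def aass_alignment() -> Alignment:
    """The canonical one-column A,A,S,S alignment over four species."""
    return Alignment(
        id="aass",
        sequences={"sp1": "A", "sp2": "A", "sp3": "S", "sp4": "S"},
    )


@pytest.fixture
def four_species_groups() -> DiscoveryGroups:
    return DiscoveryGroups(fg=frozenset({"sp1", "sp2"}), bg=frozenset({"sp3", "sp4"}))
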