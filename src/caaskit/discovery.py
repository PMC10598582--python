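"""Column scan for convergent amino acid substitutions (CAAS).

A column is a CAAS between the foreground (FG) and background (BG)
species groups when (1) the two groups share no amino acid at that
column and (2) at least one group is monomorphic there.  Those two
conditions close over exactly three patterns:

    P1  both groups monomorphic        FG {L}      vs BG {V}
    P2  FG monomorphic, BG polymorphic FG {L}      vs BG {V, I}
    P3  FG polymorphic, BG monomorphic FG {L, M}   vs BG {V}

Each detected position can carry an empirical p-value: the fraction of
randomized FG/BG assignments (drawn from a resampling pool, by default
FG ∪ BG) that reproduce any CAAS pattern at that column — a direct
measure of the convergent noise at the site.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .io import AMINO_ACIDS, GAP, UNKNOWN, Alignment, DiscoveryGroups

logger = logging.getLogger("caaskit")

#: default cap on exact enumeration of randomized group assignments
ENUMERATION_CAP = 10_000

_AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CODE = -1
UNKNOWN_CODE = -2


class Pattern(Enum):
    """CAAS mutation pattern classes."""

    P1 = "P1"
    P2 = "P2"
    P3 = "P3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_PATTERNS = frozenset(Pattern)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column residue/missing breakdown for the two discovery groups."""

    fg_residues: Tuple[str, ...]
    bg_residues: Tuple[str, ...]
    fg_gaps: int
    bg_gaps: int
    fg_unknown: int
    bg_unknown: int

    @property
    def fg_missing(self) -> int:
        return self.fg_gaps + self.fg_unknown

    @property
    def bg_missing(self) -> int:
        return self.bg_gaps + self.bg_unknown


@dataclass(frozen=True)
class CAASRecord:
    """One detected CAAS position (position is 0-based internally)."""

    alignment_id: str
    position: int
    pattern: Pattern
    fg_aas: FrozenSet[str]
    bg_aas: FrozenSet[str]
    fg_missing: int
    bg_missing: int
    pvalue: Optional[float] = None


def _split_chars(chars: Sequence[str]) -> Tuple[Tuple[str, ...], int, int]:
    residues = tuple(c for c in chars if c != GAP and c != UNKNOWN)
    gaps = sum(1 for c in chars if c == GAP)
    unknown = sum(1 for c in chars if c == UNKNOWN)
    return residues, gaps, unknown


def profile_column(alignment: Alignment, column: int, groups: DiscoveryGroups) -> ColumnProfile:
    """Partition each group's species at a column into residues vs missing."""
    if not 0 <= column < alignment.length:
        raise IndexError(f"column {column} out of range for length {alignment.length}")
    absent = (groups.fg | groups.bg) - set(alignment.sequences)
    if absent:
        raise ValueError(
            f"discovery-group species missing from alignment {alignment.id!r}: "
            f"{sorted(absent)}"
        )
    fg_chars = [alignment.sequences[sp][column] for sp in sorted(groups.fg)]
    bg_chars = [alignment.sequences[sp][column] for sp in sorted(groups.bg)]
    fg_res, fg_gaps, fg_unk = _split_chars(fg_chars)
    bg_res, bg_gaps, bg_unk = _split_chars(bg_chars)
    return ColumnProfile(
        fg_residues=fg_res, bg_residues=bg_res,
        fg_gaps=fg_gaps, bg_gaps=bg_gaps,
        fg_unknown=fg_unk, bg_unknown=bg_unk,
    )


def classify_chars(
    fg_chars: Sequence[str],
    bg_chars: Sequence[str],
    max_fg_missing: int = 0,
    max_bg_missing: int = 0,
    max_fg_gaps: int = 0,
    max_bg_gaps: int = 0,
) -> Optional[Pattern]:
    """Classify raw column characters of the two groups.

    This is the single decision core shared by discovery, p-value
    randomization and bootstrap counting.  Returns None for no CAAS.
    """
    fg_res, fg_gaps, fg_unk = _split_chars(fg_chars)
    bg_res, bg_gaps, bg_unk = _split_chars(bg_chars)
    if fg_gaps > max_fg_gaps or fg_unk > max_fg_missing:
        return None
    if bg_gaps > max_bg_gaps or bg_unk > max_bg_missing:
        return None
    u_fg = set(fg_res)
    u_bg = set(bg_res)
    if not u_fg or not u_bg or (u_fg & u_bg):
        return None
    fg_mono = len(u_fg) == 1
    bg_mono = len(u_bg) == 1
    if fg_mono and bg_mono:
        return Pattern.P1
    if fg_mono:
        return Pattern.P2
    if bg_mono:
        return Pattern.P3
    return None


def classify_column(profile: ColumnProfile, groups: DiscoveryGroups) -> Optional[Pattern]:
    """Classify a profiled column; None means no CAAS.

    A column is skipped (None) when either group exceeds its gap or
    unknown tolerance, or when either group has no residue left.
    """
    if profile.fg_gaps > groups.max_fg_gaps or profile.fg_unknown > groups.max_fg_missing:
        return None
    if profile.bg_gaps > groups.max_bg_gaps or profile.bg_unknown > groups.max_bg_missing:
        return None
    return classify_chars(
        profile.fg_residues + (GAP,) * profile.fg_gaps + (UNKNOWN,) * profile.fg_unknown,
        profile.bg_residues + (GAP,) * profile.bg_gaps + (UNKNOWN,) * profile.bg_unknown,
        max_fg_missing=groups.max_fg_missing,
        max_bg_missing=groups.max_bg_missing,
        max_fg_gaps=groups.max_fg_gaps,
        max_bg_gaps=groups.max_bg_gaps,
    )


# ---------------------------------------------------------------------------
# empirical position p-values
# ---------------------------------------------------------------------------

def _column_chars(alignment: Alignment, column: int, species: Sequence[str]) -> List[str]:
    return [alignment.sequences[sp][column] for sp in species]


def _assignment_is_caas(
    chars: Sequence[str], fg_idx: Sequence[int], bg_idx: Sequence[int],
    groups: DiscoveryGroups,
) -> bool:
    return classify_chars(
        [chars[i] for i in fg_idx],
        [chars[i] for i in bg_idx],
        max_fg_missing=groups.max_fg_missing,
        max_bg_missing=groups.max_bg_missing,
        max_fg_gaps=groups.max_fg_gaps,
        max_bg_gaps=groups.max_bg_gaps,
    ) is not None


def n_assignments(pool_size: int, fg_size: int, bg_size: int) -> int:
    """Number of distinct ordered (FG, BG) draws from a pool."""
    return math.comb(pool_size, fg_size) * math.comb(pool_size - fg_size, bg_size)


def position_pvalue(
    alignment: Alignment,
    column: int,
    groups: DiscoveryGroups,
    mode: str = "auto",
    cycles: int = 10_000,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
    enumeration_cap: int = ENUMERATION_CAP,
) -> float:
    """Empirical probability of a CAAS at a column under randomized groups.

    Virtual groups keep the observed sizes and tolerance caps and are
    drawn without replacement from ``pool`` (default FG ∪ BG).  Exact
    mode enumerates every assignment and returns the true fraction;
    Monte-Carlo mode estimates it from ``cycles`` uniform draws using
    the (hits + 1)/(cycles + 1) convention.  mode='auto' enumerates
    when the number of assignments is at most ``enumeration_cap``.
    """
    if pool is None:
        pool = sorted(groups.fg | groups.bg)
    else:
        pool = sorted(pool)
    f, b = groups.fg_size, groups.bg_size
    if len(pool) < f + b:
        raise ValueError(
            f"resampling pool of {len(pool)} species is smaller than "
            f"fg_size + bg_size = {f + b}"
        )
    if mode not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown p-value mode {mode!r}")
    total = n_assignments(len(pool), f, b)
    if mode == "auto":
        mode = "exact" if total <= enumeration_cap else "mc"
    chars = _column_chars(alignment, column, pool)
    indices = range(len(pool))
    if mode == "exact":
        hits = 0
        for fg_idx in itertools.combinations(indices, f):
            rest = [i for i in indices if i not in fg_idx]
            for bg_idx in itertools.combinations(rest, b):
                if _assignment_is_caas(chars, fg_idx, bg_idx, groups):
                    hits += 1
        return hits / total
    if cycles < 1:
        raise ValueError("montecarlo mode needs cycles >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    n_pool = len(pool)
    for _ in range(cycles):
        perm = rng.permutation(n_pool)
        if _assignment_is_caas(chars, perm[:f], perm[f:f + b], groups):
            hits += 1
    return (hits + 1) / (cycles + 1)


def discover(
    alignment: Alignment,
    groups: DiscoveryGroups,
    patterns: FrozenSet[Pattern] = ALL_PATTERNS,
    pvalue_mode: str = "auto",
    cycles: int = 10_000,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> List[CAASRecord]:
    """Scan every column of an alignment for CAAS.

    Returns one record per column whose pattern is in ``patterns``, in
    ascending column order.  ``pvalue_mode`` of 'off' skips p-values;
    otherwise each record carries its empirical position p-value.
    Columns failing the missing-data tolerances are skipped silently
    (a count goes to the log).
    """
    patterns = frozenset(patterns)
    records: List[CAASRecord] = []
    n_skipped = 0
    for column in range(alignment.length):
        profile = profile_column(alignment, column, groups)
        if (
            profile.fg_gaps > groups.max_fg_gaps
            or profile.fg_unknown > groups.max_fg_missing
            or profile.bg_gaps > groups.max_bg_gaps
            or profile.bg_unknown > groups.max_bg_missing
        ):
            n_skipped += 1
            continue
        pattern = classify_column(profile, groups)
        if pattern is None or pattern not in patterns:
            continue
        pvalue = None
        if pvalue_mode != "off":
            pvalue = position_pvalue(
                alignment, column, groups,
                mode=pvalue_mode, cycles=cycles,
                seed=seed + column, pool=pool,
            )
        records.append(
            CAASRecord(
                alignment_id=alignment.id,
                position=column,
                pattern=pattern,
                fg_aas=frozenset(profile.fg_residues),
                bg_aas=frozenset(profile.bg_residues),
                fg_missing=profile.fg_missing,
                bg_missing=profile.bg_missing,
                pvalue=pvalue,
            )
        )
    if n_skipped:
        logger.info(
            "alignment %s: %d columns skipped for missing-data tolerance",
            alignment.id, n_skipped,
        )
    return records


# ---------------------------------------------------------------------------
# vectorized column classification (bitmask encoding)
# ---------------------------------------------------------------------------
# The bootstrap tool evaluates thousands of virtual group assignments
# against every column; doing that through the scalar path would
# dominate runtime.  Columns are encoded as integer codes, residue sets
# as 20-bit masks, and whole-alignment classification reduces to a few
# array operations per assignment.  Tests cross-check this path against
# classify_chars on random inputs.

def encode_alignment(alignment: Alignment, species_order: Sequence[str]) -> np.ndarray:
    """Encode sequences as an (n_species, length) int8 code matrix.

    Amino acids map to 0..19, '-' to GAP_CODE, 'X' to UNKNOWN_CODE.
    """
    mat = np.empty((len(species_order), alignment.length), dtype=np.int8)
    for row, sp in enumerate(species_order):
        seq = alignment.sequences[sp]
        mat[row] = [
            _AA_CODE[c] if c in _AA_CODE else (GAP_CODE if c == GAP else UNKNOWN_CODE)
            for c in seq
        ]
    return mat


def classify_matrix(
    codes: np.ndarray,
    fg_rows: Sequence[int],
    bg_rows: Sequence[int],
    max_fg_missing: int = 0,
    max_bg_missing: int = 0,
    max_fg_gaps: int = 0,
    max_bg_gaps: int = 0,
    bits: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Classify every column for one FG/BG row assignment.

    Returns an int8 array per column: 0 = no CAAS, 1/2/3 = P1/P2/P3.
    ``bits`` may carry the precomputed residue bitmask matrix
    (np.where(codes >= 0, 1 << codes, 0), int32) to amortize encoding
    across many assignments.
    """
    if bits is None:
        bits = np.where(codes >= 0, np.int32(1) << codes.astype(np.int32), np.int32(0))
    fg_rows = np.asarray(fg_rows, dtype=np.intp)
    bg_rows = np.asarray(bg_rows, dtype=np.intp)
    fg_codes = codes[fg_rows]
    bg_codes = codes[bg_rows]
    fg_mask = np.bitwise_or.reduce(bits[fg_rows], axis=0)
    bg_mask = np.bitwise_or.reduce(bits[bg_rows], axis=0)
    fg_count = np.bitwise_count(fg_mask)
    bg_count = np.bitwise_count(bg_mask)
    ok = (
        ((fg_codes == GAP_CODE).sum(axis=0) <= max_fg_gaps)
        & ((fg_codes == UNKNOWN_CODE).sum(axis=0) <= max_fg_missing)
        & ((bg_codes == GAP_CODE).sum(axis=0) <= max_bg_gaps)
        & ((bg_codes == UNKNOWN_CODE).sum(axis=0) <= max_bg_missing)
        & ((fg_mask & bg_mask) == 0)
        & (fg_count > 0)
        & (bg_count > 0)
    )
    out = np.zeros(codes.shape[1], dtype=np.int8)
    out[ok & (fg_count == 1) & (bg_count == 1)] = 1
    out[ok & (fg_count == 1) & (bg_count > 1)] = 2
    out[ok & (fg_count > 1) & (bg_count == 1)] = 3
    return out
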