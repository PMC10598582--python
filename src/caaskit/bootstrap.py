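"""Bootstrap counting of CAAS over virtual discovery groups.

For every alignment column the tool counts how many resampling
iterations (virtual FG/BG assignments) reproduce a CAAS there, and
reports the empirical p-value (hits + 1) / (cycles + 1) — the same
pseudocount convention the discovery tool uses for its Monte-Carlo
position p-values, so the two outputs are directly comparable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .discovery import ALL_PATTERNS, Pattern, classify_matrix, encode_alignment
from .io import Alignment
from .resample import ResampleSet

logger = logging.getLogger("caaskit")


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap outcome for one column (position is 0-based internally)."""

    alignment_id: str
    position: int
    hits: int
    cycles: int
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.cycles:
            raise ValueError("hits must lie in [0, cycles]")


def bootstrap_alignment(
    alignment: Alignment,
    resamples: ResampleSet,
    patterns: FrozenSet[Pattern] = ALL_PATTERNS,
    max_fg_missing: int = 0,
    max_bg_missing: int = 0,
    max_fg_gaps: int = 0,
    max_bg_gaps: int = 0,
    sparse: bool = False,
) -> List[BootstrapResult]:
    """Count, per column, the iterations whose virtual groups yield a CAAS.

    Iterations naming species absent from the alignment are dropped
    with a logged count (hard error if more than half are dropped).
    Iterations failing the per-group missing-data tolerance at a column
    count as non-hits there.  With sparse=True only columns with at
    least one hit are reported; otherwise every column is.
    """
    patterns = frozenset(patterns)
    wanted = np.zeros(4, dtype=bool)
    for pat in patterns:
        wanted[int(pat.value[1])] = True
    present = set(alignment.sequences)
    retained = [
        vdg for vdg in resamples if (vdg.fg | vdg.bg) <= present
    ]
    n_dropped = len(resamples) - len(retained)
    if n_dropped:
        logger.warning(
            "alignment %s: dropped %d/%d resampling iterations naming absent species",
            alignment.id, n_dropped, len(resamples),
        )
    if len(resamples) and n_dropped > len(resamples) / 2:
        raise ValueError(
            f"{n_dropped} of {len(resamples)} resampling iterations name species "
            f"absent from alignment {alignment.id!r}"
        )
    if not retained:
        raise ValueError("no resampling iterations left after filtering")
    species_order = sorted(present)
    row_of = {sp: i for i, sp in enumerate(species_order)}
    codes = encode_alignment(alignment, species_order)
    bits = np.where(codes >= 0, np.int32(1) << codes.astype(np.int32), np.int32(0))
    hits = np.zeros(alignment.length, dtype=np.int64)
    for vdg in retained:
        classes = classify_matrix(
            codes,
            fg_rows=[row_of[sp] for sp in sorted(vdg.fg)],
            bg_rows=[row_of[sp] for sp in sorted(vdg.bg)],
            max_fg_missing=max_fg_missing,
            max_bg_missing=max_bg_missing,
            max_fg_gaps=max_fg_gaps,
            max_bg_gaps=max_bg_gaps,
            bits=bits,
        )
        hits += wanted[classes]
    cycles = len(retained)
    results = []
    for column in range(alignment.length):
        h = int(hits[column])
        if sparse and h == 0:
            continue
        results.append(
            BootstrapResult(
                alignment_id=alignment.id,
                position=column,
                hits=h,
                cycles=cycles,
                pvalue=(h + 1) / (cycles + 1),
            )
        )
    return results


def merge_bootstrap(paths: Iterable, out_path=None) -> pd.DataFrame:
    """Concatenate per-alignment bootstrap TSVs into one table.

    No recomputation happens; duplicate (alignment_id, position) keys
    across inputs are a hard error.  An empty input list yields an
    empty table with the standard columns.
    """
    columns = ["alignment_id", "position", "hits", "cycles", "pvalue"]
    frames = []
    for path in paths:
        df = pd.read_csv(Path(path), sep="\t", comment="#")
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing bootstrap columns {sorted(missing)}")
        frames.append(df[columns])
    merged = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=columns)
    )
    dupes = merged.duplicated(subset=["alignment_id", "position"])
    if dupes.any():
        keys = merged.loc[dupes, ["alignment_id", "position"]].drop_duplicates()
        raise ValueError(
            "duplicate (alignment_id, position) keys across inputs: "
            + ", ".join(f"({r.alignment_id}, {r.position})" for r in keys.itertuples())
        )
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("# positions are 1-based\n")
            merged.to_csv(fh, sep="\t", index=False)
    return merged
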