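"""Readers and writers for the toolkit's file formats.

Alignments come in as FASTA or sequential PHYLIP, trees as newick,
and all configuration (discovery groups, continuous traits, clade
labels) as plain two-column TSV.  Output tables are TSV with a
comment header; alignment positions are 0-based inside the library
and 1-based in every file written.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("caaskit")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: symbols treated as "no residue observed" by the CAAS logic
MISSING_SYMBOLS = GAP + UNKNOWN
#: ambiguous or non-standard residue codes normalized to UNKNOWN on input
AMBIGUOUS_SYMBOLS = set("BJZUO*")
_VALID_SYMBOLS = frozenset(AMINO_ACIDS) | frozenset(MISSING_SYMBOLS)


def _normalize_sequence(raw: str, record_name: str) -> Tuple[str, int]:
    """Uppercase a sequence, map ambiguous codes to 'X', validate symbols.

    Returns the normalized string and the number of ambiguous symbols
    replaced.  Raises ValueError on symbols outside the amino-acid
    alphabet plus '-'/'X'.
    """
    seq = raw.upper()
    n_ambiguous = 0
    out = []
    for ch in seq:
        if ch in _VALID_SYMBOLS:
            out.append(ch)
        elif ch in AMBIGUOUS_SYMBOLS:
            out.append(UNKNOWN)
            n_ambiguous += 1
        else:
            raise ValueError(
                f"invalid residue symbol {ch!r} in sequence {record_name!r}"
            )
    return "".join(out), n_ambiguous


@dataclass
class Alignment:
    """An amino-acid multiple sequence alignment.

    ``sequences`` maps species name -> residue string.  All sequences
    must share one length; symbols are normalized to uppercase with
    ambiguous codes (B, J, Z, U, O, *) mapped to 'X'.
    """

    id: str
    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"alignment {self.id!r} contains no sequences")
        normalized: Dict[str, str] = {}
        n_ambiguous = 0
        ref_name = next(iter(self.sequences))
        ref_len = len(self.sequences[ref_name])
        if ref_len == 0:
            raise ValueError(f"sequence {ref_name!r} in {self.id!r} is empty")
        for name, seq in self.sequences.items():
            if len(seq) != ref_len:
                raise ValueError(
                    f"ragged alignment {self.id!r}: sequence {name!r} has "
                    f"length {len(seq)}, expected {ref_len} (as {ref_name!r})"
                )
            norm, n_amb = _normalize_sequence(seq, name)
            normalized[name] = norm
            n_ambiguous += n_amb
        if n_ambiguous:
            logger.warning(
                "alignment %s: %d ambiguous residue symbols normalized to 'X'",
                self.id, n_ambiguous,
            )
        self.sequences = normalized

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(self.sequences)

    def column(self, index: int) -> Dict[str, str]:
        """Residues of every species at a column (0-based)."""
        if not 0 <= index < self.length:
            raise IndexError(f"column {index} out of range for length {self.length}")
        return {name: seq[index] for name, seq in self.sequences.items()}


@dataclass(frozen=True)
class DiscoveryGroups:
    """The foreground (FG) and background (BG) species sets.

    Tolerances cap, per group and per column, how many gap ('-') and
    unknown ('X') symbols a column may contain and still be scanned;
    both default to zero.
    """

    fg: frozenset
    bg: frozenset
    max_fg_missing: int = 0
    max_bg_missing: int = 0
    max_fg_gaps: int = 0
    max_bg_gaps: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fg", frozenset(self.fg))
        object.__setattr__(self, "bg", frozenset(self.bg))
        if not self.fg or not self.bg:
            raise ValueError("both FG and BG must be non-empty")
        overlap = self.fg & self.bg
        if overlap:
            raise ValueError(
                f"species assigned to both FG and BG: {sorted(overlap)}"
            )
        for attr, size in (
            ("max_fg_missing", len(self.fg)),
            ("max_fg_gaps", len(self.fg)),
            ("max_bg_missing", len(self.bg)),
            ("max_bg_gaps", len(self.bg)),
        ):
            value = getattr(self, attr)
            if not 0 <= value < size:
                raise ValueError(
                    f"{attr}={value} must lie in [0, group size {size})"
                )

    @property
    def fg_size(self) -> int:
        return len(self.fg)

    @property
    def bg_size(self) -> int:
        return len(self.bg)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path, fmt: str = "fasta", alignment_id: Optional[str] = None) -> Alignment:
    """Read an amino-acid alignment from FASTA or sequential PHYLIP.

    The alignment id defaults to the file stem.
    """
    path = Path(path)
    if fmt not in ("fasta", "phylip"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if alignment_id is None:
        alignment_id = path.stem
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "phylip-sequential"))
        except ValueError as exc:
            raise ValueError(f"cannot parse {path} as sequential PHYLIP: {exc}") from exc
    if not records:
        raise ValueError(f"no sequences found in {path}")
    sequences: Dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate species name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return Alignment(id=alignment_id, sequences=sequences)


def write_alignment(alignment: Alignment, path, fmt: str = "fasta") -> None:
    """Write an alignment as FASTA or sequential PHYLIP."""
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in alignment.sequences.items()
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-sequential")
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path, rooting: str = "keep") -> dendropy.Tree:
    """Read a single newick tree.

    rooting='keep' treats the first node of the newick string as the
    root (deterministic for any input); rooting='midpoint' re-roots at
    the midpoint of the longest tip-to-tip path, which requires branch
    lengths.  Duplicate tip labels are a hard error.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"cannot parse newick tree in {path}: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(label is None for label in labels):
        raise ValueError(f"tree in {path} has unnamed tips")
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip names in {path}: {dupes}")
    tree.is_rooted = True
    if rooting == "midpoint":
        if any(e.length is None for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node):
            raise ValueError("midpoint rooting requires branch lengths on all edges")
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif rooting != "keep":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    return tree


def tree_tip_names(tree: dendropy.Tree) -> Tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# configuration tables
# ---------------------------------------------------------------------------

def _read_two_column_tsv(path) -> Iterable[Tuple[str, str]]:
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            yield parts[0].strip(), parts[1].strip()


def read_groups(
    path,
    max_fg_missing: int = 0,
    max_bg_missing: int = 0,
    max_fg_gaps: int = 0,
    max_bg_gaps: int = 0,
) -> DiscoveryGroups:
    """Read a species->{FG,BG} assignment from a two-column TSV.

    Rows with labels other than FG/BG are ignored with a warning.
    """
    fg, bg = set(), set()
    seen: Dict[str, str] = {}
    for species, label in _read_two_column_tsv(path):
        label_up = label.upper()
        if label_up not in ("FG", "BG"):
            logger.warning("%s: ignoring species %r with label %r", path, species, label)
            continue
        if species in seen and seen[species] != label_up:
            raise ValueError(
                f"species {species!r} listed under both FG and BG in {path}"
            )
        seen[species] = label_up
        (fg if label_up == "FG" else bg).add(species)
    if not fg or not bg:
        raise ValueError(f"groups file {path} must name at least one FG and one BG species")
    return DiscoveryGroups(
        fg=frozenset(fg),
        bg=frozenset(bg),
        max_fg_missing=max_fg_missing,
        max_bg_missing=max_bg_missing,
        max_fg_gaps=max_fg_gaps,
        max_bg_gaps=max_bg_gaps,
    )


def write_groups(groups: DiscoveryGroups, path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(groups.fg):
            fh.write(f"{sp}\tFG\n")
        for sp in sorted(groups.bg):
            fh.write(f"{sp}\tBG\n")


def read_trait_table(path) -> Dict[str, float]:
    """Read a species -> continuous trait value TSV."""
    values: Dict[str, float] = {}
    for species, raw in _read_two_column_tsv(path):
        if species in values:
            raise ValueError(f"duplicate species {species!r} in trait table {path}")
        try:
            values[species] = float(raw)
        except ValueError as exc:
            raise ValueError(
                f"non-numeric trait value {raw!r} for species {species!r} in {path}"
            ) from exc
    if not values:
        raise ValueError(f"empty trait table {path}")
    return values


def write_trait_table(values: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(values):
            fh.write(f"{sp}\t{values[sp]!r}\n")


def read_taxonomy(path) -> Dict[str, str]:
    """Read a species -> clade label TSV."""
    clade_of: Dict[str, str] = {}
    for species, clade in _read_two_column_tsv(path):
        if species in clade_of:
            raise ValueError(f"duplicate species {species!r} in taxonomy template {path}")
        clade_of[species] = clade
    if not clade_of:
        raise ValueError(f"empty taxonomy template {path}")
    return clade_of


def write_taxonomy(clade_of: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(clade_of):
            fh.write(f"{sp}\t{clade_of[sp]}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_POSITION_NOTE = "# positions are 1-based\n"


def write_caas_table(records, path) -> None:
    """Write discovery results as TSV (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write(_POSITION_NOTE)
        fh.write(
            "alignment_id\tposition\tpattern\tfg_aas\tbg_aas\t"
            "fg_missing\tbg_missing\tpvalue\n"
        )
        for rec in records:
            pvalue = "NA" if rec.pvalue is None else repr(rec.pvalue)
            fh.write(
                f"{rec.alignment_id}\t{rec.position + 1}\t{rec.pattern.value}\t"
                f"{','.join(sorted(rec.fg_aas))}\t{','.join(sorted(rec.bg_aas))}\t"
                f"{rec.fg_missing}\t{rec.bg_missing}\t{pvalue}\n"
            )


def write_bootstrap_table(results, path) -> None:
    """Write bootstrap results as TSV (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write(_POSITION_NOTE)
        fh.write("alignment_id\tposition\thits\tcycles\tpvalue\n")
        for res in results:
            fh.write(
                f"{res.alignment_id}\t{res.position + 1}\t{res.hits}\t"
                f"{res.cycles}\t{res.pvalue!r}\n"
            )
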