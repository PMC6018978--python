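"""Aligned K-domain families and the interacting-site partition.

An :class:`AlignedFamily` holds a gap-aware multiple sequence alignment of
K-domains together with a subfamily label per sequence and an optional map
from alignment columns to full-protein residue numbers (SEP3 numbering by
convention, e.g. column 1 -> residue 95).

The :class:`SitePartition` splits the analysed span into "interacting"
residues — the hydrophobic positions that mediate intra- and intermolecular
contacts in the SEP3 homotetramer — and the remaining, non-interacting
K-domain positions.  Crystal-structure work names 12 interacting leucines;
the partition defaults to those plus three further hydrophobic interface
positions that are an explicit, user-overridable choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALLOWED = set(AMINO_ACIDS) | {GAP, "X"}

#: the 12 interacting leucines of the SEP3 homotetramer (full-protein numbering)
INTERACTING_LEUCINES = (101, 108, 115, 120, 123, 128, 131, 135, 154, 157, 164, 171)
#: default extra interface positions completing the 15-residue interacting set
#: (a user-overridable modelling choice, not a published enumeration)
DEFAULT_EXTRA_INTERACTING = (105, 112, 150)
#: K-domain span analysed by default, SEP3 numbering
KDOMAIN_SPAN = (95, 181)


@dataclass
class AlignedFamily:
    """Aligned K-domain sequences with per-sequence subfamily labels."""

    ids: list[str]
    subfamilies: list[str]
    rows: list[str]
    column_map: dict[int, int] | None = None  # 1-based column -> protein position
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or len(self.subfamilies) != len(self.rows):
            raise ValidationError("ids, subfamilies and rows must have equal length")
        if not self.rows:
            raise ValidationError("family must contain at least one sequence")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValidationError(f"sequence {sid!r} has length {len(row)} != {width}")
            bad = set(row) - ALLOWED
            if bad:
                raise ValidationError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """Residues of 1-based alignment column ``col``."""
        if not 1 <= col <= self.n_cols:
            raise ValidationError(f"column {col} outside 1..{self.n_cols}")
        return "".join(row[col - 1] for row in self.rows)

    def position_of(self, col: int) -> int | None:
        """Full-protein position mapped to a 1-based column, if known."""
        return None if self.column_map is None else self.column_map.get(col)

    def column_for_position(self, position: int) -> int:
        if self.column_map is None:
            raise ValidationError("family has no column map")
        for col, pos in self.column_map.items():
            if pos == position:
                return col
        raise ValidationError(f"position {position} not covered by the column map")

    def subfamily_names(self) -> list[str]:
        seen: list[str] = []
        for name in self.subfamilies:
            if name not in seen:
                seen.append(name)
        return seen

    def subset(self, subfamily: str) -> "AlignedFamily":
        idx = [i for i, s in enumerate(self.subfamilies) if s == subfamily]
        if not idx:
            raise ValidationError(f"no sequences labelled {subfamily!r}")
        return AlignedFamily(
            ids=[self.ids[i] for i in idx],
            subfamilies=[subfamily] * len(idx),
            rows=[self.rows[i] for i in idx],
            column_map=self.column_map,
            label=self.label,
        )

    # -- I/O ----------------------------------------------------------------

    def to_fasta(self, fasta_path, labels_path=None) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description=sub)
            for sid, sub, row in zip(self.ids, self.subfamilies, self.rows)
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                fh.write("id\tsubfamily\n")
                for sid, sub in zip(self.ids, self.subfamilies):
                    fh.write(f"{sid}\t{sub}\n")

    @classmethod
    def from_fasta(cls, fasta_path, labels_path=None, column_map=None, label="") -> "AlignedFamily":
        try:
            records = list(SeqIO.parse(str(fasta_path), "fasta"))
        except ValueError as exc:
            raise ValidationError(f"{fasta_path}: malformed FASTA ({exc})") from None
        if not records:
            raise ValidationError(f"{fasta_path}: no sequences found")
        ids = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        if labels_path is not None:
            table: dict[str, str] = {}
            with open(labels_path) as fh:
                header = fh.readline()
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    sid, sub = line.rstrip("\n").split("\t")[:2]
                    table[sid] = sub
            missing = [sid for sid in ids if sid not in table]
            if missing:
                raise ValidationError(f"labels file lacks entries for ids: {missing}")
            subfamilies = [table[sid] for sid in ids]
        else:
            # fall back to the FASTA description word, else a single block
            subfamilies = [
                r.description.split(maxsplit=1)[1].strip() if " " in r.description else "all"
                for r in records
            ]
        return cls(ids=ids, subfamilies=subfamilies, rows=rows, column_map=column_map, label=label)


def default_column_map(n_cols: int, span: tuple[int, int] = KDOMAIN_SPAN) -> dict[int, int]:
    """Map columns 1..n to consecutive protein positions starting at span[0]."""
    start = span[0]
    return {c: start + c - 1 for c in range(1, n_cols + 1)}


@dataclass(frozen=True)
class SitePartition:
    """Interacting vs non-interacting K-domain positions (protein numbering)."""

    interacting: frozenset[int]
    non_interacting: frozenset[int]

    def __post_init__(self) -> None:
        if self.interacting & self.non_interacting:
            raise ValidationError("interacting and non-interacting sets overlap")
        if not self.interacting or not self.non_interacting:
            raise ValidationError("both site classes must be non-empty")

    @classmethod
    def default(
        cls,
        span: tuple[int, int] = KDOMAIN_SPAN,
        extra_interacting: tuple[int, ...] = DEFAULT_EXTRA_INTERACTING,
    ) -> "SitePartition":
        interacting = frozenset(INTERACTING_LEUCINES) | frozenset(extra_interacting)
        lo, hi = span
        outside = [p for p in interacting if not lo <= p <= hi]
        if outside:
            raise ValidationError(f"interacting positions outside span: {outside}")
        non = frozenset(range(lo, hi + 1)) - interacting
        return cls(interacting=interacting, non_interacting=non)
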