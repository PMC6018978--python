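"""CArG-box motif scanning and probe geometry on EMSA DNA probes.

Two probe fixtures ship with the package, letter-for-letter as designed for
the binding assays: a 151-nt probe carrying two CArG boxes spaced six
helical turns apart (cooperativity titrations) and a 51-nt probe with a
single central CArG box (saturation assays).  The CArG consensus is
CC(A/T)6GG; the exact box used on both probes is CCAAATAAGG.

Coordinates are 0-based half-open internally; report writers emit 1-based
inclusive coordinates and say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq

from .exceptions import ValidationError

__all__ = [
    "ProbeRecord",
    "MotifHit",
    "CARG_BOX",
    "CARG_CONSENSUS",
    "two_carg_probe",
    "single_carg_probe",
    "load_probe",
    "scan_exact",
    "scan_consensus",
    "spacing",
    "hits_to_bed",
]

DNA = set("ACGT")
#: the exact CArG box used on all probes
CARG_BOX = "CCAAATAAGG"
#: the CArG consensus, W = A or T
CARG_CONSENSUS = "CCWWWWWWGG"
_WILDCARDS = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT"}
BP_PER_TURN = 10.5


@dataclass(frozen=True)
class ProbeRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA
        if bad:
            raise ValidationError(f"probe {self.id}: non-ACGT symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "ProbeRecord":
        return ProbeRecord(
            id=self.id + "_rc",
            sequence=str(Seq(self.sequence).reverse_complement()),
            description=self.description,
        )


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    matched: str  # the motif as read on the reported strand


def load_probe(path) -> ProbeRecord:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{path}: expected exactly one probe record")
    r = records[0]
    return ProbeRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)


def _fixture(name: str) -> ProbeRecord:
    ref = resources.files("madskit.data").joinpath(name)
    with resources.as_file(ref) as path:
        return load_probe(path)


def two_carg_probe() -> ProbeRecord:
    """The 151-nt probe with two CArG boxes six helical turns apart."""
    return _fixture("probe_2carg.fa")


def single_carg_probe() -> ProbeRecord:
    """The 51-nt probe with a single central CArG box."""
    return _fixture("probe_1carg.fa")


def _validate_pattern(pattern: str, allowed: str) -> None:
    if not pattern:
        raise ValidationError("motif/pattern must be non-empty")
    bad = set(pattern) - set(allowed)
    if bad:
        raise ValidationError(f"invalid symbols in pattern: {sorted(bad)}")


def _scan_strand(sequence: str, matcher, length: int, strand: str, seq_len: int) -> list[MotifHit]:
    hits = []
    for i in range(len(sequence) - length + 1):
        window = sequence[i : i + length]
        if matcher(window):
            if strand == "+":
                start = i
            else:  # position on the forward coordinate system
                start = seq_len - i - length
            hits.append(MotifHit(start=start, end=start + length, strand=strand, matched=window))
    return hits


def scan_exact(probe: ProbeRecord, motif: str = CARG_BOX, both_strands: bool = False) -> list[MotifHit]:
    """All exact (possibly overlapping) occurrences of a motif, sorted by start."""
    _validate_pattern(motif, "ACGT")
    hits = _scan_strand(probe.sequence, lambda w: w == motif, len(motif), "+", len(probe))
    if both_strands:
        rc = str(Seq(probe.sequence).reverse_complement())
        hits += _scan_strand(rc, lambda w: w == motif, len(motif), "-", len(probe))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_consensus(
    probe: ProbeRecord, pattern: str = CARG_CONSENSUS, both_strands: bool = False
) -> list[MotifHit]:
    """All matches of a consensus pattern (exact bases plus W = A/T)."""
    _validate_pattern(pattern, "ACGTW")
    allowed = [_WILDCARDS[c] for c in pattern]

    def matcher(window: str) -> bool:
        return all(base in ok for base, ok in zip(window, allowed))

    hits = _scan_strand(probe.sequence, matcher, len(pattern), "+", len(probe))
    if both_strands:
        rc = str(Seq(probe.sequence).reverse_complement())
        hits += _scan_strand(rc, matcher, len(pattern), "-", len(probe))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def spacing(hits: list[MotifHit], bp_per_turn: float = BP_PER_TURN) -> tuple[int, float]:
    """Start-to-start spacing of exactly two same-strand hits, in bp and helical turns."""
    if len(hits) != 2:
        raise ValidationError(f"spacing requires exactly 2 hits, got {len(hits)}")
    a, b = hits
    if a.strand != b.strand:
        raise ValidationError("spacing requires both hits on the same strand")
    if bp_per_turn <= 0:
        raise ValidationError("bp_per_turn must be positive")
    bp = abs(b.start - a.start)
    return bp, bp / bp_per_turn


def hits_to_bed(probe: ProbeRecord, hits: list[MotifHit]) -> str:
    """BED-like TSV (0-based half-open, as in BED) for a list of hits."""
    lines = ["#probe_id\tstart\tend\tstrand\tmatched"]
    for h in hits:
        lines.append(f"{probe.id}\t{h.start}\t{h.end}\t{h.strand}\t{h.matched}")
    return "\n".join(lines) + "\n"
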