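"""In-silico mutagenesis: point-substitution and domain-swap constructs.

Constructs are named the way bench scientists name them: ``L164P`` is
"leucine 164 to proline", double mutants are hyphen-joined
(``E161L-N168L``).  Positions are 1-based coordinates in the full-length
protein, not alignment columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .exceptions import CoordinateError, ParseError, ValidationError
from .family import AMINO_ACIDS

__all__ = [
    "Substitution",
    "SubstitutionSpec",
    "ChimeraSpec",
    "parse_spec",
    "format_spec",
    "apply_spec",
    "make_chimera",
]

_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based, full-protein coordinates
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        for aa in (self.from_aa, self.to_aa):
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"{aa!r} is not a canonical amino acid")
        if self.from_aa == self.to_aa:
            raise ValidationError(
                f"substitution at {self.position} replaces {self.from_aa} with itself"
            )
        if self.position < 1:
            raise ValidationError("positions are 1-based")

    def inverted(self) -> "Substitution":
        return Substitution(self.position, self.to_aa, self.from_aa)

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class SubstitutionSpec:
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"duplicate positions in spec: {positions}")
        if positions != sorted(positions):
            raise ValidationError("substitutions must be ordered by position")

    def inverted(self) -> "SubstitutionSpec":
        return SubstitutionSpec(tuple(s.inverted() for s in self.substitutions))


@dataclass(frozen=True)
class ChimeraSpec:
    """Replace host_region of a host protein by donor_region of a donor."""

    host_region: tuple[int, int]  # 1-based inclusive
    donor_region: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (start, end) in (("host", self.host_region), ("donor", self.donor_region)):
            if start < 1 or start > end:
                raise ValidationError(f"{name}_region ({start}, {end}) is empty or invalid")


def parse_spec(text: str) -> SubstitutionSpec:
    """Parse a hyphen-joined mutation string such as ``"E161L-N168L"``."""
    if not text or not text.strip():
        raise ParseError("empty mutation string")
    subs = []
    for token in text.strip().split("-"):
        m = _TOKEN.match(token)
        if not m:
            raise ParseError(f"malformed mutation token {token!r} (expected e.g. 'L164P')")
        from_aa, pos, to_aa = m.group(1), int(m.group(2)), m.group(3)
        try:
            subs.append(Substitution(pos, from_aa, to_aa))
        except ValidationError as exc:
            raise ParseError(f"invalid token {token!r}: {exc}") from None
    subs.sort(key=lambda s: s.position)
    return SubstitutionSpec(tuple(subs))


def format_spec(spec: SubstitutionSpec) -> str:
    return "-".join(str(s) for s in spec.substitutions)


def apply_spec(sequence: str, spec: SubstitutionSpec) -> str:
    """Apply substitutions; the wild-type residue must match at every site."""
    chars = list(sequence)
    for sub in spec.substitutions:
        idx = sub.position - 1
        if idx >= len(chars):
            raise CoordinateError(
                f"position {sub.position} beyond sequence length {len(chars)}"
            )
        found = chars[idx]
        if found != sub.from_aa:
            raise CoordinateError(
                f"position {sub.position}: expected {sub.from_aa}, found {found}"
            )
        chars[idx] = sub.to_aa
    return "".join(chars)


def make_chimera(host: str, donor: str, spec: ChimeraSpec) -> str:
    """Replace the host region by the donor region (1-based inclusive)."""
    h0, h1 = spec.host_region
    d0, d1 = spec.donor_region
    if h1 > len(host):
        raise ValidationError(f"host_region {spec.host_region} beyond host length {len(host)}")
    if d1 > len(donor):
        raise ValidationError(f"donor_region {spec.donor_region} beyond donor length {len(donor)}")
    return host[: h0 - 1] + donor[d0 - 1 : d1] + host[h1:]
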