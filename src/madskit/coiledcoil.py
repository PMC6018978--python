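"""Heptad-repeat register annotation, helical wheels, and a periodicity score.

The K-domain comprises three coiled-coil-forming subdomains (K1, K2, K3)
with heptad repeats [abcdefg]_n whose 'a' and 'd' positions carry the
hydrophobic interface.  The register phase is anchored per subdomain:
published assignments fix L164 and L145 at 'd' and E161/N168 at 'a', which
is only consistent with distinct phases for K2 and K3, so each annotated
span carries its own anchor.  The K1 anchor is not constrained by published
assignments and is a configurable default.

:func:`heptad_periodicity_score` is a deliberately simple sliding-window
score of hydrophobic periodicity (best-of-seven-phases fraction of 'a'/'d'
positions occupied by hydrophobic residues).  It is a substitute for
coiled-coil predictors such as COILS, not a reimplementation of their
probabilistic scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "HeptadSpan",
    "DEFAULT_SPANS",
    "heptad_register",
    "helical_wheel",
    "heptad_periodicity_score",
    "HYDROPHOBIC",
    "WHEEL_STEP_DEG",
]

REGISTERS = "abcdefg"
#: residues counted as hydrophobic at 'a'/'d' positions
HYDROPHOBIC = frozenset("LIVMFAWY")
#: angular advance per residue on a coiled-coil helical wheel (7 residues / 2 turns)
WHEEL_STEP_DEG = 720.0 / 7.0
#: window sizes accepted by the periodicity score (the conventional choices)
PERIODICITY_WINDOWS = (14, 21, 28)


@dataclass(frozen=True)
class HeptadSpan:
    """One annotated heptad-repeat span with its register anchor.

    ``a_anchor`` is a residue position (full-protein numbering) assigned
    register 'a'; every other register in the span follows mod 7.
    """

    name: str
    start: int
    end: int
    a_anchor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"span {self.name}: start > end")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def register(self, position: int) -> str:
        return REGISTERS[(position - self.a_anchor) % 7]


#: default K-subdomain annotation (SEP3 numbering).  K2/K3 anchors follow the
#: published register assignments (145->d; 161,168->a; hence 164->d and the
#: M150/L157/L164/L171 stripe all at 'd'); the K1 anchor places the zipper
#: leucines 101/108/115 at 'd' and is a configurable choice.
DEFAULT_SPANS = (
    HeptadSpan("K1", 94, 119, a_anchor=98),
    HeptadSpan("K2", 126, 149, a_anchor=142),
    HeptadSpan("K3", 150, 181, a_anchor=161),
)


def heptad_register(position: int, spans: Sequence[HeptadSpan] = DEFAULT_SPANS) -> str:
    """Register letter ('a'..'g') of a residue position within annotated spans."""
    for span in spans:
        if span.contains(position):
            return span.register(position)
    covered = ", ".join(f"{s.name}:{s.start}-{s.end}" for s in spans)
    raise ValidationError(f"position {position} outside annotated heptad spans ({covered})")


def helical_wheel(window: str, start_register: str = "a") -> list[tuple[str, float]]:
    """Project residues onto a coiled-coil helical wheel.

    Consecutive residues advance by 720/7 ≈ 102.86 degrees, so residues
    seven apart coincide.  By convention register 'a' sits at 0 degrees;
    ``start_register`` sets the register of the first residue.
    """
    if not window:
        raise ValidationError("window must be non-empty")
    if start_register not in REGISTERS:
        raise ValidationError(f"start_register must be one of {REGISTERS!r}")
    offset = REGISTERS.index(start_register) * WHEEL_STEP_DEG
    return [
        (residue, (offset + i * WHEEL_STEP_DEG) % 360.0)
        for i, residue in enumerate(window)
    ]


def heptad_periodicity_score(
    sequence: str,
    window: int = 21,
    hydrophobic: frozenset[str] = HYDROPHOBIC,
) -> np.ndarray:
    """Per-residue hydrophobic heptad-periodicity score in [0, 1].

    For every window placement the score is the best, over the seven
    possible register phases, of the fraction of 'a'/'d' positions occupied
    by hydrophobic residues.  Each residue reports the maximum over all
    windows covering it (so an ideal leucine zipper scores 1 at interior
    positions).  ``window`` must be one of 14, 21, or 28 and no longer than
    the sequence.
    """
    if window not in PERIODICITY_WINDOWS:
        raise ValidationError(f"window must be one of {PERIODICITY_WINDOWS}")
    n = len(sequence)
    if n < window:
        raise ValidationError(f"sequence length {n} shorter than window {window}")
    is_h = np.array([r in hydrophobic for r in sequence], dtype=float)
    window_scores = np.empty(n - window + 1)
    for start in range(n - window + 1):
        best = 0.0
        for phase in range(7):
            idx = [
                i
                for i in range(start, start + window)
                if (i - start + phase) % 7 in (0, 3)  # 'a' and 'd'
            ]
            frac = is_h[idx].mean()
            if frac > best:
                best = frac
        window_scores[start] = best
    per_residue = np.zeros(n)
    for start, score in enumerate(window_scores):
        end = start + window
        per_residue[start:end] = np.maximum(per_residue[start:end], score)
    return per_residue
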