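"""Synthetic EMSA titrations, saturation series, and aligned K-domain families.

This module stands in for the wet-lab inputs of the analysis: quantified gel
band intensities and a curated alignment of MIKC-type K-domain sequences.
Every generator is a pure function of its parameters and seed.

Noise model for gel quantification: additive Gaussian perturbation on each
band fraction, clipping to [0, 1], an optional detection floor (faint bands
read as zero), and per-lane renormalization — the simplest model consistent
with densitometry of three bands that must sum to the lane total.

Families are drawn column-independently from per-column amino-acid
distributions.  The shipped presets emulate the conservation structure of
MIKC-type subfamilies: near-invariant leucine at the interacting positions
in SEP3-like sequences, alternative hydrophobic or polar residues at
homologous tetramerization-interface positions in AP3-/PI-like sequences,
and diffuse variability elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binding import (
    SaturationSeries,
    TitrationSeries,
    fraction_matrix,
    predict_saturation,
)
from .exceptions import ValidationError
from .family import (
    AMINO_ACIDS,
    AlignedFamily,
    DEFAULT_EXTRA_INTERACTING,
    INTERACTING_LEUCINES,
    KDOMAIN_SPAN,
)

__all__ = [
    "NoiseModel",
    "ColumnProfile",
    "simulate_titration",
    "simulate_saturation",
    "simulate_family",
    "preset_profiles",
    "default_protein_ladder",
    "default_probe_ladder",
    "PRESET_STYLES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on band fractions, with a detection floor."""

    sd: float = 0.05
    detection_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if not 0 <= self.detection_floor < 0.5:
            raise ValidationError("detection_floor must lie in [0, 0.5)")


def default_protein_ladder(n: int = 12, lo: float = 0.05, hi: float = 3.0) -> np.ndarray:
    """Log-spaced applied-protein amounts, 0.05 to 3 volume units.

    The default range mirrors the cooperative-binding EMSA protocol this
    generator emulates, where 0.05 to 3 microlitres of translation mix are
    titrated against a constant two-site probe.
    """
    return np.geomspace(lo, hi, n)


def default_probe_ladder(n: int = 12, lo: float = 0.05, hi: float = 32.0) -> np.ndarray:
    """Geometric probe ladder, 0.05 to 32 units, as used in saturation assays."""
    return np.geomspace(lo, hi, n)


def simulate_titration(
    kd1: float,
    kcoop: float,
    protein_amounts: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    label: str = "sim",
    probe_id: str = "probe_2carg",
) -> TitrationSeries:
    """Simulate an EMSA titration of a two-site probe.

    With ``noise.sd == 0`` and no detection floor the output fractions are
    bitwise-identical to the forward model.  Lanes where flooring removes
    all three bands are recorded as all-free probe (an undetectable lane
    reads as unshifted on a gel).
    """
    if kd1 <= 0 or kcoop <= 0:
        raise ValidationError("kd1 and kcoop must be positive")
    noise = noise or NoiseModel(sd=0.0)
    p = default_protein_ladder() if protein_amounts is None else np.asarray(protein_amounts, float)
    if p.size < 1:
        raise ValidationError("need at least one protein amount")
    kd2 = kd1 / kcoop
    y = fraction_matrix(p, kd1, kd2)
    y = _perturb(y, noise)
    return TitrationSeries.from_arrays(
        p, y, label=label, probe_id=probe_id, renormalize=False
    )


def _perturb(y: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Apply the noise model; exact identity when it is a no-op."""
    if noise.sd == 0 and noise.detection_floor == 0:
        return y
    out = y.astype(float).copy()
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        out = np.clip(out + rng.normal(0.0, noise.sd, size=out.shape), 0.0, 1.0)
    if noise.detection_floor > 0:
        out[out < noise.detection_floor] = 0.0
    sums = out.sum(axis=1)
    dead = sums == 0
    out[dead] = [1.0, 0.0, 0.0]
    sums[dead] = 1.0
    return out / sums[:, None]


def simulate_saturation(
    pt: float,
    kd: float,
    probe_amounts: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    label: str = "sim",
) -> SaturationSeries:
    """Simulate a saturation binding series over a free-probe ladder.

    ``noise.sd`` is interpreted relative to the plateau: the additive
    Gaussian sd on bound signal is ``sd * pt``, so sd=0.05 perturbs by 5%
    of total protein — the same magnitude the titration noise model applies
    to band fractions.
    """
    if pt <= 0 or kd <= 0:
        raise ValidationError("pt and kd must be positive")
    noise = noise or NoiseModel(sd=0.0)
    d = default_probe_ladder() if probe_amounts is None else np.asarray(probe_amounts, float)
    if d.size < 1:
        raise ValidationError("need at least one probe amount")
    b = predict_saturation(d, pt, kd)
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        b = np.clip(b + rng.normal(0.0, noise.sd * pt, size=b.shape), 0.0, None)
    if noise.detection_floor > 0:
        b = np.where(b < noise.detection_floor * pt, 0.0, b)
    return SaturationSeries.from_arrays(d, b, label=label)


# ---------------------------------------------------------------------------
# synthetic aligned families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnProfile:
    """Amino-acid distribution for one alignment column."""

    position: int  # full-protein position (1-based)
    distribution: dict[str, float]

    def __post_init__(self) -> None:
        if not self.distribution:
            raise ValidationError("empty column distribution")
        bad = set(self.distribution) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(f"non-canonical residues in profile: {sorted(bad)}")
        total = sum(self.distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {total}, not 1")

    def letters_probs(self) -> tuple[list[str], list[float]]:
        letters = sorted(self.distribution)
        return letters, [self.distribution[a] for a in letters]


def simulate_family(
    profiles: Sequence[ColumnProfile],
    n_seqs: int,
    label: str,
    seed: int = 0,
) -> AlignedFamily:
    """Draw an aligned family column-independently from per-column profiles."""
    if not profiles:
        raise ValidationError("need at least one column profile")
    if n_seqs < 2:
        raise ValidationError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    columns = []
    for prof in profiles:
        letters, probs = prof.letters_probs()
        columns.append(rng.choice(list(letters), size=n_seqs, p=probs))
    mat = np.column_stack(columns)
    rows = ["".join(row) for row in mat]
    ids = [f"{label}_{i + 1:03d}" for i in range(n_seqs)]
    column_map = {c + 1: profiles[c].position for c in range(len(profiles))}
    return AlignedFamily(
        ids=ids, subfamilies=[label] * n_seqs, rows=rows, column_map=column_map, label=label
    )


# -- presets ---------------------------------------------------------------

PRESET_STYLES = ("SEP3-like", "AP3-like", "PI-like", "background")

# diffuse templates cycled over non-interacting columns: mixed conservation
# levels typical of the K-domain outside the hydrophobic interface
_BACKGROUND_TEMPLATES = (
    {"S": 0.20, "T": 0.15, "N": 0.15, "D": 0.15, "E": 0.15, "K": 0.10, "Q": 0.10},
    {"E": 0.25, "K": 0.20, "R": 0.15, "Q": 0.15, "D": 0.10, "N": 0.10, "S": 0.05},
    {"A": 0.20, "V": 0.15, "S": 0.15, "T": 0.15, "L": 0.10, "E": 0.15, "G": 0.10},
    {"Q": 0.30, "E": 0.20, "H": 0.10, "N": 0.15, "K": 0.10, "R": 0.10, "S": 0.05},
    {"L": 0.15, "M": 0.10, "I": 0.10, "E": 0.20, "Q": 0.15, "S": 0.15, "A": 0.15},
)

_HIGH_LEUCINE = {"L": 0.95, "M": 0.02, "I": 0.02, "V": 0.01}
_HIGH_MET = {"M": 0.90, "L": 0.05, "I": 0.05}
_HIGH_ILE = {"I": 0.80, "V": 0.10, "L": 0.10}

# AP3-/PI-like replacements at tetramerization-interface positions: the
# SEP3 'd'-position leucines 157 and 164 are threonine and glutamine in
# AP3; PI-like proteins favour other polar residues there.
_AP3_OVERRIDES = {
    154: {"M": 0.60, "I": 0.25, "L": 0.15},
    157: {"T": 0.85, "S": 0.10, "A": 0.05},
    164: {"Q": 0.85, "E": 0.10, "H": 0.05},
    171: {"L": 0.50, "M": 0.30, "I": 0.20},
}
_PI_OVERRIDES = {
    154: {"I": 0.55, "V": 0.30, "M": 0.15},
    157: {"S": 0.60, "T": 0.30, "A": 0.10},
    164: {"T": 0.55, "S": 0.25, "N": 0.20},
    171: {"M": 0.50, "L": 0.30, "I": 0.20},
}


def preset_profiles(
    style: str,
    span: tuple[int, int] = KDOMAIN_SPAN,
    leucine_prob: float = 0.95,
    extra_interacting: tuple[int, ...] = DEFAULT_EXTRA_INTERACTING,
) -> list[ColumnProfile]:
    """Column profiles emulating subfamily-specific K-domain conservation.

    ``SEP3-like`` places probability ``leucine_prob`` on leucine at the 12
    interacting-leucine positions and conserved hydrophobics at the extra
    interface positions; ``AP3-like``/``PI-like`` swap the central
    tetramerization-interface leucines for the alternative residues those
    subfamilies prefer; ``background`` is diffuse everywhere (null model).
    """
    if style not in PRESET_STYLES:
        raise ValidationError(f"unknown style {style!r}; choose from {PRESET_STYLES}")
    lo, hi = span
    leucine_dist = dict(_HIGH_LEUCINE)
    if leucine_prob != 0.95:
        rest = 1.0 - leucine_prob
        leucine_dist = {"L": leucine_prob, "M": rest / 2, "I": rest / 2}
    profiles = []
    for i, pos in enumerate(range(lo, hi + 1)):
        dist = _BACKGROUND_TEMPLATES[i % len(_BACKGROUND_TEMPLATES)]
        if style != "background":
            if pos in INTERACTING_LEUCINES:
                dist = leucine_dist
            elif pos in extra_interacting:
                dist = _HIGH_MET if pos == 150 else _HIGH_ILE
            if style == "AP3-like" and pos in _AP3_OVERRIDES:
                dist = _AP3_OVERRIDES[pos]
            elif style == "PI-like" and pos in _PI_OVERRIDES:
                dist = _PI_OVERRIDES[pos]
        profiles.append(ColumnProfile(position=pos, distribution=dict(dist)))
    return profiles
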