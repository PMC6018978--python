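"""Alignment-column conservation scoring and site-class statistics.

The central statistic is the *mean relative sequence similarity* of an
alignment column: every unordered pair of residues (a, b) in the column is
scored with a substitution-matrix entry normalized to a maximum of 1,

    s(a, b) = 1/2 * ( B(a, b) / max_row(a) + B(a, b) / max_row(b) )

where ``max_row(x)`` is the largest matrix entry in row x over the 20
canonical residues (the diagonal for every BLOSUM matrix shipped here), and
the column score is the average of s over all pairs.  A column of identical
residues scores exactly 1; negative normalized scores are retained so the
average is not biased upward.  BLOSUM40 is the default matrix, matching the
~40% identity regime of K-domain alignments.

Interacting vs non-interacting site classes are compared with a two-sided
Mann–Whitney U test: exact enumeration for small classes (both sizes <= 8,
handling ties via midranks), tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .exceptions import ValidationError
from .family import AMINO_ACIDS, GAP, AlignedFamily, SitePartition

__all__ = [
    "NormalizedMatrix",
    "SimilarityProfile",
    "MannWhitneyResult",
    "load_matrix",
    "column_similarity",
    "similarity_profile",
    "compare_site_classes",
    "mann_whitney",
    "aa_frequency",
    "hydropathy_profile",
    "HYDROPATHY_SCALES",
]

_EXACT_MAX_CLASS = 8  # both classes at most this size -> exact enumeration


# ---------------------------------------------------------------------------
# normalized substitution matrices
# ---------------------------------------------------------------------------

class NormalizedMatrix:
    """A substitution matrix with rows normalized to a maximum of 1.

    normalization
        ``"symmetric"`` (default): mean of both single-sided normalizations,
        making s(a, b) symmetric.  ``"first"``/``"second"``: divide by the
        row maximum of only the first or second residue of the pair.
    """

    def __init__(self, name: str = "BLOSUM40", normalization: str = "symmetric"):
        if normalization not in ("symmetric", "first", "second"):
            raise ValidationError(f"unknown normalization {normalization!r}")
        self.name = name
        self.normalization = normalization
        raw = _load_raw_matrix(name)
        self._index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        row_max = raw.max(axis=1)
        if np.any(row_max <= 0):
            raise ValidationError(f"{name}: non-positive row maximum")
        left = raw / row_max[:, None]
        right = raw / row_max[None, :]
        if normalization == "symmetric":
            self.pair_scores = 0.5 * (left + right)
        elif normalization == "first":
            self.pair_scores = left
        else:
            self.pair_scores = right

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.pair_scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ValidationError(f"residue {exc} not in the 20-letter alphabet") from None


def _load_raw_matrix(name: str) -> np.ndarray:
    """Load a 20x20 substitution matrix (canonical residue order) by name."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alph = bseq.ProteinSequence.alphabet
    try:
        mat = balign.SubstitutionMatrix(alph, alph, name)
    except Exception as exc:
        raise ValidationError(f"cannot load substitution matrix {name!r}: {exc}") from None
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat.get_score(a, b)
    return out


def load_matrix(name: str = "BLOSUM40", normalization: str = "symmetric") -> NormalizedMatrix:
    return NormalizedMatrix(name, normalization)


# ---------------------------------------------------------------------------
# column similarity
# ---------------------------------------------------------------------------

def column_similarity(column: str | Sequence[str], matrix: NormalizedMatrix | None = None) -> float:
    """Mean normalized pairwise similarity of one alignment column.

    Gaps and 'X' are excluded pairwise; with fewer than two usable residues
    the column is missing (NaN).  Identical columns score exactly 1 when the
    matrix row maxima lie on the diagonal (true for all BLOSUM matrices).
    """
    matrix = matrix or _default_matrix()
    residues = [r for r in column if r not in (GAP, "X")]
    if len(residues) < 2:
        return float("nan")
    counts = np.zeros(20)
    for r in residues:
        try:
            counts[AMINO_ACIDS.index(r)] += 1
        except ValueError:
            raise ValidationError(f"invalid residue {r!r} in column") from None
    s = matrix.pair_scores
    total = counts @ s @ counts - counts @ np.diag(s)
    n = len(residues)
    return float(total / (n * (n - 1)))


_DEFAULT_MATRIX: NormalizedMatrix | None = None


def _default_matrix() -> NormalizedMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = NormalizedMatrix()
    return _DEFAULT_MATRIX


@dataclass
class SimilarityProfile:
    """Per-column mean relative similarity over an aligned family."""

    columns: np.ndarray  # 1-based alignment columns
    positions: np.ndarray  # mapped protein positions (-1 where unmapped)
    scores: np.ndarray  # NaN = missing (fewer than 2 usable residues)
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": self.columns,
                "position": self.positions,
                "similarity": self.scores,
                "n_pairs": self.n_pairs,
            }
        )

    def scores_at(self, positions: Sequence[int]) -> np.ndarray:
        """Non-missing scores at the given protein positions."""
        wanted = set(positions)
        mask = np.array([p in wanted for p in self.positions])
        vals = self.scores[mask]
        return vals[~np.isnan(vals)]


def similarity_profile(family: AlignedFamily, matrix: NormalizedMatrix | None = None) -> SimilarityProfile:
    """Apply :func:`column_similarity` to every column of a family."""
    if family.n_seqs < 2:
        raise ValidationError("similarity profile requires at least 2 sequences")
    matrix = matrix or _default_matrix()
    cols = np.arange(1, family.n_cols + 1)
    scores = np.empty(family.n_cols)
    n_pairs = np.zeros(family.n_cols, dtype=int)
    for i, c in enumerate(cols):
        col = family.column(int(c))
        usable = sum(1 for r in col if r not in (GAP, "X"))
        n_pairs[i] = usable * (usable - 1) // 2
        scores[i] = column_similarity(col, matrix)
    positions = np.array([family.position_of(int(c)) or -1 for c in cols])
    return SimilarityProfile(columns=cols, positions=positions, scores=scores, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U1, U2), the conventional reported statistic
    p_value: float
    direction: str  # which class has the higher median
    method: str  # "exact" or "asymptotic"
    median_x: float
    median_y: float


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test with ties.

    Exact enumeration of all rank assignments when both samples have at
    most 8 observations (ties handled through midranks); otherwise the
    tie-corrected, continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1
    if n1 <= _EXACT_MAX_CLASS and n2 <= _EXACT_MAX_CLASS:
        p = _exact_two_sided_p(ranks, n1, u1)
        method = "exact"
    else:
        p = float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
        method = "asymptotic"
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "x" if mx > my else ("y" if my > mx else "tie")
    return MannWhitneyResult(
        u=min(u1, u2), p_value=p, direction=direction, method=method, median_x=mx, median_y=my
    )


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u1_obs: float) -> float:
    """P(|U - n1*n2/2| >= |observed|) over all C(n, n1) rank assignments."""
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2
    obs_dev = abs(u1_obs - mu)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def compare_site_classes(
    profile: SimilarityProfile, partition: SitePartition
) -> MannWhitneyResult:
    """Compare similarity of interacting vs non-interacting sites.

    Returns the Mann–Whitney result with ``direction`` reporting
    "interacting" or "non_interacting" (whichever class has the higher
    median similarity), after dropping missing columns.
    """
    xs = profile.scores_at(sorted(partition.interacting))
    ys = profile.scores_at(sorted(partition.non_interacting))
    if xs.size == 0 or ys.size == 0:
        raise ValidationError("both site classes must contain scored columns")
    res = mann_whitney(xs, ys)
    direction = {"x": "interacting", "y": "non_interacting"}.get(res.direction, "tie")
    return MannWhitneyResult(
        u=res.u,
        p_value=res.p_value,
        direction=direction,
        method=res.method,
        median_x=res.median_x,
        median_y=res.median_y,
    )


# ---------------------------------------------------------------------------
# frequency and hydropathy profiles
# ---------------------------------------------------------------------------

def aa_frequency(
    family: AlignedFamily,
    sites: Sequence[int] | None = None,
    collapse_threshold: float = 0.05,
    by_position: bool = True,
) -> pd.DataFrame:
    """Per-site amino-acid frequencies with rare residues pooled as "others".

    ``sites`` are protein positions when the family has a column map and
    ``by_position`` is true, else 1-based alignment columns.  Frequencies
    are over non-gap residues and sum to 1 per site; residues below
    ``collapse_threshold`` are pooled into the "others" column.  All-gap
    sites yield a row of NaN.
    """
    if sites is None:
        cols = list(range(1, family.n_cols + 1))
        index = [family.position_of(c) or c for c in cols]
    elif by_position and family.column_map is not None:
        cols = [family.column_for_position(p) for p in sites]
        index = list(sites)
    else:
        cols = list(sites)
        for c in cols:
            if not 1 <= c <= family.n_cols:
                raise ValidationError(f"site {c} outside alignment span")
        index = cols
    rows = []
    for c in cols:
        col = family.column(c)
        residues = [r for r in col if r != GAP]
        if not residues:
            rows.append({})
            continue
        n = len(residues)
        freqs = {a: residues.count(a) / n for a in sorted(set(residues))}
        kept = {a: f for a, f in freqs.items() if f >= collapse_threshold}
        others = sum(f for a, f in freqs.items() if f < collapse_threshold)
        if others > 0:
            kept["others"] = others
        rows.append(kept)
    letters = sorted({a for row in rows for a in row if a != "others"})
    if any("others" in row for row in rows):
        letters.append("others")
    table = pd.DataFrame(
        [[row.get(a, 0.0) if row else float("nan") for a in letters] for row in rows],
        index=pd.Index(index, name="site"),
        columns=letters,
    )
    return table


#: named hydropathy scales (taken from the standard protein-parameter tables)
def _load_scales() -> dict[str, dict[str, float]]:
    from Bio.SeqUtils import ProtParamData

    return {
        "kyte-doolittle": dict(ProtParamData.kd),
        "hopp-woods": dict(ProtParamData.hw),
    }


HYDROPATHY_SCALES = _load_scales()


def hydropathy_profile(family: AlignedFamily, scale: str = "kyte-doolittle") -> pd.DataFrame:
    """Mean hydropathy per column over non-gap residues (NaN for all-gap)."""
    if scale not in HYDROPATHY_SCALES:
        raise ValidationError(
            f"unknown hydropathy scale {scale!r}; available: {sorted(HYDROPATHY_SCALES)}"
        )
    table = HYDROPATHY_SCALES[scale]
    means = []
    for c in range(1, family.n_cols + 1):
        residues = [r for r in family.column(c) if r != GAP]
        vals = [table[r] for r in residues if r in table]
        means.append(sum(vals) / len(vals) if vals else float("nan"))
    positions = [family.position_of(c) or -1 for c in range(1, family.n_cols + 1)]
    return pd.DataFrame(
        {
            "column": range(1, family.n_cols + 1),
            "position": positions,
            "hydropathy": means,
        }
    )
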