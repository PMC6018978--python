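"""Equilibrium models of cooperative dimer binding to two-site DNA probes.

MIKC-type MADS-domain transcription factors such as SEP3 bind CArG-box
elements as dimers.  On a probe carrying two CArG boxes, an EMSA resolves
three bands: free probe, probe bound by one dimer, and probe bound by two
dimers (a DNA-bound tetramer, the "floral quartet" configuration).  With
``p2`` the applied dimer concentration (in practice an uncalibrated proxy,
e.g. microlitres of translation mix), the three band fractions follow a
two-site partition function

    Z  = 1 + 2*p2/kd1 + p2**2/(kd1*kd2)
    y0 = 1/Z,   y2 = (2*p2/kd1)/Z,   y4 = (p2**2/(kd1*kd2))/Z

where ``kd1`` is the dissociation constant of the first dimer on an empty
probe and ``kd2`` that of the second dimer on a half-occupied probe.  The
cooperativity constant ``kcoop = kd1/kd2`` is 1 for independent binding and
grows with tetramerization strength; unlike kd1/kd2 it is invariant under
rescaling of the (unknown) protein units and is therefore the quantity
reported per construct.

A single-site saturation model ``bound = pt*d/(kd + d)`` covers titrations
of a one-CArG-box probe against a fixed amount of protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ValidationError

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "CooperativeFit",
    "SaturationPoint",
    "SaturationSeries",
    "SaturationFit",
    "FitConfig",
    "predict_fractions",
    "cooperativity",
    "fit_cooperative",
    "predict_saturation",
    "fit_saturation",
    "bound_from_total_probe",
]

#: default detection threshold for the intermediate (one-dimer) band
DEFAULT_DELTA = 0.02
#: default upper determinability limit for kcoop
DEFAULT_CEILING = 200.0
#: lane-level tolerance on sum(fractions) for measured data
INGEST_TOLERANCE = 0.05


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationPoint:
    """One EMSA lane: applied protein and the three band fractions."""

    applied_protein: float
    frac_free: float
    frac_one_dimer: float
    frac_two_dimers: float

    def fractions(self) -> tuple[float, float, float]:
        return (self.frac_free, self.frac_one_dimer, self.frac_two_dimers)


@dataclass
class TitrationSeries:
    """An ordered EMSA titration over increasing applied protein."""

    points: list[TitrationPoint]
    label: str = ""
    probe_id: str = ""

    @classmethod
    def from_arrays(
        cls,
        applied_protein: Sequence[float],
        fractions: np.ndarray,
        label: str = "",
        probe_id: str = "",
        renormalize: bool = True,
        tolerance: float = INGEST_TOLERANCE,
    ) -> "TitrationSeries":
        """Build a series from arrays, renormalizing measured fractions.

        Lanes whose fractions do not sum to 1 within ``tolerance`` are
        rejected; lanes within tolerance are renormalized to sum exactly
        to 1 (densitometry never sums perfectly).
        """
        p = np.asarray(applied_protein, dtype=float)
        y = np.asarray(fractions, dtype=float)
        if y.shape != (p.size, 3):
            raise ValidationError(
                f"fractions must have shape ({p.size}, 3), got {y.shape}"
            )
        if np.any(p < 0):
            raise ValidationError("applied_protein must be non-negative")
        if np.any(y < -1e-12) or np.any(y > 1 + 1e-12):
            raise ValidationError("band fractions must lie in [0, 1]")
        sums = y.sum(axis=1)
        if renormalize:
            bad = np.abs(sums - 1.0) > tolerance
            if np.any(bad):
                lanes = np.nonzero(bad)[0].tolist()
                raise ValidationError(
                    f"lanes {lanes} have fraction sums outside 1±{tolerance}: "
                    f"{sums[bad].tolist()}"
                )
            with np.errstate(invalid="ignore"):
                y = y / sums[:, None]
        pts = [TitrationPoint(float(pi), *map(float, yi)) for pi, yi in zip(p, y)]
        return cls(points=pts, label=label, probe_id=probe_id)

    @property
    def applied_protein(self) -> np.ndarray:
        return np.array([pt.applied_protein for pt in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([pt.fractions() for pt in self.points])

    def validate_for_fit(self) -> None:
        p = self.applied_protein
        if np.any(p < 0):
            raise ValidationError("applied_protein must be non-negative")
        if np.count_nonzero(p == 0) > 1:
            raise ValidationError("at most one zero-protein lane is allowed")
        if np.unique(p).size < 3:
            raise ValidationError(
                "need at least 3 lanes with distinct applied_protein for fitting"
            )
        y = self.fractions
        if np.allclose(y, 0):
            raise ValidationError("all band fractions are zero; nothing to fit")

    def scaled(self, c: float) -> "TitrationSeries":
        """Return a copy with all applied-protein values multiplied by c."""
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        pts = [replace(pt, applied_protein=pt.applied_protein * c) for pt in self.points]
        return TitrationSeries(points=pts, label=self.label, probe_id=self.probe_id)


@dataclass(frozen=True)
class CooperativeFit:
    """Result of fitting the two-site cooperative binding model.

    ``kd1``/``kd2`` are in (relative) protein units; ``kcoop`` is their
    dimensionless ratio.  When ``censored`` is true the reported ``kcoop``
    equals ``ceiling`` and must be read as a lower bound: the intermediate
    band never rose above the detection threshold, so only "at least this
    cooperative" can be claimed.
    """

    kd1: float
    kd2: float
    kcoop: float
    censored: bool
    ceiling: float
    rss: float
    converged: bool
    n_lanes: int = 0
    max_intermediate: float = float("nan")

    def __post_init__(self) -> None:
        if not self.censored:
            ratio = self.kd1 / self.kd2
            if not math.isclose(self.kcoop, ratio, rel_tol=1e-9):
                raise ValidationError("kcoop must equal kd1/kd2 when not censored")


@dataclass(frozen=True)
class SaturationPoint:
    """One lane of a saturation binding assay (free probe [D], bound [PD])."""

    free_probe: float
    bound: float

    def __post_init__(self) -> None:
        if self.free_probe < 0 or self.bound < 0:
            raise ValidationError("free_probe and bound must be non-negative")


@dataclass
class SaturationSeries:
    points: list[SaturationPoint]
    label: str = ""

    @classmethod
    def from_arrays(
        cls, free_probe: Sequence[float], bound: Sequence[float], label: str = ""
    ) -> "SaturationSeries":
        d = np.asarray(free_probe, dtype=float)
        b = np.asarray(bound, dtype=float)
        if d.shape != b.shape:
            raise ValidationError("free_probe and bound must have equal length")
        return cls([SaturationPoint(float(x), float(y)) for x, y in zip(d, b)], label)

    @property
    def free_probe(self) -> np.ndarray:
        return np.array([pt.free_probe for pt in self.points])

    @property
    def bound(self) -> np.ndarray:
        return np.array([pt.bound for pt in self.points])


@dataclass(frozen=True)
class SaturationFit:
    kd: float
    pt: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class FitConfig:
    """Options for :func:`fit_cooperative`.

    delta
        Detection threshold for the intermediate band; if the fitted
        one-dimer fraction never exceeds it over the observed lanes the
        kcoop estimate is censored at ``ceiling``.
    ceiling
        Upper determinability limit for kcoop (≈200 for the EMSA setup
        this model describes).
    n_starts
        Grid side for the multi-start over (kd1, kd2) initial values.
    """

    delta: float = DEFAULT_DELTA
    ceiling: float = DEFAULT_CEILING
    n_starts: int = 3

    def __post_init__(self) -> None:
        if self.delta < 0 or self.ceiling <= 0 or self.n_starts < 1:
            raise ValidationError("invalid FitConfig")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def predict_fractions(p2, kd1: float, kd2: float):
    """Band fractions (y0, y2, y4) of a two-site probe at dimer amount p2.

    Accepts a scalar or array ``p2``; kd1, kd2 must be positive.
    """
    if kd1 <= 0 or kd2 <= 0:
        raise ValidationError("kd1 and kd2 must be positive")
    p = np.asarray(p2, dtype=float)
    if np.any(p < 0):
        raise ValidationError("p2 must be non-negative")
    z = 1.0 + 2.0 * p / kd1 + p * p / (kd1 * kd2)
    y0 = 1.0 / z
    y2 = (2.0 * p / kd1) / z
    y4 = (p * p / (kd1 * kd2)) / z
    if p.ndim == 0:
        return float(y0), float(y2), float(y4)
    return y0, y2, y4


def fraction_matrix(p2: Sequence[float], kd1: float, kd2: float) -> np.ndarray:
    """(n, 3) matrix of predicted fractions over a protein ladder."""
    y0, y2, y4 = predict_fractions(np.asarray(p2, dtype=float), kd1, kd2)
    return np.column_stack([y0, y2, y4])


def cooperativity(kd1: float, kd2: float) -> float:
    """kcoop = kd1/kd2 (1 = independent binding; >1 = cooperative)."""
    if kd1 <= 0 or kd2 <= 0:
        raise ValidationError("kd1 and kd2 must be positive")
    return kd1 / kd2


def predict_saturation(d_free, pt: float, kd: float):
    """Bound complex [PD] = pt*d/(kd + d) for free probe concentration d."""
    if pt <= 0 or kd <= 0:
        raise ValidationError("pt and kd must be positive")
    d = np.asarray(d_free, dtype=float)
    if np.any(d < 0):
        raise ValidationError("d_free must be non-negative")
    out = pt * d / (kd + d)
    return float(out) if d.ndim == 0 else out


def bound_from_total_probe(d_total, pt: float, kd: float):
    """Bound complex as a function of *total* probe, for convenience.

    Solves [PD] from the quadratic mass balance d_total = [D] + [PD] with
    [PD] = pt*[D]/(kd+[D]); useful when only applied (total) probe is
    known.  The physically meaningful root is returned.
    """
    if pt <= 0 or kd <= 0:
        raise ValidationError("pt and kd must be positive")
    dt = np.asarray(d_total, dtype=float)
    if np.any(dt < 0):
        raise ValidationError("d_total must be non-negative")
    # [PD]^2 - (dt + pt + kd)[PD] + dt*pt = 0, take the smaller root
    b = dt + pt + kd
    pd = (b - np.sqrt(b * b - 4.0 * dt * pt)) / 2.0
    return float(pd) if dt.ndim == 0 else pd


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _multistart_values(p: np.ndarray, n: int) -> np.ndarray:
    """Candidate kd starting values spanning the observed protein range."""
    pos = p[p > 0]
    lo, hi = pos.min(), pos.max()
    if n == 1 or lo == hi:
        return np.array([math.sqrt(lo * hi)])
    return np.geomspace(lo, hi, n)


def fit_cooperative(series: TitrationSeries, config: FitConfig | None = None) -> CooperativeFit:
    """Jointly fit kd1, kd2 to the three band-fraction curves of a titration.

    Unweighted least squares over all three fractions at every lane;
    kd1 and kd2 are optimized on a log10 scale (positivity for free) with
    a small multi-start grid spanning the observed protein range to guard
    against local minima.  Censoring: if the *fitted* intermediate-band
    fraction never exceeds ``config.delta`` over the observed lanes, or the
    fitted kcoop exceeds ``config.ceiling``, the result is reported
    censored with kcoop pinned at the ceiling (a lower bound).
    """
    config = config or FitConfig()
    series.validate_for_fit()
    p = series.applied_protein
    y_obs = series.fractions

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd1, kd2 = 10.0 ** theta
        return (fraction_matrix(p, kd1, kd2) - y_obs).ravel()

    starts = np.log10(_multistart_values(p, config.n_starts))
    best = None
    for s1 in starts:
        for s2 in starts:
            sol = least_squares(residuals, x0=np.array([s1, s2]), method="lm")
            if best is None or sol.cost < best.cost:
                best = sol
    kd1, kd2 = (float(v) for v in 10.0 ** best.x)
    rss = float(2.0 * best.cost)
    kcoop = kd1 / kd2
    max_y2 = float(fraction_matrix(p, kd1, kd2)[:, 1].max())
    censored = (max_y2 < config.delta) or (kcoop > config.ceiling)
    return CooperativeFit(
        kd1=kd1,
        kd2=kd2,
        kcoop=config.ceiling if censored else kcoop,
        censored=censored,
        ceiling=config.ceiling,
        rss=rss,
        converged=bool(best.success),
        n_lanes=len(series.points),
        max_intermediate=max_y2,
    )


def fit_saturation(series: SaturationSeries) -> SaturationFit:
    """Least-squares fit of (pt, kd) to a single-site saturation series.

    A flat series (bound already at plateau for every probe amount) drives
    kd to the zero boundary; such fits are returned with converged=False
    rather than raising, since the plateau pt is still informative.
    """
    d = series.free_probe
    b = series.bound
    if d.size < 3:
        raise ValidationError("need at least 3 saturation points")
    if np.allclose(b, 0):
        raise ValidationError("all bound values are zero; nothing to fit")
    pos = d[d > 0]
    if pos.size == 0:
        raise ValidationError("need at least one positive free_probe value")
    half = b.max() / 2.0
    if not (b.min() < half < b.max()):
        warnings.warn(
            "saturation series does not span the half-saturation region; "
            "kd may be poorly determined",
            stacklevel=2,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        pt, kd = 10.0 ** theta
        return predict_saturation(d, pt, kd) - b

    pt0 = max(b.max(), 1e-12) * 1.2
    best = None
    for kd0 in _multistart_values(d, 3):
        sol = least_squares(residuals, x0=np.log10([pt0, kd0]), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    pt, kd = (float(v) for v in 10.0 ** best.x)
    rss = float(2.0 * best.cost)
    # kd collapsing far below the sampled probe range = boundary solution
    at_boundary = kd < 1e-6 * pos.min()
    return SaturationFit(
        kd=kd, pt=pt, rss=rss, converged=bool(best.success) and not at_boundary
    )
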