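"""Isotopologue bookkeeping for stable-isotope tracing and quantification.

Three groups of operations:

* Natural-abundance correction.  Measured mass-isotopologue intensities are
  the true tracer-labeled distribution convolved with the binomial spread
  of the naturally occurring heavy isotope over the unlabeled positions.
  The correction inverts that convolution with a non-negativity constraint
  (single tracer element, tracer purity 1, resolution-independent).

* Salvage-fraction estimators for nucleotide pools labeled to steady state
  from the glutamine amide nitrogen.  De novo GTP carries three
  glutamine-amide nitrogens (m+3) while salvaged GTP carries none (m+0),
  so the guanine salvage fraction is m0/(m0+m3).  De novo ATP carries two
  (ring N3 and N9), giving m0/(m0+m2); adenine's direct contribution is
  read from the aspartate-donated m+1 of ATP relative to aspartate itself
  under alpha-15N glutamine.

* Isotope-dilution quantification.  Peak areas are divided by a co-run
  labeled internal standard to form response ratios, mapped through a
  calibration curve fitted to a dilution series (linear, power, or
  quadratic — selected by small-sample-corrected AIC with a monotonicity
  gate), and scaled to intracellular concentration by the reconstitution
  and total cell volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, nnls
from scipy.stats import binom

__all__ = [
    "NATURAL_ABUNDANCE_13C",
    "NATURAL_ABUNDANCE_15N",
    "TRACERS",
    "IsotopologueDistribution",
    "CalibrationCurve",
    "QuantResult",
    "natural_abundance_matrix",
    "convolve_natural_abundance",
    "correct_natural_abundance",
    "guanine_salvage_fraction",
    "purine_salvage_fraction_atp",
    "denovo_fraction_via_aspartate",
    "fit_calibration",
    "quantify",
    "fold_change",
]

NATURAL_ABUNDANCE_13C = 0.0107
NATURAL_ABUNDANCE_15N = 0.00364

TRACERS = ("amide-15N-Gln", "alpha-15N-Gln", "U-13C-Gln", "U-13C-Asn")

_MAX_ATOMS = 60  # beyond this the convolution matrix is numerically useless


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Mass-isotopologue fraction vector m+0..m+n for one compound."""

    compound: str
    tracer: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; allowed: {TRACERS}")
        frac = np.asarray(self.fractions, dtype=float)
        if np.any(frac < 0):
            raise ValueError("fractions must be non-negative")
        total = frac.sum()
        if total <= 0:
            raise ValueError("fractions must not all be zero")
        object.__setattr__(self, "fractions", frac / total)

    def m(self, k: int) -> float:
        """Fraction of the m+k isotopologue (0 beyond the vector)."""
        return float(self.fractions[k]) if k < len(self.fractions) else 0.0


def natural_abundance_matrix(n_atoms: int, abundance: float) -> np.ndarray:
    """Forward convolution matrix C with measured = C @ true.

    Column j spreads a species with j tracer atoms binomially over the
    remaining n_atoms - j positions at the natural heavy-isotope abundance.
    """
    if n_atoms < 0:
        raise ValueError("n_atoms must be non-negative")
    if n_atoms > _MAX_ATOMS:
        raise ValueError(f"n_atoms > {_MAX_ATOMS}: correction matrix is ill-conditioned")
    if not (0 <= abundance < 1):
        raise ValueError("abundance must lie in [0, 1)")
    size = n_atoms + 1
    mat = np.zeros((size, size))
    for j in range(size):
        k = np.arange(0, n_atoms - j + 1)
        mat[j + k, j] = binom.pmf(k, n_atoms - j, abundance)
    return mat


def convolve_natural_abundance(
    true_fractions, n_atoms: int, abundance: float = NATURAL_ABUNDANCE_13C
) -> np.ndarray:
    """Forward model: what the spectrometer sees for a true distribution."""
    true_fractions = np.asarray(true_fractions, dtype=float)
    if len(true_fractions) != n_atoms + 1:
        raise ValueError("true distribution must have n_atoms + 1 entries")
    return natural_abundance_matrix(n_atoms, abundance) @ true_fractions


def correct_natural_abundance(
    raw,
    n_atoms: int,
    abundance: float = NATURAL_ABUNDANCE_13C,
    compound: str = "",
    tracer: str = "U-13C-Gln",
) -> IsotopologueDistribution:
    """Invert the natural-abundance convolution.

    Solves measured = C @ true by non-negative least squares and
    renormalizes; small negative components that an unconstrained inverse
    would produce are thereby truncated at zero.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != n_atoms + 1:
        raise ValueError("raw vector must have n_atoms + 1 entries")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    if raw.sum() <= 0:
        raise ValueError("all-zero intensity vector cannot be corrected")
    mat = natural_abundance_matrix(n_atoms, abundance)
    solution, _ = nnls(mat, raw / raw.sum())
    return IsotopologueDistribution(compound=compound, tracer=tracer, fractions=solution)


# ---------------------------------------------------------------------------
# Salvage fractions


def guanine_salvage_fraction(gtp: IsotopologueDistribution) -> float:
    """Fraction of the GTP pool from guanine salvage: m0/(m0+m3) under
    amide-15N glutamine (de novo GTP carries 3 amide nitrogens)."""
    if gtp.tracer != "amide-15N-Gln":
        raise ValueError("guanine salvage requires the amide-15N-Gln tracer")
    m0, m3 = gtp.m(0), gtp.m(3)
    if m0 + m3 == 0:
        raise ValueError("m+0 and m+3 are both zero: no informative signal")
    return m0 / (m0 + m3)


def purine_salvage_fraction_atp(atp: IsotopologueDistribution, strict_m0: bool = False) -> float:
    """Fraction of the ATP pool from purine salvage under amide-15N
    glutamine.  De novo ATP carries 2 amide nitrogens (N3, N9), so the
    default is m0/(m0+m2); ``strict_m0`` returns m+0 alone, which treats
    intermediate isotopologues as de novo."""
    if atp.tracer != "amide-15N-Gln":
        raise ValueError("purine salvage requires the amide-15N-Gln tracer")
    m0, m2 = atp.m(0), atp.m(2)
    if strict_m0:
        return m0
    if m0 + m2 == 0:
        raise ValueError("m+0 and m+2 are both zero: no informative signal")
    return m0 / (m0 + m2)


def denovo_fraction_via_aspartate(product_m1: float, precursor_m1: float) -> float:
    """De novo fraction of a product pool via the aspartate nitrogen
    donation: product m+1 over aspartate m+1 under alpha-15N glutamine,
    clipped to [0, 1].  The direct salvage contribution is 1 - result."""
    if precursor_m1 <= 0:
        raise ValueError("precursor m+1 fraction must be positive")
    ratio = product_m1 / precursor_m1
    if ratio > 1:
        warnings.warn(
            f"product m+1 ({product_m1:g}) exceeds precursor m+1 ({precursor_m1:g}); "
            "clipping de novo fraction to 1",
            stacklevel=2,
        )
    return float(np.clip(ratio, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Isotope-dilution quantification

_MODEL_ORDER = ("linear", "power", "quadratic")  # tie-break preference


@dataclass(frozen=True)
class CalibrationCurve:
    """Response-ratio calibration over a dilution series.

    model: 'linear' (y = a x + b), 'power' (y = a x^b), or 'quadratic'
    (y = a x^2 + b x + c); strictly monotonic over ``valid_range`` so it
    can be inverted.
    """

    model: str
    params: tuple
    valid_range: tuple  # (min, max) concentration, uM
    fit_diagnostics: dict = field(default_factory=dict, compare=False)

    def predict(self, conc):
        x = np.asarray(conc, dtype=float)
        if self.model == "linear":
            a, b = self.params
            return a * x + b
        if self.model == "power":
            a, b = self.params
            return a * np.power(x, b)
        a, b, c = self.params
        return a * x**2 + b * x + c

    def response_range(self) -> tuple:
        lo, hi = (float(self.predict(c)) for c in self.valid_range)
        return (min(lo, hi), max(lo, hi))

    def invert(self, response: float) -> float:
        """Concentration at a given response ratio (within valid_range)."""
        lo, hi = self.valid_range
        f = lambda x: float(self.predict(x)) - response
        flo, fhi = f(lo), f(hi)
        if flo == 0:
            return float(lo)
        if fhi == 0:
            return float(hi)
        if flo * fhi > 0:
            raise ValueError("response outside the calibrated range")
        return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of one compound in one sample."""

    vial_concentration_uM: float
    intracellular_mM: float
    in_range: bool  # False => the value is to be discarded


def _aicc(rss: float, n: int, k: int, scale: float) -> float:
    if n - k - 1 <= 0:
        return math.inf
    if rss <= n * (1e-10 * max(scale, 1e-300)) ** 2:
        return -math.inf  # perfect fit to numerical precision
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _is_monotonic(
    model: str, params: tuple, lo: float, hi: float, response_scale: float
) -> bool:
    """Strictly monotonic over [lo, hi] with a non-degenerate response span
    (a flat curve cannot be inverted)."""
    if model == "power":
        a, b = params
        monotone = a != 0 and b != 0
    elif model == "linear":
        monotone = params[0] != 0
    else:
        a, b, _ = params
        monotone = (b != 0) if a == 0 else not (lo < -b / (2 * a) < hi)
    if not monotone:
        return False
    curve = CalibrationCurve(model=model, params=params, valid_range=(lo, hi))
    span = abs(float(curve.predict(hi)) - float(curve.predict(lo)))
    return span > 1e-9 * max(response_scale, 1e-300)


def fit_calibration(concentrations, response_ratios) -> CalibrationCurve:
    """Fit and select a calibration curve for one compound.

    LC-MS response noise is multiplicative, so linear and quadratic models
    are fitted by relative-error (1/y-weighted) least squares and the power
    model by least squares on log response vs log concentration; selection
    compares small-sample-corrected AIC on the relative residuals of all
    three, after discarding candidates that are not strictly monotonic over
    the dilution range.  Ties — e.g. a noiseless proportional series, which
    linear and power both fit exactly — resolve in the order linear, power,
    quadratic.  If any response is non-positive, fitting and selection fall
    back to unweighted residuals and the power family is excluded.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(response_ratios, dtype=float)
    if len(x) != len(y):
        raise ValueError("concentrations and responses must align")
    if len(np.unique(x)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")
    if np.any(x <= 0):
        raise ValueError("calibration concentrations must be positive")
    lo, hi = float(x.min()), float(x.max())
    n = len(x)
    positive = bool(np.all(y > 0))
    y_scale = float(np.max(np.abs(y)))

    def _wlstsq(design: np.ndarray) -> np.ndarray:
        weights = 1.0 / y if positive else np.ones(n)
        sol, *_ = np.linalg.lstsq(design * weights[:, None], y * weights, rcond=None)
        return sol

    def _selection_rss(pred: np.ndarray) -> float:
        if positive:
            if np.any(pred <= 0):
                return math.inf
            return float(np.sum(((pred - y) / y) ** 2))
        return float(np.sum((pred - y) ** 2))

    rss_scale = 1.0 if positive else y_scale
    candidates: dict[str, tuple[tuple, float]] = {}

    a1, b1 = _wlstsq(np.column_stack([x, np.ones(n)]))
    candidates["linear"] = (
        (float(a1), float(b1)),
        _aicc(_selection_rss(a1 * x + b1), n, 2, rss_scale),
    )

    if positive:
        bp, log_a = np.polyfit(np.log(x), np.log(y), 1)
        ap = float(np.exp(log_a))
        candidates["power"] = (
            (ap, float(bp)),
            _aicc(_selection_rss(ap * np.power(x, bp)), n, 2, rss_scale),
        )

    a2, b2, c2 = _wlstsq(np.column_stack([x**2, x, np.ones(n)]))
    candidates["quadratic"] = (
        (float(a2), float(b2), float(c2)),
        _aicc(_selection_rss(a2 * x**2 + b2 * x + c2), n, 3, rss_scale),
    )

    best = None
    for model in _MODEL_ORDER:
        if model not in candidates:
            continue
        params, aicc = candidates[model]
        if not _is_monotonic(model, params, lo, hi, y_scale):
            continue
        if best is None or aicc < best[2] - 1e-9:
            best = (model, params, aicc)
    if best is None:
        raise ValueError("no strictly monotonic calibration model fits the series")
    model, params, aicc = best
    diagnostics = {m: {"params": p, "aicc": a} for m, (p, a) in candidates.items()}
    return CalibrationCurve(
        model=model, params=params, valid_range=(lo, hi), fit_diagnostics=diagnostics
    )


def quantify(
    area: float,
    is_area: float,
    curve: CalibrationCurve,
    reconstitution_volume_uL: float,
    total_cell_volume_uL: float,
) -> QuantResult:
    """Absolute intracellular concentration by isotope dilution.

    The response ratio area / internal-standard area is inverted through
    the calibration curve to a vial concentration (uM); the intracellular
    concentration is vial_uM * reconstitution_volume / total_cell_volume
    / 1000 (mM).  Ratios outside the calibrated response range are flagged
    (``in_range=False``) rather than raised — such measurements are to be
    discarded.
    """
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if reconstitution_volume_uL <= 0 or total_cell_volume_uL <= 0:
        raise ValueError("volumes must be positive")
    ratio = area / is_area
    r_lo, r_hi = curve.response_range()
    if not (r_lo <= ratio <= r_hi):
        return QuantResult(vial_concentration_uM=math.nan, intracellular_mM=math.nan, in_range=False)
    vial = curve.invert(ratio)
    intracellular = vial * reconstitution_volume_uL / total_cell_volume_uL / 1000.0
    return QuantResult(vial_concentration_uM=vial, intracellular_mM=intracellular, in_range=True)


def fold_change(conc_treated: float, conc_control: float) -> float:
    """Treated-over-control concentration ratio."""
    if conc_control <= 0:
        raise ValueError("control concentration must be positive")
    return float(conc_treated / conc_control)
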