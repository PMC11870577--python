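"""Seeded synthetic-data generators.

Each generator emulates the statistical structure of one instrument export
so every estimator in the package can be exercised against a recoverable
ground truth without any external data.  Noise models follow the
measurement physics at the level the analyses are sensitive to: lognormal
(multiplicative) noise for fluorescence intensities and concentrations,
multinomial ion-counting noise for isotopologue fractions, and Poisson
noise plus rounding for nuclei counts.  Identical generator specs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budget import CompositionTable
from .exchange import GrowthFit, MediaSeries
from .isotopes import CalibrationCurve, IsotopologueDistribution
from .model import Trajectory
from .timecourse import BiosensorTrace

__all__ = [
    "GeneratorSpec",
    "SENSOR_KD_MM",
    "gen_biosensor",
    "gen_media_series",
    "gen_isotopologues",
    "gen_calibration",
    "gen_composition",
]

#: Apparent dissociation constant of the sensor transfer function (mM).
#: Only monotonicity matters downstream; sensor calibration is out of scope.
SENSOR_KD_MM = 0.9

_RFP_SCALE = 1000.0  # a.u. per relative cell volume
_GFP_GAIN = 2.0  # peak GFP/RFP at sensor saturation
_NUCLEI_SCALE = 1000.0  # counts per relative cell volume


@dataclass(frozen=True)
class GeneratorSpec:
    """Seeded generator settings; identical specs give identical outputs."""

    seed: int = 0
    noise_cv: float = 0.03  # coefficient of variation of multiplicative noise
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _sensor(asp_mM: np.ndarray) -> np.ndarray:
    """Saturating (Hill coefficient 1) sensor transfer function."""
    return asp_mM / (asp_mM + SENSOR_KD_MM)


def gen_biosensor(traj: Trajectory, spec: GeneratorSpec, condition: str = "sim") -> list[BiosensorTrace]:
    """Plate-style biosensor traces driven by a model trajectory.

    RFP tracks simulated cell volume, GFP is RFP times the sensor response
    to the aspartate trace, nuclei are Poisson counts around the volume
    curve, and a pre-treatment scan (the trajectory's initial state) is
    prepended one reporting interval before t = 0.
    """
    rng = spec.rng()
    dt = float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 1.0
    times = np.concatenate([[traj.times[0] - dt], traj.times])
    asp = np.concatenate([[traj.asp[0]], traj.asp])
    vol = np.concatenate([[traj.cell_volume[0]], traj.cell_volume])
    traces = []
    for r in range(spec.n_replicates):
        rfp = _RFP_SCALE * vol * _lognormal(rng, spec.noise_cv, len(times))
        gfp = rfp * _GFP_GAIN * _sensor(asp) * _lognormal(rng, spec.noise_cv, len(times))
        expected = _NUCLEI_SCALE * vol
        nuclei = rng.poisson(expected).astype(float) if spec.noise_cv > 0 else np.round(expected)
        traces.append(
            BiosensorTrace(
                well_id=f"W{r + 1:02d}",
                condition=condition,
                times=times,
                gfp=gfp,
                rfp=rfp,
                nuclei=nuclei,
                pretreatment_index=0,
            )
        )
    return traces


def gen_media_series(
    true_flux: float,
    mu: float,
    evaporation_rate: float,
    times,
    spec: GeneratorSpec,
    conc0_uM: float = 100.0,
    volume0_ml: float = 2.0,
    V0_uL: float = 1.0,
) -> tuple[list[MediaSeries], GrowthFit]:
    """Media sampling series with known exchange flux and evaporation.

    Amounts integrate the exponential cell-volume curve exactly:
    A(t) = A0 - F * V0 (e^{mu t} - 1)/mu (nmol); media volume decays
    exponentially at the evaporation rate; measured concentrations are
    amount/volume with multiplicative noise.  Returns the replicate series
    and the true growth fit.
    """
    times = np.asarray(times, dtype=float)
    growth = GrowthFit(V0=V0_uL, mu=mu)
    integral = np.array([growth.integrated_volume(times[0], t) for t in times])
    amounts = conc0_uM * volume0_ml - true_flux * integral
    if np.any(amounts < 0):
        raise ValueError("flux depletes the media amount below zero over the sampling span")
    volumes = volume0_ml * np.exp(-evaporation_rate * (times - times[0]))
    rng = spec.rng()
    series = []
    for _ in range(spec.n_replicates):
        conc = amounts / volumes * _lognormal(rng, spec.noise_cv, len(times))
        series.append(MediaSeries(times=times, concentration=conc, media_volume=volumes))
    return series, growth


_PURE_PROFILES = {
    # (tracer, compound) -> (salvage profile, de novo profile)
    ("amide-15N-Gln", "GTP"): ([1, 0, 0, 0], [0, 0, 0, 1]),  # de novo carries 3 amide N
    ("amide-15N-Gln", "ATP"): ([1, 0, 0], [0, 0, 1]),  # de novo carries N3 + N9
    ("alpha-15N-Gln", "ATP"): ([1, 0], [0, 1]),  # de novo carries the Asp-donated N
    ("alpha-15N-Gln", "aspartate"): ([1, 0], [0, 1]),
}


def gen_isotopologues(
    true_salvage: float,
    tracer: str,
    compound: str,
    n_ions: int | None,
    spec: GeneratorSpec,
) -> IsotopologueDistribution:
    """Two-source isotopologue mixture with multinomial counting noise.

    The pool is a mixture of a pure salvage profile (weight
    ``true_salvage``) and a pure de novo profile; ``n_ions`` ions are drawn
    multinomially (None for the infinite-ion limit).
    """
    if not (0 <= true_salvage <= 1):
        raise ValueError("true_salvage must lie in [0, 1]")
    try:
        salvage, denovo = _PURE_PROFILES[(tracer, compound)]
    except KeyError:
        raise ValueError(f"no labeling profile for {compound!r} under {tracer!r}") from None
    probs = true_salvage * np.asarray(salvage, dtype=float) + (1 - true_salvage) * np.asarray(
        denovo, dtype=float
    )
    if n_ions is None:
        fractions = probs
    else:
        fractions = spec.rng().multinomial(n_ions, probs) / n_ions
    return IsotopologueDistribution(compound=compound, tracer=tracer, fractions=fractions)


def gen_calibration(
    curve_truth: CalibrationCurve,
    spec: GeneratorSpec,
    n_points: int = 12,
    max_conc_uM: float = 500.0,
) -> pd.DataFrame:
    """Dilution-series calibration table from a true response curve.

    Defaults mirror the standard design: a 12-point 2-fold dilution from
    500 uM, run in replicates, with multiplicative response noise.
    Columns: concentration_uM, response_ratio.
    """
    conc = max_conc_uM / 2.0 ** np.arange(n_points)
    rng = spec.rng()
    rows = []
    for _ in range(spec.n_replicates):
        response = np.asarray(curve_truth.predict(conc), dtype=float)
        response = response * _lognormal(rng, spec.noise_cv, len(conc))
        rows.append(pd.DataFrame({"concentration_uM": conc, "response_ratio": response}))
    return pd.concat(rows, ignore_index=True)


def gen_composition(
    target_total_demand: float,
    K_per_h: float,
    spec: GeneratorSpec,  # noqa: ARG001 - deterministic; kept for interface symmetry
) -> tuple[CompositionTable, dict]:
    """Cellular composition whose fate budget totals a chosen demand.

    Flux shares (of the target total): combined Asp+Asn pool 0.65, Asn
    efflux 0.10, pyrimidines 0.10 (purine rule adds 0.15), with 0.20
    routed to asparagine-in-protein inside the combined pool.
    Concentrations are the shares divided by K ln 2, so build_budget on the
    output reproduces the target exactly.  Returns the table and the truth
    dict (asn fluxes and total).
    """
    if K_per_h <= 0:
        raise ValueError("K must be positive: fluxes are undefined without growth")
    if target_total_demand <= 0:
        raise ValueError("target total demand must be positive")
    k_ln2 = K_per_h * np.log(2.0)
    pool_flux = 0.65 * target_total_demand
    asn_efflux = 0.10 * target_total_demand
    pyr_flux = 0.10 * target_total_demand
    asn_prot = 0.20 * target_total_demand
    pyr_species = ("uracil", "cytosine", "thymine")
    rows = [("Asp+Asn", pool_flux / k_ln2, "asp_asn_combined"),
            ("Glu+Gln", 1.2 * pool_flux / k_ln2, "glu_gln_combined")]
    rows += [(name, pyr_flux / len(pyr_species) / k_ln2, "pyrimidine") for name in pyr_species]
    table = CompositionTable(
        pd.DataFrame(rows, columns=["compound", "concentration_mM", "pool_type"])
    )
    truth = {
        "asn_prot_flux": asn_prot,
        "asn_efflux": asn_efflux,
        "total_demand": target_total_demand,
    }
    return table, truth
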