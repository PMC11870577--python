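"""Media exchange-flux estimation and asparagine flux partitioning.

Nutrient uptake/efflux is inferred from timed media samples taken over a
culture of exponentially growing cells.  Because the incubator evaporates
medium, concentrations drift even without exchange; the conserved quantity
is the molar *amount* (concentration x media volume), so all bookkeeping is
done on amounts and the estimate is invariant to evaporation.

Fluxes are normalized to total cell volume: with amount in nmol, cell
volume in uL and time in hours, nmol / (h * uL) == mM/h.  Sign convention:
uptake positive, efflux negative.

The asparagine partition resolves protein-synthesis and synthesis fluxes
from the net influx of labeled (media-derived) asparagine, the net efflux
of unlabeled asparagine, and the intracellular unlabeled-to-labeled ratio,
under a stationary intracellular pool.  The steady-state balance is
J_in + J_syn = J_prot + J_out with intracellular labeled/unlabeled ratio
J_in / (J_syn - J_out), giving J_prot = J_in * (1 + unlabeled/labeled).
Efflux is treated as drawing on the unlabeled (synthesized) pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MediaSeries",
    "GrowthFit",
    "AsnPartition",
    "fit_growth",
    "estimate_exchange_flux",
    "partition_asn_flux",
]


@dataclass(frozen=True)
class MediaSeries:
    """Timed media concentration samples with (possibly interpolated) volumes."""

    times: np.ndarray  # hours
    concentration: np.ndarray  # uM
    media_volume: np.ndarray  # mL

    def __post_init__(self) -> None:
        for name in ("times", "concentration", "media_volume"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.concentration) == len(self.media_volume)):
            raise ValueError("times, concentration and media_volume must align")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.media_volume <= 0):
            raise ValueError("media volumes must be positive")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def amounts(self) -> np.ndarray:
        """Molar amount in the well, nmol (uM x mL)."""
        return self.concentration * self.media_volume

    @classmethod
    def from_endpoint_volumes(
        cls, times, concentration, volume_initial_ml: float, volume_residual_ml: float
    ) -> "MediaSeries":
        """Build a series when only the initial and residual (end-of-run)
        media volumes were measured, interpolating volume linearly in time —
        appropriate for steady evaporation."""
        times = np.asarray(times, dtype=float)
        volumes = np.interp(times, [times[0], times[-1]], [volume_initial_ml, volume_residual_ml])
        return cls(times, np.asarray(concentration, dtype=float), volumes)


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth parameters: V(t) = V0 * exp(mu * t)."""

    V0: float  # total cell volume at t = 0 of the fit's clock, uL
    mu: float  # specific growth rate, 1/h

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")

    def volume(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.V0 * np.exp(self.mu * np.asarray(t, dtype=float))

    def integrated_volume(self, t0: float, t1: float) -> float:
        """Closed-form integral of V over [t0, t1] (uL * h), with the
        mu -> 0 limit handled analytically."""
        dt = t1 - t0
        if abs(self.mu) < 1e-12:
            return self.V0 * dt
        return float(self.V0 * np.exp(self.mu * t0) * np.expm1(self.mu * dt) / self.mu)


@dataclass(frozen=True)
class AsnPartition:
    """Asparagine flux partition; the balance J_in + J_syn = J_prot + J_out
    holds exactly by construction."""

    J_in: float  # mM/h, net influx of labeled Asn
    J_out: float  # mM/h, net efflux of unlabeled Asn
    ratio_unlabeled_to_labeled: float  # intracellular Asn / labeled-Asn
    J_prot: float  # mM/h
    J_syn: float  # mM/h


def fit_growth(times, cell_volumes) -> GrowthFit:
    """Log-linear least-squares fit of exponential growth.

    Exact on noiseless exponentials; with >= 3 noisy points this is the
    standard OLS estimator of the specific growth rate.
    """
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(cell_volumes, dtype=float)
    if len(times) < 2:
        raise ValueError("at least two time points are required")
    if np.any(volumes <= 0):
        raise ValueError("cell volumes must be positive")
    mu, logv0 = np.polyfit(times - times[0], np.log(volumes), 1)
    return GrowthFit(V0=float(np.exp(logv0)), mu=float(mu))


def estimate_exchange_flux(
    media: MediaSeries,
    growth: GrowthFit,
    initial_rate: bool = False,
) -> float:
    """Exchange flux in mM per hour of cell volume.

    F = -[A(t1) - A(t0)] / integral_{t0}^{t1} V0 exp(mu t) dt, where A is
    the molar amount in the well.  Positive F is uptake.  ``initial_rate``
    restricts the estimate to the first sampling interval — the right choice
    for efflux of metabolites absent from fresh media, before the medium
    becomes conditioned.

    The growth fit's clock must match the media series' time axis.
    """
    if len(media.times) < 2:
        raise ValueError("at least two media samples are required")
    amounts = media.amounts
    if initial_rate:
        t0, t1 = media.times[0], media.times[1]
        d_amount = amounts[1] - amounts[0]
    else:
        t0, t1 = media.times[0], media.times[-1]
        d_amount = amounts[-1] - amounts[0]
    integral = growth.integrated_volume(t0, t1)
    if integral <= 0:
        raise ValueError("integrated cell volume over the interval is zero")
    return float(-d_amount / integral)


def partition_asn_flux(
    J_in: float, J_out: float, ratio_unlabeled_to_labeled: float
) -> AsnPartition:
    """Partition asparagine flux using the intracellular label ratio.

    J_prot = J_in * (1 + unlabeled/labeled); J_syn closes the balance.
    """
    if J_in <= 0:
        raise ValueError("J_in must be positive (the label ratio is undefined without influx)")
    if J_out < 0:
        raise ValueError("J_out must be non-negative")
    if ratio_unlabeled_to_labeled < 0:
        raise ValueError("label ratio must be non-negative")
    J_prot = J_in * (1.0 + ratio_unlabeled_to_labeled)
    J_syn = J_prot + J_out - J_in
    return AsnPartition(
        J_in=float(J_in),
        J_out=float(J_out),
        ratio_unlabeled_to_labeled=float(ratio_unlabeled_to_labeled),
        J_prot=float(J_prot),
        J_syn=float(J_syn),
    )
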