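"""Aspartate fate-flux budget.

Converts total cellular composition (free pools plus polymer-liberated
monomers, per total cell volume) and the proliferation rate into per-fate
aspartate consumption fluxes.  For a cell doubling at rate K (doublings/h)
with constant composition, maintaining a total concentration C_i of
compound i requires a synthesis flux F_i = K * ln(2) * C_i (mM/h).

Acid hydrolysis converts asparagine to aspartate (and glutamine to
glutamate), so the hydrolysate reports a combined Asp+Asn pool; the
aspartate-to-protein flux is the combined-pool flux minus the
independently measured asparagine-to-protein flux.  Asparagine synthesis
retains the aspartate carbon skeleton, so both its protein deposition and
its efflux still count 1:1 toward aspartate demand.

Purines are destroyed by hot acid, so the purine aspartate demand is
estimated from pyrimidines: assuming equal purine and pyrimidine molar
demand P and equal AMP/GMP synthesis flux, de novo purine synthesis costs
P aspartate at the shared IMP step plus P/2 at the AMP step — 1.5x the
pyrimidine cost (one aspartate per pyrimidine ring).

Arginine synthesis is absent in cells grown with excess media arginine, so
its term defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PURINE_TO_PYRIMIDINE_RATIO",
    "POOL_TYPES",
    "CompositionTable",
    "FateFluxBudget",
    "concentration_to_flux",
    "build_budget",
]

#: Aspartate cost of de novo purine synthesis relative to pyrimidine
#: synthesis: 1 Asp/IMP for all purines + 1 extra Asp/AMP with AMP = GMP.
PURINE_TO_PYRIMIDINE_RATIO = 1.5

POOL_TYPES = ("single", "asp_asn_combined", "glu_gln_combined", "pyrimidine")


@dataclass(frozen=True)
class CompositionTable:
    """Total cellular concentrations (mM per total cell volume) by compound.

    ``pool_type`` flags combined acid-hydrolysis pools and pyrimidine
    species that draw one aspartate per ring.
    """

    table: pd.DataFrame  # columns: compound, concentration_mM, pool_type

    def __post_init__(self) -> None:
        required = {"compound", "concentration_mM", "pool_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"composition table missing columns: {sorted(missing)}")
        if (self.table["concentration_mM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        bad = set(self.table["pool_type"]) - set(POOL_TYPES)
        if bad:
            raise ValueError(f"unknown pool types {sorted(bad)}; allowed: {POOL_TYPES}")

    def concentration(self, pool_type: str) -> float:
        """Summed concentration (mM) over all rows of one pool type."""
        sel = self.table["pool_type"] == pool_type
        return float(self.table.loc[sel, "concentration_mM"].sum())

    def n_rows(self, pool_type: str) -> int:
        return int((self.table["pool_type"] == pool_type).sum())


@dataclass(frozen=True)
class FateFluxBudget:
    """Per-fate aspartate consumption fluxes, mM/h, and their total."""

    asp_to_protein: float
    asn_synthesis_to_protein: float
    asn_efflux: float
    pyrimidine: float
    purine: float
    arginine: float

    @property
    def total_demand(self) -> float:
        return (
            self.asp_to_protein
            + self.asn_synthesis_to_protein
            + self.asn_efflux
            + self.pyrimidine
            + self.purine
            + self.arginine
        )

    def as_series(self) -> pd.Series:
        data = {
            "asp_to_protein": self.asp_to_protein,
            "asn_synthesis_to_protein": self.asn_synthesis_to_protein,
            "asn_efflux": self.asn_efflux,
            "pyrimidine": self.pyrimidine,
            "purine": self.purine,
            "arginine": self.arginine,
            "total_demand": self.total_demand,
        }
        return pd.Series(data, name="flux_mM_per_h")


def concentration_to_flux(C_mM: float, K_per_h: float) -> float:
    """Synthesis flux maintaining concentration C at doubling rate K:
    F = K * ln(2) * C (mM/h)."""
    if C_mM < 0:
        raise ValueError("concentration must be non-negative")
    if K_per_h < 0:
        raise ValueError("doubling rate must be non-negative")
    return float(K_per_h * np.log(2.0) * C_mM)


def build_budget(
    comp: CompositionTable,
    K_per_h: float,
    asn_prot_flux: float,
    asn_efflux: float,
    purine_rule: bool = True,
) -> FateFluxBudget:
    """Assemble the per-fate aspartate budget.

    ``K_per_h`` is the proliferation rate in doublings per hour;
    ``asn_prot_flux`` and ``asn_efflux`` (mM/h) come from the asparagine
    partition.  With ``purine_rule`` the purine demand is 1.5x the
    pyrimidine demand; otherwise purines are reported as zero (e.g. when an
    independent purine estimate will be substituted).
    """
    if asn_prot_flux < 0 or asn_efflux < 0:
        raise ValueError("asparagine fluxes must be non-negative")
    combined = comp.concentration("asp_asn_combined")
    pool_flux = concentration_to_flux(combined, K_per_h)
    if asn_prot_flux > pool_flux + 1e-12:
        raise ValueError(
            f"asparagine-to-protein flux ({asn_prot_flux:g} mM/h) exceeds the "
            f"combined Asp+Asn pool flux ({pool_flux:g} mM/h)"
        )
    pyrimidine = concentration_to_flux(comp.concentration("pyrimidine"), K_per_h)
    if purine_rule:
        if comp.n_rows("pyrimidine") == 0:
            raise ValueError("purine rule requires at least one pyrimidine entry")
        purine = PURINE_TO_PYRIMIDINE_RATIO * pyrimidine
    else:
        purine = 0.0
    return FateFluxBudget(
        asp_to_protein=pool_flux - asn_prot_flux,
        asn_synthesis_to_protein=float(asn_prot_flux),
        asn_efflux=float(asn_efflux),
        pyrimidine=pyrimidine,
        purine=purine,
        arginine=0.0,
    )
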