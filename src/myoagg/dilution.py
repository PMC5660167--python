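"""Reconciling per-mass and per-nucleus aggregate readouts.

A ligand-capture ELISA reads aggregated-HTT load per unit tissue mass,
while image statistics read load per nucleus.  If a treatment makes fibres
hypertrophy by a factor ``h`` at constant myonuclei per fibre, the density
of nuclei per milligram falls as ``1/h`` per unit fibre length (and as
``1/h**2`` per unit cross-sectional area), so the per-mass signal can fall
even when the aggregation process per nucleus is untouched.  This module
formalises that argument as a small linear model

    per_mass_signal = nuclei_per_mg / h * (1 - satellite_fraction)
                      * load_per_nucleus

(``satellite_fraction`` is the aggregate-free satellite-cell share of
nuclei, which inflates nucleus counts without contributing aggregate), and
classifies a treated/vehicle experiment from the two ratios:

* ``dilution``        — per-mass signal fell but per-nucleus load did not;
* ``disease-modifying`` — both fell;
* ``mixed``           — anything else (including no change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueState",
    "Verdict",
    "per_mass_signal",
    "per_nucleus_load",
    "reconcile",
    "simulate_elisa",
]


@dataclass(frozen=True)
class TissueState:
    """Aggregate-relevant state of one muscle condition.

    ``nuclei_per_mg`` is the baseline (h=1) nuclear density; the realized
    density is ``nuclei_per_mg / hypertrophy_factor``.  Loads are in
    arbitrary aggregate units per nucleus.
    """

    nuclei_per_mg: float
    load_per_nucleus: float
    hypertrophy_factor: float = 1.0
    satellite_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.nuclei_per_mg <= 0:
            raise ValueError("nuclei_per_mg must be positive")
        if self.load_per_nucleus < 0:
            raise ValueError("load_per_nucleus must be non-negative")
        if self.hypertrophy_factor <= 0:
            raise ValueError("hypertrophy_factor must be positive")
        if not 0 <= self.satellite_fraction < 1:
            raise ValueError("satellite_fraction must lie in [0, 1)")


def per_mass_signal(state: TissueState) -> float:
    """Expected per-mass aggregate signal of a tissue state.

    Linear in ``load_per_nucleus`` and proportional to ``1/h`` at fixed
    other fields; satellite nuclei contribute no aggregate.
    """
    return (
        state.nuclei_per_mg
        / state.hypertrophy_factor
        * (1.0 - state.satellite_fraction)
        * state.load_per_nucleus
    )


def per_nucleus_load(
    mean_nuclear_inclusion_px: float, pct_nuclei_with_inclusions: float
) -> float:
    """Per-nucleus aggregate load from image statistics.

    Defined as mean nuclear-inclusion size times the fraction of nuclei
    carrying an inclusion — the two per-nucleus panel quantities — so a
    shift in either inclusion size or penetrance moves the load.
    """
    if not 0 <= pct_nuclei_with_inclusions <= 100:
        raise ValueError("pct_nuclei_with_inclusions must lie in [0, 100]")
    return mean_nuclear_inclusion_px * pct_nuclei_with_inclusions / 100.0


@dataclass(frozen=True)
class Verdict:
    verdict: str  # "dilution" | "disease-modifying" | "mixed"
    elisa_ratio: float
    image_ratio: float
    tol: float


def reconcile(elisa_ratio: float, image_ratio: float, tol: float = 0.1) -> Verdict:
    """Classify a treated/vehicle experiment from its two readout ratios.

    ``elisa_ratio`` is treated/vehicle per-mass signal; ``image_ratio`` is
    treated/vehicle per-nucleus load.  A ratio below ``1 - tol`` counts as
    a decrease.
    """
    if elisa_ratio <= 0 or image_ratio <= 0:
        raise ValueError("ratios must be positive")
    if not 0 <= tol < 1:
        raise ValueError("tol must lie in [0, 1)")
    cut = 1.0 - tol
    if elisa_ratio < cut and image_ratio >= cut:
        verdict = "dilution"
    elif elisa_ratio < cut and image_ratio < cut:
        verdict = "disease-modifying"
    else:
        verdict = "mixed"
    return Verdict(verdict=verdict, elisa_ratio=elisa_ratio, image_ratio=image_ratio, tol=tol)


def simulate_elisa(
    states: list[TissueState],
    cv: float,
    n_replicates: int,
    seed: int = 0,
) -> np.ndarray:
    """Replicate per-mass signals with multiplicative lognormal noise.

    The noise factor has mean 1 and coefficient of variation ``cv``
    (``sigma**2 = log(1 + cv**2)``, ``mu = -sigma**2 / 2``), so replicate
    means converge to the closed-form :func:`per_mass_signal`.  Returns an
    array of shape ``(len(states), n_replicates)``; deterministic per seed.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    signals = np.array([per_mass_signal(s) for s in states])
    if cv == 0:
        return np.tile(signals[:, None], (1, n_replicates))
    sigma = np.sqrt(np.log1p(cv**2))
    noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=(len(states), n_replicates))
    return signals[:, None] * noise
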