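"""Stochastic error propagation for the plate assay.

Four independent error sources perturb the measured bound fraction:

1. *antigen quantity* — serial-dilution and coating-uniformity errors,
   modelled as a +/-10% perturbation of every [Ag]0 entering the exact
   binding model (and, under kinetic distortion, the rate factor too);
2. *antibody quantity* — a +/-1% pipetting error on T; because the blank
   wells stand in for T, the apparent bound fraction transforms as
   ``B'/T = B/T - (dT/T)*(1 - B/T)``, so this error scales with the
   unbound fraction;
3. *nonspecific binding* — well-to-well variation of the blank signal,
   entering twice (once through U_blank and once through U) so the
   propagated SD is sqrt(2) times the blank relative SD;
4. *gamma counter* — a constant counting SD in bound-fraction units.

Each source yields an SD grid over (K_D, [Ag]0); the overall SD is their
quadratic sum, and dividing by the mean bound fractions gives the
coefficient-of-variation grid.

SD convention: each perturbation-based SD is the *sample* SD (n-1
denominator) of the triplet {perturbed down, nominal, perturbed up}.
For a symmetric triplet {x-d, x, x+d} this equals d exactly, which is
what makes the antibody SD identically ``0.01*(1 - B/T)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import (
    AntigenSeries,
    BindingParameters,
    BoundFractionGrid,
    bound_fraction_exact,
)
from .kinetics import KineticSettings, integrated_rate_factor

__all__ = [
    "NoiseModel",
    "antibody_error_transform",
    "sd_antigen_grid",
    "sd_antibody_grid",
    "sd_nonspecific",
    "overall_sd_grid",
    "cv_grid",
    "build_sd_grid",
]


@dataclass(frozen=True)
class NoiseModel:
    """Magnitudes of the four stochastic error sources.

    rel_err_antigen : relative error on coated [Ag]0 (default 0.10)
    rel_err_antibody : relative pipetting error on T (default 0.01)
    blank_sd_fraction : relative SD of blank-well counts (default 0.015)
    counter_sd : gamma-counter SD in bound-fraction units (default 0.01)
    """

    rel_err_antigen: float = 0.10
    rel_err_antibody: float = 0.01
    blank_sd_fraction: float = 0.015
    counter_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("rel_err_antigen", "rel_err_antibody", "blank_sd_fraction", "counter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def antibody_error_transform(bound_fraction, delta_t_over_t):
    """Apparent bound fraction under a relative antibody-volume error.

    ``B'/T = B/T - (dT/T) * (1 - B/T)``: a fully bound well (B/T = 1)
    carries no antibody error because there is no unbound signal.
    """
    bf = np.asarray(bound_fraction, dtype=float)
    out = bf - np.asarray(delta_t_over_t, dtype=float) * (1.0 - bf)
    return out if out.ndim else float(out)


def _triplet_sd(low, mid, high):
    """Sample SD (ddof=1) over a perturbation triplet, elementwise."""
    return np.std(np.stack([low, mid, high]), axis=0, ddof=1)


def sd_antigen_grid(
    params: BindingParameters,
    kd_axis,
    antigen: AntigenSeries,
    kinetics: KineticSettings | None = None,
    rel_err: float = 0.10,
    perturb_rate_factor: bool = True,
) -> np.ndarray:
    """SD grid for a relative error on the coated antigen quantity.

    For each cell the exact bound fraction is evaluated at
    {1-rel_err, 1, 1+rel_err} times the coated [Ag]0 and the sample SD
    of the triplet taken.  When ``kinetics`` is given the cells are the
    kinetics-distorted fractions; the perturbed antigen then also enters
    the integrated rate factor unless ``perturb_rate_factor`` is False.

    The SD peaks where K_D is comparable to [Ag]0: well below, the bound
    fraction is small so the absolute SD is small; well above, [Ag]0
    drops out of the isotherm and the error vanishes.
    """
    ag = antigen.as_array()
    kd_axis = tuple(float(k) for k in kd_axis)
    triplet = []
    for f in (1.0 - rel_err, 1.0, 1.0 + rel_err):
        rows = []
        for kd in kd_axis:
            p = BindingParameters(r=params.r, kd=kd, kon=params.kon, T=params.T)
            bf = bound_fraction_exact(f * ag, p)
            if kinetics is not None:
                ag_in_rate = f * ag if perturb_rate_factor else ag
                bf = bf * integrated_rate_factor(kinetics.kon, ag_in_rate, kinetics.time)
            rows.append(bf)
        triplet.append(np.vstack(rows))
    return _triplet_sd(*triplet)


def sd_antibody_grid(grid: BoundFractionGrid | np.ndarray, rel_err: float = 0.01) -> np.ndarray:
    """SD grid for a relative antibody-volume error.

    Sample SD of {B/T transformed at -rel_err, B/T, transformed at
    +rel_err}; analytically equal to ``rel_err * (1 - B/T)``.
    """
    values = grid.values if isinstance(grid, BoundFractionGrid) else np.asarray(grid, dtype=float)
    return _triplet_sd(
        antibody_error_transform(values, -rel_err),
        values,
        antibody_error_transform(values, rel_err),
    )


def sd_nonspecific(noise: NoiseModel) -> float:
    """Constant SD from nonspecific-binding variation: sqrt(2) * blank SD."""
    return float(np.sqrt(2.0) * noise.blank_sd_fraction)


def overall_sd_grid(sd_ag, sd_ab, sd_ns: float, sd_counter: float) -> np.ndarray:
    """Cellwise quadratic sum of the four SD components."""
    sd_ag = np.asarray(sd_ag, dtype=float)
    sd_ab = np.asarray(sd_ab, dtype=float)
    if sd_ag.shape != sd_ab.shape:
        raise ValueError(f"component shapes differ: {sd_ag.shape} vs {sd_ab.shape}")
    return np.sqrt(sd_ag**2 + sd_ab**2 + sd_ns**2 + sd_counter**2)


def cv_grid(sd: np.ndarray, mean: BoundFractionGrid | np.ndarray) -> np.ndarray:
    """Coefficient of variation SD/mean; NaN where the mean is nonpositive."""
    mean = mean.values if isinstance(mean, BoundFractionGrid) else np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return out


def build_sd_grid(
    params: BindingParameters,
    kd_axis,
    antigen: AntigenSeries,
    noise: NoiseModel,
    kinetics: KineticSettings | None = None,
) -> np.ndarray:
    """Overall SD grid for a configuration, kinetics-adjusted when given.

    The antigen and antibody SD grids are recomputed from the
    kinetics-distorted bound fractions; the nonspecific and counter SDs
    are constants and unaffected.
    """
    sd_ag = sd_antigen_grid(
        params, kd_axis, antigen, kinetics=kinetics, rel_err=noise.rel_err_antigen
    )
    # distorted mean grid for the antibody component
    ag = antigen.as_array()
    rows = []
    for kd in kd_axis:
        p = BindingParameters(r=params.r, kd=kd, kon=params.kon, T=params.T)
        bf = bound_fraction_exact(ag, p)
        if kinetics is not None:
            bf = bf * integrated_rate_factor(kinetics.kon, ag, kinetics.time)
        rows.append(bf)
    sd_ab = sd_antibody_grid(np.vstack(rows), rel_err=noise.rel_err_antibody)
    return overall_sd_grid(sd_ag, sd_ab, sd_nonspecific(noise), noise.counter_sd)
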