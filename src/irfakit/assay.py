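"""Real-assay arithmetic and design helpers.

Plate reduction converts raw gamma-counter records into bound-fraction
curve points.  The assay measures the *supernatant* (unbound) activity
``U`` of each well; blocked-but-uncoated blank wells give ``U_blank``.
Because nonspecific binding is invariant across wells (the blocked
polystyrene area is the same everywhere), the specific bound activity
is simply ``B_spec = mean(U_blank) - U``, and the mean blank stands in
for the total activity ``T`` when forming bound fractions.  Separate
total-activity tubes serve only as an internal control, from which the
nonspecific binding ``B_NS = mean(T_tubes) - mean(U_blank)`` is
reported.

Design helpers compute the well surface area of a cylindrical well
filled to a given volume and the maximum antigen concentration that a
high-binding polystyrene plate can coat, which caps the usable [Ag]0
series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import CurvePoint
from .kinetics import TimeCourse, kon_from_half_time

__all__ = [
    "PlateCounts",
    "WellGeometry",
    "specific_bound",
    "reduce_plate",
    "estimate_kon_from_kinetic_series",
    "well_surface_area",
    "max_coated_antigen",
    "read_plate_csv",
]


@dataclass
class PlateCounts:
    """Per-well gamma-counter records for one assay plate.

    ``wells`` is a DataFrame with columns ``well`` (id), ``ag0_nM``
    (NaN for blanks and T tubes), ``counts`` (cpm) and ``role`` in
    {well, blank, t_tube}.
    """

    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"well", "ag0_nM", "counts", "role"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if (self.wells["counts"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if not (self.wells["role"] == "blank").any():
            raise ValueError("at least one blank well is required")
        blanks = self.wells[self.wells["role"] == "blank"]
        if blanks["ag0_nM"].notna().any():
            raise ValueError("blank wells must not carry an antigen concentration")

    @property
    def blank_counts(self) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == "blank", "counts"].to_numpy(float)

    @property
    def t_tube_counts(self) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == "t_tube", "counts"].to_numpy(float)


@dataclass(frozen=True)
class WellGeometry:
    """Microplate well geometry and binding capacity.

    ``binding_capacity`` is the areal capacity of a high-binding plate
    (ng IgG per cm^2).  ``nominal_mass_ng`` is the practical per-well
    coatable mass used for concentration caps; its default of 500 ng is
    the vendor round figure, consistent with the areal capacity times
    the ~0.95 cm^2 wetted area at 100 uL.
    """

    diameter_mm: float = 6.4
    volume_ul: float = 100.0
    binding_capacity_ng_per_cm2: float = 500.0
    nominal_mass_ng: float = 500.0

    def __post_init__(self) -> None:
        for name in ("diameter_mm", "volume_ul", "binding_capacity_ng_per_cm2", "nominal_mass_ng"):
            if getattr(self, name) < 0 or (name != "volume_ul" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    def geometric_mass_ng(self) -> float:
        """Coatable mass from areal capacity x wetted area (~473 ng)."""
        area_cm2 = well_surface_area(self) / 100.0
        return self.binding_capacity_ng_per_cm2 * area_cm2


def specific_bound(u: float, u_blank_mean: float) -> float:
    """Specifically bound activity ``mean(U_blank) - U``.

    Negative values (counting noise) are reported with a warning, never
    clipped, so downstream estimator behaviour matches the simulation.
    """
    if u < 0 or u_blank_mean < 0:
        raise ValueError("counts must be nonnegative")
    b = u_blank_mean - u
    if b < 0:
        warnings.warn(
            f"negative specific binding ({b:.3g}): supernatant exceeds blank mean",
            RuntimeWarning,
            stacklevel=2,
        )
    return b


def reduce_plate(plate: PlateCounts) -> tuple[list[CurvePoint], dict]:
    """Reduce raw counts to bound-fraction curve points.

    Per antigen level: bound fraction = (mean U_blank - mean U) / mean
    U_blank, with the replicate SD of the bound fraction attached.
    Returns the points plus a diagnostics dict with the nonspecific
    binding estimate (from T tubes), the blank relative SD, and a count
    of negative bound fractions.
    """
    blanks = plate.blank_counts
    u_blank = float(blanks.mean())
    if u_blank <= 0:
        raise ValueError("mean blank counts must be positive")
    coated = plate.wells[plate.wells["role"] == "well"]
    if coated["ag0_nM"].nunique() < 2:
        raise ValueError("need at least 2 antigen levels")
    points: list[CurvePoint] = []
    n_negative = 0
    for ag0, group in coated.groupby("ag0_nM", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bf = np.array([specific_bound(u, u_blank) / u_blank for u in group["counts"]])
        n_negative += int((bf < 0).sum())
        sd = float(bf.std(ddof=1)) if len(bf) > 1 else None
        points.append(CurvePoint(float(ag0), float(bf.mean()), sd=sd))
    t_tubes = plate.t_tube_counts
    b_ns = float(t_tubes.mean() - u_blank) if t_tubes.size else None
    diagnostics = {
        "u_blank_mean": u_blank,
        "u_blank_rel_sd": float(blanks.std(ddof=1) / u_blank) if blanks.size > 1 else None,
        "nonspecific_binding": b_ns,
        "n_negative_bound_fractions": n_negative,
    }
    if n_negative:
        warnings.warn(
            f"{n_negative} negative bound fraction(s) retained (not clipped)",
            RuntimeWarning,
            stacklevel=2,
        )
    return points, diagnostics


def estimate_kon_from_kinetic_series(tc: TimeCourse, ag0_ref: float) -> float:
    """Association rate constant from the half-rise time of a trajectory.

    Finds the time at which the trajectory at ``ag0_ref`` reaches half
    its maximum by linear interpolation between the bracketing sampled
    time points, then converts via ``kon = ln2 / (t_half * ag0)``.
    """
    y = tc.trajectory(ag0_ref)
    times = np.asarray(tc.times, dtype=float)
    ymax = float(y.max())
    if ymax <= 0 or np.ptp(y) == 0:
        raise ValueError("trajectory is flat; cannot locate half-maximum")
    half = ymax / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        raise ValueError("trajectory never reaches half of its maximum")
    i = int(above[0])
    if i == 0:
        if y[0] == half:
            t_half = times[0]
        else:
            raise ValueError(
                "first sampled point already above half-maximum; sample earlier times"
            )
    else:
        t0, t1 = times[i - 1], times[i]
        y0, y1 = y[i - 1], y[i]
        t_half = t0 + (half - y0) * (t1 - t0) / (y1 - y0)
    return kon_from_half_time(float(t_half), ag0_ref)


def well_surface_area(geom: WellGeometry) -> float:
    """Wetted polystyrene area (mm^2): base disc + lateral band.

    The lateral height is the fill height ``volume / base_area`` of a
    cylindrical well.  Defaults give 94.7 mm^2 at 100 uL.
    """
    radius = geom.diameter_mm / 2.0
    base = math.pi * radius**2
    height = geom.volume_ul / base  # 1 uL = 1 mm^3
    lateral = math.pi * geom.diameter_mm * height
    return base + lateral


def max_coated_antigen(
    geom: WellGeometry, antigen_mw_kda: float, mass_ng: float | None = None
) -> float:
    """Maximum coatable antigen concentration (nM).

    ``mass_ng / (volume * MW)``: with the default nominal 500 ng per
    well, 100 uL and a 100 kDa antigen this is 50 nM.  Pass
    ``mass_ng=geom.geometric_mass_ng()`` to use the areal-capacity
    figure (~47 nM) instead.
    """
    if antigen_mw_kda <= 0:
        raise ValueError("antigen molecular weight must be positive")
    if mass_ng is None:
        mass_ng = geom.nominal_mass_ng
    # ng / (uL * kDa): 1 ng/uL of a 1 kDa species is 1 mM = 1e6 nM
    return 1e6 * mass_ng / (geom.volume_ul * antigen_mw_kda * 1000.0)


def read_plate_csv(path) -> PlateCounts:
    """Read a plate-counts CSV (columns well, ag0_nM, counts, role).

    Lines starting with ``#`` are metadata comments.  A legacy
    ``is_blank`` boolean column is honoured when ``role`` is absent.
    """
    df = pd.read_csv(path, comment="#")
    if "role" not in df.columns and "is_blank" in df.columns:
        df["role"] = np.where(df["is_blank"].astype(bool), "blank", "well")
    return PlateCounts(df)
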