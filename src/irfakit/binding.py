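"""Equilibrium binding models for the immunoreactive-fraction assay (IRFA).

The assay saturates a fixed trace concentration ``T`` of radiolabeled
antibody with an increasing series of plate-coated antigen ``[Ag]0`` and
measures the bound fraction ``B/T``.  Only a fraction ``r`` of the labeled
antibody is immunoreactive; ``r`` is defined as the bound fraction at
infinite antigen excess at equilibrium.

Three models live here:

* the *exact* 1:1 Langmuir model with antigen depletion, obtained by
  solving the mass-balance quadratic for ``B/T`` (free antigen is the
  applied antigen minus the bound complex);
* the *rectangular hyperbola* approximation
  ``B/T = r*[Ag]0 / ([Ag]0 + KD)``, valid when antigen is in large excess
  over antibody so that depletion is negligible;
* the *double-inverse (Lindmo) linearization* of the hyperbola,
  ``T/B = 1/r + (KD/r)/[Ag]0``.

Internal units are nM and minutes throughout; ``r`` is stored as a
fraction and formatted as a percentage only in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingParameters",
    "AntigenSeries",
    "BoundFractionGrid",
    "CurvePoint",
    "bound_fraction_exact",
    "bound_fraction_hyperbola",
    "lindmo_transform",
    "generate_ideal_grid",
    "generate_depletion_curves",
    "DEFAULT_KD_AXIS",
    "DEFAULT_ANTIGEN_NM",
]

#: K_D axis used in the simulation study (nM), spanning four orders of magnitude.
DEFAULT_KD_AXIS: tuple[float, ...] = (0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0, 31.62, 100.0)

#: Coated-antigen series for an unsaturated plate (nM).
DEFAULT_ANTIGEN_NM: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0)


@dataclass(frozen=True)
class BindingParameters:
    """True system parameters driving all models.

    Parameters
    ----------
    r : float
        Immunoreactive fraction, in [0, 1].
    kd : float
        Equilibrium dissociation constant K_D = k_off/k_on, nM.
    kon : float
        Association rate constant, nM^-1 min^-1.
    T : float
        Total applied antibody concentration, nM.
    """

    r: float = 0.7
    kd: float = 1.0
    kon: float = 1.444e-4
    T: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"immunoreactive fraction r must be in [0, 1], got {self.r}")
        if self.kd <= 0:
            raise ValueError(f"KD must be positive, got {self.kd}")
        if self.kon < 0:
            raise ValueError(f"kon must be nonnegative, got {self.kon}")
        if self.T <= 0:
            raise ValueError(f"total antibody T must be positive, got {self.T}")

    @property
    def koff(self) -> float:
        """Dissociation rate constant k_off = k_on * K_D (min^-1)."""
        return self.kon * self.kd


@dataclass(frozen=True)
class AntigenSeries:
    """Ordered series of coated total-antigen concentrations (nM).

    ``values`` are the concentrations actually available on the plate and
    used by every computation.  ``labels`` keep the nominal applied
    concentrations for reporting; they differ from ``values`` only on a
    saturated plate, where solutions applied above the polystyrene
    binding capacity all coat the same capped amount.
    """

    values: tuple[float, ...]
    labels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(v <= 0 for v in vals):
            raise ValueError("antigen concentrations must be positive")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("antigen series must be non-decreasing")
        if self.labels is None:
            object.__setattr__(self, "labels", vals)
        else:
            labels = tuple(float(v) for v in self.labels)
            if len(labels) != len(vals):
                raise ValueError("labels must match values in length")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CurvePoint:
    """One point of the saturation isotherm: bound fraction at one [Ag]0."""

    ag0: float
    bound_fraction: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.ag0 <= 0:
            raise ValueError(f"ag0 must be positive, got {self.ag0}")


@dataclass
class BoundFractionGrid:
    """Matrix of bound fractions B/T indexed by (K_D row, [Ag]0 column)."""

    kd_axis: tuple[float, ...]
    antigen: AntigenSeries
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.kd_axis = tuple(float(k) for k in self.kd_axis)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.kd_axis), len(self.antigen)):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.kd_axis)}, {len(self.antigen)})"
            )

    def row(self, kd: float) -> np.ndarray:
        """Bound-fraction series for one K_D (nM)."""
        kd_arr = np.asarray(self.kd_axis)
        i = int(np.argmin(np.abs(kd_arr - kd)))
        if not np.isclose(kd_arr[i], kd, rtol=1e-9):
            raise KeyError(f"KD={kd} not on the grid axis {self.kd_axis}")
        return self.values[i]

    def row_points(self, kd: float) -> list[CurvePoint]:
        """Curve points for one K_D row.

        Points carry the *nominal applied* antigen labels: on a
        saturated plate the experimenter fits against what was applied,
        not against the (unknown) coated amount — that mismatch is the
        saturation artefact being modelled.
        """
        return [CurvePoint(a, float(v)) for a, v in zip(self.antigen.labels, self.row(kd))]

    def copy_with(self, values: np.ndarray) -> "BoundFractionGrid":
        return BoundFractionGrid(self.kd_axis, self.antigen, np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns kd_nM, ag0_nM, bound_fraction."""
        kd = np.repeat(self.kd_axis, len(self.antigen))
        ag = np.tile(self.antigen.labels, len(self.kd_axis))
        return pd.DataFrame(
            {"kd_nM": kd, "ag0_nM": ag, "bound_fraction": self.values.ravel()}
        )


def bound_fraction_exact(ag0, params: BindingParameters):
    """Bound fraction from the depletion-exact quadratic model.

    Solves the mass balance ``B/T = r*([Ag]0 - B) / (([Ag]0 - B) + KD)``
    exactly: with ``x = B/T``, ``a = [Ag]0/T`` and ``k = KD/T``,

        x**2 - (k + a + r) * x + r * a = 0

    and the physically meaningful smaller root is returned (the larger
    one neither vanishes at ``[Ag]0 = 0`` nor converges to ``r``).  To
    avoid catastrophic cancellation when ``[Ag]0/T`` is large, the larger
    root is computed first and the smaller obtained from the product of
    roots ``r*a``.

    Accepts scalar or array ``ag0`` (nM); returns the same shape.
    """
    ag0 = np.asarray(ag0, dtype=float)
    if np.any(ag0 < 0):
        raise ValueError("ag0 must be nonnegative")
    a = ag0 / params.T
    s = params.kd / params.T + a + params.r
    disc = s * s - 4.0 * params.r * a
    if np.any(disc < 1e-12):
        warnings.warn(
            "near-degenerate quadratic (discriminant < 1e-12); roots nearly coincide",
            RuntimeWarning,
            stacklevel=2,
        )
    disc = np.maximum(disc, 0.0)
    larger = 0.5 * (s + np.sqrt(disc))
    out = np.where(larger > 0, params.r * a / np.where(larger > 0, larger, 1.0), 0.0)
    return out if out.ndim else float(out)


def bound_fraction_hyperbola(ag0, r: float, kd: float):
    """Rectangular-hyperbola (Langmuir) bound fraction ``r*ag0/(ag0+kd)``."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    ag0 = np.asarray(ag0, dtype=float)
    if np.any(ag0 < 0):
        raise ValueError("ag0 must be nonnegative")
    out = r * ag0 / (ag0 + kd)
    return out if out.ndim else float(out)


def lindmo_transform(
    points: Sequence[CurvePoint],
) -> tuple[list[tuple[float, float]], int]:
    """Double-inverse transform ``(ag0, B/T) -> (1/ag0, T/B)``.

    Points with nonpositive bound fraction have no reciprocal; they are
    excluded and counted, never silently dropped.  Returns the
    transformed pairs (input order preserved) and the number of points
    excluded.
    """
    pairs: list[tuple[float, float]] = []
    dropped = 0
    for p in points:
        if p.bound_fraction <= 0:
            dropped += 1
            continue
        pairs.append((1.0 / p.ag0, 1.0 / p.bound_fraction))
    return pairs, dropped


def generate_ideal_grid(
    kd_axis: Iterable[float],
    antigen: AntigenSeries | Iterable[float],
    params: BindingParameters,
) -> BoundFractionGrid:
    """Theoretical equilibrium bound fractions from the exact model.

    Each cell ``(K_D, [Ag]0)`` is the exact-quadratic bound fraction for
    the grid's K_D at that antigen level; ``params.kd`` is ignored in
    favour of the row's K_D.
    """
    if not isinstance(antigen, AntigenSeries):
        antigen = AntigenSeries(tuple(antigen))
    kd_axis = tuple(float(k) for k in kd_axis)
    if not kd_axis or not len(antigen):
        raise ValueError("axes must be non-empty")
    ag = antigen.as_array()
    rows = []
    for kd in kd_axis:
        p = BindingParameters(r=params.r, kd=kd, kon=params.kon, T=params.T)
        rows.append(bound_fraction_exact(ag, p))
    return BoundFractionGrid(kd_axis, antigen, np.vstack(rows))


def generate_depletion_curves(
    t_axis: Iterable[float],
    antigen: AntigenSeries | Iterable[float],
    r: float = 0.7,
    kd: float = 1.0,
) -> pd.DataFrame:
    """Exact bound fractions over a total-antibody axis at fixed K_D.

    Used to study antigen depletion: once ``T`` exceeds the smallest
    coated antigen level, free antigen is no longer approximated by the
    applied antigen and both approximate estimators overestimate ``r``.
    Returns a long table (T_nM, ag0_nM, bound_fraction).
    """
    if not isinstance(antigen, AntigenSeries):
        antigen = AntigenSeries(tuple(antigen))
    ag = antigen.as_array()
    records = []
    for T in t_axis:
        p = BindingParameters(r=r, kd=kd, T=float(T))
        bf = bound_fraction_exact(ag, p)
        for a, v in zip(antigen.labels, np.atleast_1d(bf)):
            records.append({"T_nM": float(T), "ag0_nM": a, "bound_fraction": float(v)})
    return pd.DataFrame.from_records(records)
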