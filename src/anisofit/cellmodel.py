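"""Cytosolic partitioning of formaldehyde between a sensor and glutathione.

A trace transcriptional sensor (effective formaldehyde dissociation
constant ``k_sensor``) competes with the bulk reduced-glutathione pool
(GSH + formaldehyde <=> S-(hydroxymethyl)glutathione, dissociation
constant ``k_gsh``) for free formaldehyde F.  At each total
formaldehyde the single-unknown mass balance

    F_total = F + GSH_tot * F/(k_gsh + F) + sites_tot * F/(k_sensor + F)

is solved for free F (monotone, bracketed by [0, F_total]), from which
the fractional modification of the sensor sites, the S-HMG fraction of
the GSH pool, and the free pool follow.  Covalent modification is
treated as a reversible equilibrium with the stated effective
affinities; the sensor pool (tens of nM) is numerically negligible next
to millimolar GSH, so the sites-per-tetramer bookkeeping barely moves
free F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "AVOGADRO",
    "CellModelParams",
    "ModificationCurve",
    "CytosolCompetitionModel",
    "modification_curve",
    "formaldehyde_at_gsh_fraction",
    "copies_per_cell",
    "molar_from_copies",
    "FRMR_PARAMS",
    "RCNR_PARAMS",
]

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214e23


@dataclass(frozen=True)
class CellModelParams:
    """Fixed constants of the two-ligand competition model.

    Defaults describe the formaldehyde sensor FrmR in an enteric
    bacterium growing anaerobically: effective formaldehyde affinity
    1e-5 M, GSH/S-HMG dissociation constant 1.77e-3 M, 1.2 mM total
    GSH, 16.1 nM sensor tetramer with 4 formaldehyde sites per tetramer
    (one per monomer), 1 fl cell volume.
    """

    k_sensor: float = 1e-5  # M
    k_gsh: float = 1.77e-3  # M
    sensor_tetramer_total: float = 1.61e-8  # M
    sites_per_tetramer: int = 4
    gsh_total: float = 1.2e-3  # M
    cell_volume: float = 1e-15  # L
    label: str = "FrmR"

    def __post_init__(self) -> None:
        for name in ("k_sensor", "k_gsh", "sensor_tetramer_total", "gsh_total", "cell_volume"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be positive and finite")
        if self.sites_per_tetramer not in (1, 4):
            raise ValueError("sites_per_tetramer must be 1 or 4")

    @property
    def sensor_sites_total(self) -> float:
        return self.sites_per_tetramer * self.sensor_tetramer_total


#: FrmR under anaerobic (TMAO) growth.
FRMR_PARAMS = CellModelParams()
#: RcnR: weaker effective formaldehyde affinity (a tighter limit, 1e-4 M).
RCNR_PARAMS = CellModelParams(k_sensor=1e-4, label="RcnR")


@dataclass
class ModificationCurve:
    """Fractional modification vs total formaldehyde."""

    f_total_grid: np.ndarray  # M
    f_sensor: np.ndarray  # fraction of sensor sites carrying formaldehyde
    f_gsh: np.ndarray  # S-HMG fraction of the GSH pool
    f_free: np.ndarray  # M, free formaldehyde
    params: CellModelParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "f_total_M": self.f_total_grid,
                "f_free_M": self.f_free,
                "frac_sensor": self.f_sensor,
                "frac_gsh": self.f_gsh,
            }
        )


def _free_formaldehyde(params: CellModelParams, f_total: float) -> float:
    """Free F from the scalar mass balance at one total formaldehyde."""
    if f_total == 0.0:
        return 0.0

    def balance(f: float) -> float:
        return (
            f
            + params.gsh_total * f / (params.k_gsh + f)
            + params.sensor_sites_total * f / (params.k_sensor + f)
            - f_total
        )

    return optimize.brentq(balance, 0.0, f_total, xtol=1e-30, rtol=1e-15)


def modification_curve(params: CellModelParams, f_total_grid: np.ndarray) -> ModificationCurve:
    """Solve the competition model along a grid of total formaldehyde."""
    grid = np.asarray(f_total_grid, dtype=float)
    if grid.ndim != 1 or np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("f_total_grid must be a non-negative increasing vector")

    free = np.empty_like(grid)
    for i, ft in enumerate(grid):
        try:
            free[i] = _free_formaldehyde(params, ft)
        except Exception as exc:  # pragma: no cover - brentq on a bracketed monotone fn
            raise RuntimeError(f"mass-balance solve failed at grid index {i} (F_total={ft:g} M)") from exc

    f_sensor = free / (params.k_sensor + free)
    f_gsh = free / (params.k_gsh + free)
    return ModificationCurve(grid, f_sensor, f_gsh, free, params)


def formaldehyde_at_gsh_fraction(params: CellModelParams, target_f_gsh: float) -> float:
    """Total formaldehyde at which the S-HMG fraction of GSH equals target.

    The free concentration follows in closed form from the binding
    hyperbola, ``F = target/(1-target) * k_gsh``; the bound pools are
    then added back to give the total.
    """
    if not (0.0 < target_f_gsh < 1.0):
        raise ValueError("target_f_gsh must be in (0, 1)")
    f = target_f_gsh / (1.0 - target_f_gsh) * params.k_gsh
    return (
        f
        + params.gsh_total * f / (params.k_gsh + f)
        + params.sensor_sites_total * f / (params.k_sensor + f)
    )


def copies_per_cell(concentration: float, cell_volume: float = 1e-15) -> float:
    """Molecules per cell for a molar concentration in a given cell volume."""
    if concentration < 0 or cell_volume < 0:
        raise ValueError("concentration and cell_volume must be >= 0")
    return concentration * cell_volume * AVOGADRO


def molar_from_copies(copies: float, cell_volume: float = 1e-15) -> float:
    """Exact inverse of :func:`copies_per_cell`."""
    if copies < 0 or not (cell_volume > 0):
        raise ValueError("copies must be >= 0 and cell_volume > 0")
    return copies / (cell_volume * AVOGADRO)


class CytosolCompetitionModel:
    """Forward model of sensor-vs-GSH formaldehyde partitioning.

    A convenience wrapper over :func:`modification_curve` and
    :func:`formaldehyde_at_gsh_fraction` holding one parameter set.

    Examples
    --------
    >>> model = CytosolCompetitionModel(FRMR_PARAMS)
    >>> curve = model.curve()
    >>> model.sensor_fraction_at_gsh_fraction(0.04)  # doctest: +SKIP
    0.88...
    """

    def __init__(self, params: CellModelParams | None = None, **overrides):
        params = params or CellModelParams()
        self.params = replace(params, **overrides) if overrides else params

    def curve(self, f_total_grid: np.ndarray | None = None) -> ModificationCurve:
        if f_total_grid is None:
            f_total_grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e-1, 200)])
        return modification_curve(self.params, f_total_grid)

    def free_formaldehyde(self, f_total: float) -> float:
        return _free_formaldehyde(self.params, f_total)

    def formaldehyde_at_gsh_fraction(self, target_f_gsh: float) -> float:
        return formaldehyde_at_gsh_fraction(self.params, target_f_gsh)

    def sensor_fraction_at_gsh_fraction(self, target_f_gsh: float) -> float:
        """Sensor site occupancy at the total F where f_gsh hits target."""
        f_total = self.formaldehyde_at_gsh_fraction(target_f_gsh)
        f = _free_formaldehyde(self.params, f_total)
        return f / (self.params.k_sensor + f)

    def sensor_copies_per_cell(self) -> float:
        return copies_per_cell(self.params.sensor_tetramer_total, self.params.cell_volume)

    def summary(self, gsh_fraction: float = 0.04) -> str:
        p = self.params
        ft = self.formaldehyde_at_gsh_fraction(gsh_fraction)
        fs = self.sensor_fraction_at_gsh_fraction(gsh_fraction)
        return "\n".join(
            [
                f"Cytosolic competition model ({p.label})",
                "---------------------------------------",
                f"k_sensor:         {p.k_sensor:.2e} M",
                f"k_gsh (S-HMG):    {p.k_gsh:.2e} M",
                f"GSH total:        {p.gsh_total:.2e} M",
                f"sensor tetramer:  {p.sensor_tetramer_total:.2e} M "
                f"({self.sensor_copies_per_cell():.1f} copies/cell at {p.cell_volume:.0e} L)",
                f"sensor sites:     {p.sensor_sites_total:.2e} M ({p.sites_per_tetramer}/tetramer)",
                f"at f_gsh = {gsh_fraction:.0%}: total F = {ft:.3e} M, sensor modified = {fs:.1%}",
            ]
        )
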