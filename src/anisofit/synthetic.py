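"""Synthetic anisotropy titrations with realistic replicate noise.

Generates the two experimental designs the fitter is meant for:

* trace-probe K determination — 10 nM labelled probe, 20 points,
  0-2 uM added monomer;
* stoichiometric breakpoint — 2.5 uM probe, 0-30 uM monomer.

Noise is additive i.i.d. Gaussian on the anisotropy change (constant
variance, matching the fitter's least-squares assumption), default SD
5% of the saturating response, with independent replicates drawn from
one seeded generator so the whole dataset is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .titration import ResponseModel, TitrationData, simulate_curve

__all__ = [
    "NoiseSpec",
    "trace_probe_schedule",
    "stoichiometric_schedule",
    "gen_titration",
    "gen_effector_series",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the anisotropy change."""

    sd: float = 0.005  # anisotropy units; 5% of the default delta_r_max 0.1
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def trace_probe_schedule(n_points: int = 20, max_monomer: float = 2e-6) -> np.ndarray:
    """Default trace-probe design: 20 points, 0-2 uM added monomer."""
    return np.linspace(0.0, max_monomer, n_points)


def stoichiometric_schedule(n_points: int = 20, max_monomer: float = 30e-6) -> np.ndarray:
    """Default stoichiometric design: 0-30 uM monomer over a 2.5 uM probe."""
    return np.linspace(0.0, max_monomer, n_points)


def gen_titration(
    true_k: float,
    probe_total: float,
    schedule: np.ndarray | None = None,
    response: ResponseModel | None = None,
    noise: NoiseSpec | None = None,
    effector_label: str | None = None,
    effector_concentration: float | None = None,
) -> list[TitrationData]:
    """Simulate replicate titrations at a known K with Gaussian noise.

    Deterministic for a fixed ``noise.seed``; with ``sd = 0`` the output
    equals :func:`anisofit.titration.simulate_curve` exactly.
    """
    schedule = trace_probe_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    response = response or ResponseModel()
    noise = noise or NoiseSpec()

    clean = simulate_curve(true_k, probe_total, schedule, response)
    rng = np.random.default_rng(noise.seed)
    out = []
    for rep in range(noise.n_replicates):
        y = clean + (rng.normal(0.0, noise.sd, size=len(schedule)) if noise.sd > 0 else 0.0)
        out.append(
            TitrationData(
                probe_total=probe_total,
                titrant_monomer_totals=schedule,
                delta_r=y,
                replicate_id=rep + 1,
                effector_label=effector_label,
                effector_concentration=effector_concentration,
            )
        )
    return out


def gen_effector_series(
    true_k_apo: float,
    fold_changes: Sequence[float],
    probe_total: float = 1e-8,
    schedule: np.ndarray | None = None,
    response: ResponseModel | None = None,
    noise: NoiseSpec | None = None,
) -> dict[float, list[TitrationData]]:
    """Dose series of titrations with effector-weakened apparent K.

    Each entry of ``fold_changes`` multiplies the apo K (fold 1 is the
    apo condition); each condition gets its own replicates from one
    seeded stream.  Returns ``{fold: [TitrationData, ...]}``.
    """
    noise = noise or NoiseSpec()
    out: dict[float, list[TitrationData]] = {}
    for i, fold in enumerate(fold_changes):
        if not (fold > 0):
            raise ValueError("fold changes must be > 0")
        cond_noise = NoiseSpec(
            sd=noise.sd,
            seed=noise.seed + i,  # independent stream per condition
            n_replicates=noise.n_replicates,
        )
        out[float(fold)] = gen_titration(
            true_k_apo * fold,
            probe_total,
            schedule=schedule,
            response=response,
            noise=cond_noise,
            effector_label=f"fold={fold:g}",
        )
    return out
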