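"""Equilibrium speciation for small binding schemes.

A binding mechanism is declared as *components* (species conserved by a
mass balance, each with a total concentration) plus *complexes* (bound
states with an overall dissociation constant).  For a complex ``c`` with
stoichiometry ``nu_ic`` over components ``i``

    [c] = prod_i [free_i]**nu_ic / K_c

and the solver finds the free concentrations that close every mass
balance

    total_i = free_i + sum_c nu_ic [c]

This is the numerical core behind every simulated or fitted anisotropy
titration curve in this package, and behind the cytosolic competition
model.  All concentrations are molar; ``K_c`` carries units of
M**(sum(nu)-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

__all__ = [
    "EPS",
    "Component",
    "ComplexSpecies",
    "Scheme",
    "SpeciationResult",
    "SpeciationError",
    "solve_speciation",
    "closed_form_single_site",
    "build_two_tetramer_scheme",
]

#: Concentration floor (M) that keeps relative residuals well defined
#: when a component total is zero.
EPS = 1e-30


class SpeciationError(RuntimeError):
    """Raised when the mass-balance solver cannot reach tolerance."""


def _check_conc(value: float, what: str) -> float:
    value = float(value)
    if math.isnan(value) or math.isinf(value):
        raise ValueError(f"{what} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{what} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class Component:
    """A conserved chemical species with a total (analytic) concentration."""

    name: str
    total: float  # M

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("component name must be non-empty")
        object.__setattr__(self, "total", _check_conc(self.total, f"total of {self.name!r}"))


@dataclass(frozen=True)
class ComplexSpecies:
    """A bound state defined by integer stoichiometry over components.

    ``k_overall`` is the overall dissociation constant:
    ``[complex] = prod_i [free_i]**nu_i / k_overall``.
    """

    name: str
    composition: Mapping[str, int]
    k_overall: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("complex name must be non-empty")
        comp = dict(self.composition)
        if not comp:
            raise ValueError(f"complex {self.name!r} has empty composition")
        for cname, nu in comp.items():
            if int(nu) != nu or nu < 1:
                raise ValueError(
                    f"stoichiometry of {cname!r} in {self.name!r} must be an integer >= 1"
                )
        if sum(comp.values()) < 2:
            raise ValueError(f"complex {self.name!r} must contain at least two subunits")
        k = float(self.k_overall)
        if not (k > 0) or math.isinf(k) or math.isnan(k):
            raise ValueError(f"k_overall of {self.name!r} must be positive and finite")
        object.__setattr__(self, "composition", comp)
        object.__setattr__(self, "k_overall", k)


@dataclass(frozen=True)
class Scheme:
    """A full binding mechanism: components plus complexes."""

    components: tuple[Component, ...]
    complexes: tuple[ComplexSpecies, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        cplxs = tuple(self.complexes)
        if not comps:
            raise ValueError("scheme needs at least one component")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        cnames = [c.name for c in cplxs]
        if len(set(cnames)) != len(cnames) or set(cnames) & set(names):
            raise ValueError("complex names must be unique and distinct from components")
        for cx in cplxs:
            unknown = set(cx.composition) - set(names)
            if unknown:
                raise ValueError(f"complex {cx.name!r} references undeclared components {unknown}")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "complexes", cplxs)

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def totals(self) -> np.ndarray:
        return np.array([c.total for c in self.components], dtype=float)

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_components, n_complexes) integer stoichiometry matrix."""
        idx = {c.name: i for i, c in enumerate(self.components)}
        nu = np.zeros((len(self.components), len(self.complexes)))
        for j, cx in enumerate(self.complexes):
            for cname, n in cx.composition.items():
                nu[idx[cname], j] = n
        return nu

    def to_dict(self) -> dict:
        return {
            "components": [{"name": c.name, "total_M": c.total} for c in self.components],
            "complexes": [
                {"name": cx.name, "composition": dict(cx.composition), "k_overall": cx.k_overall}
                for cx in self.complexes
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Scheme":
        comps = tuple(Component(d["name"], d["total_M"]) for d in doc["components"])
        cplxs = tuple(
            ComplexSpecies(d["name"], d["composition"], d["k_overall"])
            for d in doc.get("complexes", [])
        )
        return cls(comps, cplxs)


@dataclass
class SpeciationResult:
    """Solved free/complex concentrations plus the worst mass-balance residual."""

    free: dict[str, float]
    complexed: dict[str, float]
    residual: float

    def bound_total(self, component: str, scheme: Scheme) -> float:
        """Total concentration of ``component`` tied up in complexes."""
        out = 0.0
        for cx in scheme.complexes:
            nu = cx.composition.get(component, 0)
            if nu:
                out += nu * self.complexed[cx.name]
        return out


def _complex_concs(log_free: np.ndarray, nu: np.ndarray, log_k: np.ndarray) -> np.ndarray:
    return np.exp(nu.T @ log_free - log_k)


def _residuals(log_free: np.ndarray, totals: np.ndarray, nu: np.ndarray, log_k: np.ndarray) -> np.ndarray:
    free = np.exp(log_free)
    cplx = _complex_concs(log_free, nu, log_k)
    balance = free + nu @ cplx
    return (balance - totals) / np.maximum(totals, EPS)


def solve_speciation(scheme: Scheme, rel_tol: float = 1e-9) -> SpeciationResult:
    """Solve the coupled mass balances of ``scheme``.

    Free concentrations are solved on a log scale (positivity by
    construction), initialised at ``free = total``, via a hybrid
    Powell root find with a damped successive-substitution fallback.

    Parameters
    ----------
    scheme : Scheme
    rel_tol : float
        Maximum allowed relative mass-balance violation, in (0, 1e-3].

    Raises
    ------
    SpeciationError
        If the residual cannot be brought below ``rel_tol``; the message
        names the component with the worst residual.
    """
    if not (0 < rel_tol <= 1e-3):
        raise ValueError("rel_tol must be in (0, 1e-3]")

    totals_all = scheme.totals()
    names = scheme.component_names

    active = totals_all > 0.0
    # Complexes containing any zero-total component cannot form.
    active_cplx = [
        cx for cx in scheme.complexes
        if all(totals_all[names.index(c)] > 0 for c in cx.composition)
    ]

    free = {n: 0.0 for n in names}
    complexed = {cx.name: 0.0 for cx in scheme.complexes}

    if not active.any():
        return SpeciationResult(free, complexed, 0.0)

    sub = Scheme(
        tuple(c for c in scheme.components if c.total > 0),
        tuple(active_cplx),
    )
    totals = sub.totals()
    nu = sub.stoichiometry_matrix()
    log_k = np.log(np.array([cx.k_overall for cx in sub.complexes])) if sub.complexes else np.zeros(0)

    x0 = np.log(totals)
    if sub.complexes:
        sol = optimize.root(_residuals, x0, args=(totals, nu, log_k), method="hybr", tol=1e-13)
        x = sol.x
        if np.max(np.abs(_residuals(x, totals, nu, log_k))) > rel_tol:
            x = _damped_fixed_point(x0, totals, nu, log_k)
            sol = optimize.root(_residuals, x, args=(totals, nu, log_k), method="hybr", tol=1e-13)
            if np.max(np.abs(_residuals(sol.x, totals, nu, log_k))) <= np.max(
                np.abs(_residuals(x, totals, nu, log_k))
            ):
                x = sol.x
    else:
        x = x0

    res = np.abs(_residuals(x, totals, nu, log_k)) if sub.complexes else np.zeros_like(x)
    worst = float(res.max()) if res.size else 0.0
    if worst > rel_tol:
        bad = sub.component_names[int(np.argmax(res))]
        raise SpeciationError(
            f"speciation solver did not converge: component {bad!r} has relative "
            f"mass-balance residual {worst:.3e} > rel_tol {rel_tol:.1e}"
        )

    free_active = np.exp(x)
    cplx_active = _complex_concs(x, nu, log_k) if sub.complexes else np.zeros(0)
    for n, f in zip(sub.component_names, free_active):
        free[n] = float(f)
    for cx, v in zip(sub.complexes, cplx_active):
        complexed[cx.name] = float(v)
    return SpeciationResult(free, complexed, worst)


def _damped_fixed_point(
    x0: np.ndarray, totals: np.ndarray, nu: np.ndarray, log_k: np.ndarray, n_iter: int = 2000
) -> np.ndarray:
    """Successive substitution on log-free with geometric damping.

    ``free_i <- total_i * free_i / (free_i + bound_i)`` is a contraction
    for these dilute schemes; used only when the root find stalls.
    """
    x = x0.copy()
    for _ in range(n_iter):
        free = np.exp(x)
        bound = nu @ _complex_concs(x, nu, log_k)
        x_new = np.log(totals * free / np.maximum(free + bound, EPS))
        x = 0.5 * (x + x_new)
        if np.max(np.abs(x_new - x)) < 1e-14:
            break
    return x


def closed_form_single_site(k: float, p_tot: float, d_tot: float) -> float:
    """Bound-complex concentration for 1:1 binding P + D <=> PD.

    The physically admissible root of
    ``[PD]^2 - (K + P_tot + D_tot)[PD] + P_tot*D_tot = 0`` in
    ``[0, min(P_tot, D_tot)]``.  Used as an independent oracle for the
    general solver.
    """
    if not (k > 0):
        raise ValueError("k must be > 0")
    p_tot = _check_conc(p_tot, "p_tot")
    d_tot = _check_conc(d_tot, "d_tot")
    s = k + p_tot + d_tot
    # Numerically stable smaller quadratic root.
    disc = math.sqrt(max(s * s - 4.0 * p_tot * d_tot, 0.0))
    bound = 2.0 * p_tot * d_tot / (s + disc)
    return min(max(bound, 0.0), min(p_tot, d_tot))


def build_two_tetramer_scheme(
    k_dna: float,
    probe_total: float,
    monomer_total: float,
    explicit_assembly: bool = False,
    k_assembly: float = 1e-60,
) -> Scheme:
    """Scheme for two non-dissociable tetramers binding one DNA probe.

    Both tetramers bind with equal stepwise macroscopic affinity
    ``K1 = K2 = k_dna`` (no statistical factors), so the doubly bound
    complex has overall constant ``k_dna**2``.  Protein enters as
    monomer total concentration; the non-dissociable-tetramer
    convention is realised by dividing by four and treating the
    tetramer as an elementary component.

    With ``explicit_assembly=True`` the monomer is kept as the
    component and the tetramer appears as a complex ``4M <=> T`` with
    overall dissociation constant ``k_assembly`` (M^3), small enough by
    default that assembly is quantitative; this mode exists only to
    cross-check the reduced formulation.
    """
    if not (k_dna > 0):
        raise ValueError("k_dna must be > 0")
    probe_total = _check_conc(probe_total, "probe_total")
    monomer_total = _check_conc(monomer_total, "monomer_total")

    if explicit_assembly:
        return Scheme(
            (
                Component("monomer", monomer_total),
                Component("probe", probe_total),
            ),
            (
                ComplexSpecies("tetramer", {"monomer": 4}, k_assembly),
                ComplexSpecies("TD", {"monomer": 4, "probe": 1}, k_assembly * k_dna),
                ComplexSpecies("T2D", {"monomer": 8, "probe": 1}, (k_assembly * k_dna) ** 2),
            ),
        )

    return Scheme(
        (
            Component("tetramer", monomer_total / 4.0),
            Component("probe", probe_total),
        ),
        (
            ComplexSpecies("TD", {"tetramer": 1, "probe": 1}, k_dna),
            ComplexSpecies("T2D", {"tetramer": 2, "probe": 1}, k_dna**2),
        ),
    )
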