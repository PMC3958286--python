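"""Physical model of a mediated amperometric glucose biosensor.

The sensor is a sandwich of four planar layers stacked on the working
electrode: an enzyme layer (soluble PQQ-dependent glucose dehydrogenase,
immobile), a polyvinyl-alcohol (PVA) film, a terylene membrane, and a
Nernst diffusion layer beyond which convection pins every concentration
to its bulk value.

Six species are modelled.  The two enzyme forms ``e_ox``/``e_red`` exist
only in the enzyme layer and do not diffuse.  Substrate (glucose) ``s``,
the two mediator forms ``m_ox``/``m_red`` (N-methylphenazonium methyl
sulfate, PMS) and dissolved oxygen ``o`` diffuse through all four layers
with layer-specific diffusivities.  Mass-action kinetics:

    E_ox + S   --k1-->  E_red + P1      (enzyme layer only)
    E_red + M_ox --k2-->  E_ox + M_red  (enzyme layer only)
    M_red + O2 --k3-->  M_ox + P2       (all layers)
    M_red      --electrode-->  M_ox + n_e e-   (x = 0, infinitely fast)

Products P1 (gluconolactone) and P2 (HO2-) feed back into nothing and
are not tracked.  All quantities are strict SI: m, s, mol/m^3, A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "FARADAY",
    "C_O2_WATER",
    "Species",
    "MOBILE_SPECIES",
    "ENZYME_SPECIES",
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "validate_parameters",
    "reaction_terms",
]

#: Faraday constant, C/mol.
FARADAY = 96486.0

#: Reference dissolved-oxygen concentration of the aerobic runs, mol/m^3.
C_O2_WATER = 2.53e-7


class Species(str, Enum):
    """The six modelled concentration fields."""

    E_OX = "e_ox"
    E_RED = "e_red"
    S = "s"
    M_OX = "m_ox"
    M_RED = "m_red"
    O = "o"


#: Species that diffuse and are defined on all four layers.
MOBILE_SPECIES = (Species.S, Species.M_OX, Species.M_RED, Species.O)

#: Immobile enzyme forms, defined on the enzyme layer only.
ENZYME_SPECIES = (Species.E_OX, Species.E_RED)


class ParameterError(ValueError):
    """A model parameter violates its physical invariant."""


def _as_layer_array(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (4,):
        raise ParameterError(f"{name} must have one value per layer (4), got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ModelParameters:
    """Geometry, transport and kinetic constants of the biosensor.

    Layer order is electrode-outward: 1 enzyme, 2 PVA, 3 terylene,
    4 Nernst diffusion layer.  Per-layer quantities are length-4 arrays
    in that order.

    Attributes
    ----------
    d1, d2, d3, d4:
        Layer thicknesses, m.
    D_S, D_Mox, D_Mred, D_O2:
        Per-layer diffusion coefficients, m^2/s.
    k1:
        Rate constant of enzyme reduction by substrate, m^3 mol^-1 s^-1.
    k2:
        Rate constant of enzyme reoxidation by oxidized mediator,
        m^3 mol^-1 s^-1.
    k3:
        Rate constant of reduced-mediator oxidation by O2,
        m^3 mol^-1 s^-1.
    e0:
        Total enzyme concentration in the enzyme layer, mol/m^3.
    s0, m0, o0:
        Bulk substrate / oxidized-mediator / oxygen concentrations,
        mol/m^3.  ``o0`` defaults to :data:`C_O2_WATER`; set it to 0 for
        anaerobic runs.
    A:
        Electrode area, m^2.
    n_e:
        Electrons transferred per mediator molecule at the electrode.
    F:
        Faraday constant, C/mol.
    """

    d1: float = 5e-6
    d2: float = 1e-6
    d3: float = 1.2e-5
    d4: float = 1.5e-4
    D_S: np.ndarray = field(
        default_factory=lambda: np.array([1.5e-10, 4.2e-10, 3.75e-10, 6.77e-10])
    )
    D_Mox: np.ndarray = field(
        default_factory=lambda: np.array([1.5e-10, 4.2e-10, 3.75e-10, 4.57e-10])
    )
    D_Mred: np.ndarray = field(
        default_factory=lambda: np.array([1.5e-10, 4.2e-10, 3.75e-10, 4.57e-10])
    )
    D_O2: np.ndarray = field(
        default_factory=lambda: np.array([1.970e-9, 1.970e-9, 1.970e-9, 1.970e-9])
    )
    k1: float = 8.1e2
    k2: float = 6.7e4
    k3: float = 1.8e-1
    e0: float = 1e-3
    s0: float = 4.98
    m0: float = 5e-2
    o0: float = C_O2_WATER
    A: float = 4.5e-6
    n_e: int = 2
    F: float = FARADAY

    def __post_init__(self):
        for name in ("D_S", "D_Mox", "D_Mred", "D_O2"):
            object.__setattr__(self, name, _as_layer_array(name, getattr(self, name)))

    @property
    def thicknesses(self) -> np.ndarray:
        """Layer thicknesses ``[d1, d2, d3, d4]``, m."""
        return np.array([self.d1, self.d2, self.d3, self.d4])

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative layer boundaries ``[a0, a1, a2, a3, a4]``, m.

        ``a0 = 0`` is the electrode surface; ``a4`` the edge of the
        Nernst diffusion layer, beyond which the bulk is well stirred.
        """
        return np.concatenate(([0.0], np.cumsum(self.thicknesses)))

    def diffusivity(self, species: Species) -> np.ndarray:
        """Per-layer diffusivity of a mobile species, m^2/s."""
        try:
            return {
                Species.S: self.D_S,
                Species.M_OX: self.D_Mox,
                Species.M_RED: self.D_Mred,
                Species.O: self.D_O2,
            }[Species(species)]
        except KeyError:
            raise ParameterError(f"{species} is not a mobile species") from None

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced and revalidated."""
        return validate_parameters(replace(self, **changes))


def default_parameters() -> ModelParameters:
    """The reference parameter set of the modelled sensor (aerobic)."""
    return validate_parameters(ModelParameters())


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Check every physical invariant of *p*; return *p* unchanged.

    Raises
    ------
    ParameterError
        Naming the offending field: non-positive thickness, diffusivity
        or electrode area; negative rate constant or concentration;
        ``n_e < 1``.
    """
    for name in ("d1", "d2", "d3", "d4"):
        if not getattr(p, name) > 0:
            raise ParameterError(f"non-positive thickness: {name} = {getattr(p, name)!r}")
    for name in ("D_S", "D_Mox", "D_Mred", "D_O2"):
        arr = getattr(p, name)
        if not np.all(arr > 0) or not np.all(np.isfinite(arr)):
            raise ParameterError(f"non-positive diffusivity in {name} = {arr!r}")
    if not p.A > 0:
        raise ParameterError(f"non-positive electrode area: A = {p.A!r}")
    for name in ("k1", "k2", "k3"):
        if getattr(p, name) < 0:
            raise ParameterError(f"negative rate constant: {name} = {getattr(p, name)!r}")
    for name in ("e0", "s0", "m0", "o0"):
        if getattr(p, name) < 0:
            raise ParameterError(f"negative concentration: {name} = {getattr(p, name)!r}")
    if int(p.n_e) != p.n_e or p.n_e < 1:
        raise ParameterError(f"n_e must be a positive integer, got {p.n_e!r}")
    if not p.F > 0:
        raise ParameterError(f"non-positive Faraday constant: F = {p.F!r}")
    a = p.boundaries
    if not np.all(np.diff(a) > 0):
        raise ParameterError(f"layer boundaries not strictly increasing: {a!r}")
    return p


def reaction_terms(
    c: Mapping[Species | str, float], layer_index: int, p: ModelParameters
) -> dict[Species, float]:
    """Pointwise net mass-action reaction rates, mol m^-3 s^-1.

    Parameters
    ----------
    c:
        Concentrations at one spatial point, keyed by species.  In
        layers 2-4 the enzyme entries may be omitted.
    layer_index:
        1 (enzyme), 2 (PVA), 3 (terylene) or 4 (diffusion layer).
    p:
        Model parameters supplying k1, k2, k3.

    Returns
    -------
    dict
        Net rate per species.  In the enzyme layer all six species are
        returned; in layers 2-4 only the mobile ones (the substrate rate
        is 0 there, and only mediator oxidation by O2 proceeds).
    """
    if layer_index not in (1, 2, 3, 4):
        raise ValueError(f"layer_index must be 1..4, got {layer_index!r}")
    cc = {Species(k): float(v) for k, v in c.items()}
    m_red = cc.get(Species.M_RED, 0.0)
    o = cc.get(Species.O, 0.0)
    r3 = p.k3 * m_red * o
    if layer_index == 1:
        e_ox = cc.get(Species.E_OX, 0.0)
        e_red = cc.get(Species.E_RED, 0.0)
        s = cc.get(Species.S, 0.0)
        m_ox = cc.get(Species.M_OX, 0.0)
        r1 = p.k1 * e_ox * s
        r2 = p.k2 * e_red * m_ox
        return {
            Species.E_OX: -r1 + r2,
            Species.E_RED: r1 - r2,
            Species.S: -r1,
            Species.M_OX: -r2 + r3,
            Species.M_RED: r2 - r3,
            Species.O: -r3,
        }
    return {
        Species.S: 0.0,
        Species.M_OX: r3,
        Species.M_RED: -r3,
        Species.O: -r3,
    }
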