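"""Closed-form membrane physics for tethered-antigen mobility.

A particle tethered to a supported lipid bilayer diffuses at a rate set by
the bilayer's surface viscosity ``eta_m = eta_mb * h`` (bulk viscosity times
bilayer thickness).  For perturbations on the scale of a single lipid the
diffusion coefficient follows a Stokes-Einstein-like form

    D = kB * T * lambda / (4 * pi * eta_m * R)

where ``lambda`` is the characteristic membrane-perturbation length
(~0.5 nm, one lipid) and ``R`` the radius of the diffusing inclusion
(~1 nm, two lipids, for a doubly-biotinylated tether through a streptavidin).
This simplified form deliberately omits the logarithmic size dependence of
the full Saffman-Delbrueck treatment.

Two bilayer compositions bracket the physiological mobility range:
DOPC (fluid phase, eta_m = 8.4e-11 Pa s m) and DPPC (gel phase,
eta_m = 3.0e-9 Pa s m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BOLTZMANN_CONSTANT",
    "MembraneSpec",
    "DOPC",
    "DPPC",
    "surface_viscosity",
    "predict_diffusion_coefficient",
    "viscosity_fold_change",
    "epitope_density",
]

#: Boltzmann constant, J/K (exact, SI 2019).
BOLTZMANN_CONSTANT = 1.380649e-23


@dataclass(frozen=True)
class MembraneSpec:
    """Physical parameters of a supported lipid bilayer and its cargo.

    Parameters
    ----------
    name
        Label for the lipid composition, e.g. ``"DOPC"``.
    eta_m
        Surface viscosity, Pa s m.  Equals ``eta_mb * h`` when the bulk
        viscosity and thickness are supplied.
    temperature
        Absolute temperature, K.
    lam
        Membrane-perturbation length, m (default 0.5 nm, one lipid).
    radius
        Radius of the diffusing inclusion, m (default 1 nm, two lipids).
    eta_mb, h
        Optional bulk viscosity (Pa s) and bilayer thickness (m); when both
        are given they must be consistent with ``eta_m``.
    """

    name: str
    eta_m: float
    temperature: float = 298.0
    lam: float = 0.5e-9
    radius: float = 1.0e-9
    eta_mb: float | None = None
    h: float | None = None
    kB: float = field(default=BOLTZMANN_CONSTANT, repr=False)

    def __post_init__(self) -> None:
        for attr in ("eta_m", "temperature", "lam", "radius"):
            value = getattr(self, attr)
            if not (value > 0):
                raise ValueError(f"{attr} must be positive, got {value!r}")
        if self.eta_mb is not None and self.h is not None:
            if not math.isclose(self.eta_m, self.eta_mb * self.h, rel_tol=1e-12):
                raise ValueError(
                    "inconsistent spec: eta_m != eta_mb * h "
                    f"({self.eta_m!r} != {self.eta_mb * self.h!r})"
                )

    @classmethod
    def from_bulk(
        cls,
        name: str,
        eta_mb: float,
        h: float,
        **kwargs,
    ) -> "MembraneSpec":
        """Build a spec from bulk viscosity and bilayer thickness."""
        return cls(name=name, eta_m=surface_viscosity(eta_mb, h), eta_mb=eta_mb, h=h, **kwargs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "eta_m": self.eta_m,
            "temperature": self.temperature,
            "lam": self.lam,
            "radius": self.radius,
            "eta_mb": self.eta_mb,
            "h": self.h,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneSpec":
        return cls(**{k: v for k, v in d.items() if v is not None})


def surface_viscosity(eta_mb: float, h: float) -> float:
    """Surface viscosity ``eta_m = eta_mb * h`` in Pa s m.

    ``eta_mb`` is the bulk viscosity of the bilayer (Pa s) and ``h`` its
    thickness (m).
    """
    if not (eta_mb > 0 and h > 0):
        raise ValueError("eta_mb and h must be positive")
    return eta_mb * h


def predict_diffusion_coefficient(spec: MembraneSpec) -> float:
    """Predicted diffusion coefficient D = kB T lambda / (4 pi eta_m R).

    Returns
    -------
    float
        D in um^2/s (the SI result in m^2/s scaled by 1e12).
    """
    d_si = spec.kB * spec.temperature * spec.lam / (4.0 * math.pi * spec.eta_m * spec.radius)
    return d_si * 1e12


def viscosity_fold_change(spec_a: MembraneSpec, spec_b: MembraneSpec) -> float:
    """Fold change in surface viscosity eta_m(b) / eta_m(a).

    Under the closed form the implied fold *decrease* in D is the same
    number, since D is inversely proportional to eta_m.
    """
    if not (spec_a.eta_m > 0 and spec_b.eta_m > 0):
        raise ValueError("surface viscosities must be positive")
    return spec_b.eta_m / spec_a.eta_m


def epitope_density(construct_density: float, epitopes_per_construct: float) -> float:
    """Epitopes per um^2 given a construct surface density and valency.

    Examples: 3,000 trivalent antigen-DNA constructs/um^2 present
    9,000 hapten epitopes/um^2; 300 receptors/um^2 each holding a
    10-trimer particle present 9,000 epitopes/um^2.
    """
    if construct_density < 0 or epitopes_per_construct < 0:
        raise ValueError("densities must be non-negative")
    return construct_density * epitopes_per_construct


#: Fluid-phase reference bilayer (thickness 5.9 nm).
DOPC = MembraneSpec.from_bulk("DOPC", eta_mb=8.4e-11 / 5.9e-9, h=5.9e-9)

#: Gel-phase reference bilayer (thickness 6.3 nm).
DPPC = MembraneSpec.from_bulk("DPPC", eta_mb=3.0e-9 / 6.3e-9, h=6.3e-9)
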