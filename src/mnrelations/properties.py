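"""Registry of motoneuron (MN) and muscle-unit (mU) properties.

Every property handled by the pipeline is registered here with its SI base
unit, its role (MN or mU side of the motor unit) and its orientation with
respect to motoneuron size: +1 for properties that grow with MN size (ACV,
capacitance, rheobase, the size indices themselves), -1 for properties that
shrink with it (input resistance, specific resistivity, time constant, AHP
duration).

``S_MN`` and ``S_mU`` are conceptual sizes: they are never stored as measured
columns but are represented by linearly related, measurable size indices
(soma diameter / neuron surface area on the MN side; tetanic and twitch
force, innervation ratio and fibre cross-sectional areas on the mU side).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PropertyName:
    """One property with its semantic metadata."""

    name: str
    role: str              # "MN" | "mU"
    si_unit: str
    orientation: int       # +1 increases with size, -1 decreases, 0 n/a
    is_size_index: bool = False
    abstract: bool = False  # conceptual size, never a measured column

    def __post_init__(self) -> None:
        if self.role not in ("MN", "mU"):
            raise ValueError(f"invalid role {self.role!r}")
        if self.orientation not in (-1, 0, 1):
            raise ValueError("orientation must be -1, 0 or +1")


_MN = "MN"
_MU = "mU"

PROPERTIES: dict[str, PropertyName] = {
    p.name: p
    for p in [
        # conceptual MN size (normalized pipeline reference; dimensionless
        # percent space, measured through D_soma or S_neuron)
        PropertyName("S_MN", _MN, "1", +1, is_size_index=True, abstract=True),
        PropertyName("S_neuron", _MN, "m^2", +1, is_size_index=True),
        PropertyName("D_soma", _MN, "m", +1, is_size_index=True),
        PropertyName("ACV", _MN, "m/s", +1),
        PropertyName("AHP", _MN, "s", -1),
        PropertyName("R", _MN, "ohm", -1),
        PropertyName("R_m", _MN, "ohm*m^2", -1),
        PropertyName("I_th", _MN, "A", +1),
        PropertyName("C", _MN, "F", +1),
        PropertyName("C_m", _MN, "F/m^2", 0),
        PropertyName("tau", _MN, "s", -1),
        PropertyName("dV_th", _MN, "V", 0),
        # mU size indices (all linearly related to S_mU)
        PropertyName("S_mU", _MU, "m^2", +1, is_size_index=True, abstract=True),
        PropertyName("F_tet", _MU, "N", +1, is_size_index=True),
        PropertyName("F_tw", _MU, "N", +1, is_size_index=True),
        PropertyName("IR", _MU, "1", +1, is_size_index=True),
        PropertyName("CSA_mean", _MU, "m^2", +1, is_size_index=True),
        PropertyName("CSA_tot", _MU, "m^2", +1, is_size_index=True),
    ]
}

SPECIES = ("cat", "rat", "mouse")

# Accepted input units -> (SI unit, multiplicative factor to SI).
UNIT_FACTORS: dict[str, tuple[str, float]] = {
    # length
    "m": ("m", 1.0),
    "um": ("m", 1e-6),
    "µm": ("m", 1e-6),
    # area
    "m^2": ("m^2", 1.0),
    "m2": ("m^2", 1.0),
    "mm^2": ("m^2", 1e-6),
    "mm2": ("m^2", 1e-6),
    "um^2": ("m^2", 1e-12),
    "um2": ("m^2", 1e-12),
    # resistance
    "ohm": ("ohm", 1.0),
    "Ohm": ("ohm", 1.0),
    "MOhm": ("ohm", 1e6),
    "MΩ": ("ohm", 1e6),
    # current
    "A": ("A", 1.0),
    "nA": ("A", 1e-9),
    # time
    "s": ("s", 1.0),
    "ms": ("s", 1e-3),
    # capacitance
    "F": ("F", 1.0),
    "nF": ("F", 1e-9),
    # velocity
    "m/s": ("m/s", 1.0),
    # specific membrane quantities
    "ohm*m^2": ("ohm*m^2", 1.0),
    "F/m^2": ("F/m^2", 1.0),
    # voltage
    "V": ("V", 1.0),
    "mV": ("V", 1e-3),
    # force
    "N": ("N", 1.0),
    "mN": ("N", 1e-3),
    # dimensionless (counts, percent space)
    "1": ("1", 1.0),
    "": ("1", 1.0),
    "percent": ("1", 1.0),
}


class UnknownPropertyError(KeyError):
    """Raised for a property name absent from the registry."""


def get_property(name: str) -> PropertyName:
    try:
        return PROPERTIES[name]
    except KeyError:
        raise UnknownPropertyError(
            f"unknown property {name!r}; known: {sorted(PROPERTIES)}"
        ) from None


def to_si(value: float, unit: str, prop: str | None = None) -> float:
    """Convert ``value`` expressed in ``unit`` to SI base units.

    If ``prop`` is given, the unit's SI target is checked against the
    property's registered unit (dimensionless pipeline columns are exempt).
    """
    try:
        si_unit, factor = UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}") from None
    if prop is not None:
        registered = get_property(prop).si_unit
        if registered not in ("1",) and si_unit not in (registered, "1"):
            raise ValueError(
                f"unit {unit!r} (SI {si_unit}) incompatible with "
                f"{prop} [{registered}]"
            )
    return value * factor
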