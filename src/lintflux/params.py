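"""Physical parameter set of the lint-transport model.

All internal values are strict SI (m, s, kg, Pa, N). Config files are flat
YAML key/value documents whose values may carry a unit suffix (``"0.1 kPa"``,
``"10 cm"``, ``"1 hr"``); they are converted to SI on load. Defaults follow
the tabulated nominal values of the analysis, with the three quantities the
table omits (the tip-to-root hair-lint friction coefficient, the shirt-lint
friction coefficient, and the abdominal radius of curvature) set from the
literature values quoted alongside it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "FiberGeometry", "FrictionSet", "GarmentSkin", "TransportParams",
    "ModelParams", "default_params", "load_params", "save_params",
    "parse_quantity",
]


class ParameterError(ValueError):
    """A parameter violates a physical bound or a config key is unknown."""


# unit suffix -> factor to SI.  Dimension checking is intentionally out of
# scope: each field is documented with its expected dimension and the factor
# table covers the units a config for this model plausibly uses.
_UNIT_FACTORS: dict[str, float] = {
    # length
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6,
    # time
    "s": 1.0, "min": 60.0, "hr": 3600.0, "h": 3600.0,
    # pressure
    "Pa": 1.0, "kPa": 1e3, "hPa": 1e2, "MPa": 1e6,
    # density of matter
    "kg/m^3": 1.0, "kg/m3": 1.0, "g/cm^3": 1e3, "g/cm3": 1e3,
    # dynamic viscosity
    "Pa.s": 1.0, "Pa*s": 1.0, "Pa s": 1.0, "N.s/m^2": 1.0, "Ns/m^2": 1.0, "Ns/m2": 1.0,
    # line tension
    "N/m": 1.0, "mN/m": 1e-3,
    # linear number density / source rate
    "1/m": 1.0, "/m": 1.0, "1/cm": 1e2,
    "1/m/s": 1.0, "1/(m.s)": 1.0, "1/(m s)": 1.0,
}


def parse_quantity(value: Any) -> float:
    """Convert a config value to an SI float.

    Accepts plain numbers (already SI) or strings of the form
    ``"<number> <unit>"`` / ``"<number><unit>"`` with a unit from the
    supported table.
    """
    if isinstance(value, bool):
        raise ParameterError(f"expected a number, got boolean {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        text = value.strip()
        try:
            return float(text)
        except ValueError:
            pass
        # split a trailing unit off the numeric part
        for i in range(len(text), 0, -1):
            head, tail = text[:i].strip(), text[i:].strip()
            try:
                number = float(head)
            except ValueError:
                continue
            if tail in _UNIT_FACTORS:
                return number * _UNIT_FACTORS[tail]
            raise ParameterError(f"unknown unit {tail!r} in {value!r}")
    raise ParameterError(f"cannot interpret {value!r} as a quantity")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class FiberGeometry:
    """Lint fiber geometry: width ``d`` (m), length ``l`` (m), density ``rho`` (kg/m^3).

    Fibers are slender (d < l); the nominal fiber is a 10 µm wide, 1 mm long
    cotton filament at 450 kg/m^3.
    """

    d: float = 1e-5
    l: float = 1e-3
    rho: float = 450.0

    def __post_init__(self) -> None:
        _require(self.d > 0, f"fiber width d must be > 0, got {self.d}")
        _require(self.l > 0, f"fiber length l must be > 0, got {self.l}")
        _require(self.rho > 0, f"fiber density rho must be > 0, got {self.rho}")
        _require(self.d < self.l, f"fibers are slender: need d < l, got d={self.d}, l={self.l}")


@dataclass(frozen=True)
class FrictionSet:
    """Kinetic friction coefficients of the shirt-lint-hair sandwich.

    ``mu_HL_plus`` / ``mu_HL_minus`` are hair-lint friction in the root-to-tip
    and tip-to-root directions; the cuticle-scale ratchet makes the latter
    larger. ``mu_SL`` (shirt-lint) must exceed ``mu_HL_plus`` so that the
    shirt can drag the fiber forward during exhale.
    """

    mu_SL: float = 0.3
    mu_HL_plus: float = 0.1
    mu_HL_minus: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mu_SL", "mu_HL_plus", "mu_HL_minus"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(
            self.mu_HL_minus >= self.mu_HL_plus,
            "directional asymmetry requires mu_HL_minus >= mu_HL_plus "
            f"(got {self.mu_HL_minus} < {self.mu_HL_plus})",
        )
        _require(
            self.mu_SL > self.mu_HL_plus,
            "forward sliding requires mu_SL > mu_HL_plus "
            f"(got mu_SL={self.mu_SL}, mu_HL_plus={self.mu_HL_plus})",
        )


@dataclass(frozen=True)
class GarmentSkin:
    """Garment/skin contact: skin pressure ``p`` (Pa), abdominal radius of
    curvature ``R`` (m), real-contact-area fraction ``alpha``, air viscosity
    ``eta`` (Pa s)."""

    p: float = 100.0
    R: float = 0.47
    alpha: float = 1e-5
    eta: float = 1.84e-5

    def __post_init__(self) -> None:
        _require(self.p > 0, f"skin pressure p must be > 0, got {self.p}")
        _require(self.R > 0, f"radius of curvature R must be > 0, got {self.R}")
        _require(0 < self.alpha <= 1, f"contact fraction alpha must be in (0, 1], got {self.alpha}")
        _require(self.eta > 0, f"air viscosity eta must be > 0, got {self.eta}")


@dataclass(frozen=True)
class TransportParams:
    """Transport-equation inputs: domain length ``L`` (m, navel at x = L),
    breathing period ``T`` (s), constant source rate ``A`` (fibers/m/s) and
    the constant initial density level ``n0_level`` (fibers/m)."""

    L: float = 0.1
    T: float = 6.0
    A: float = 1.0
    n0_level: float = 100.0

    def __post_init__(self) -> None:
        _require(self.L > 0, f"domain length L must be > 0, got {self.L}")
        _require(self.T > 0, f"breathing period T must be > 0, got {self.T}")
        _require(self.A >= 0, f"source rate A must be >= 0, got {self.A}")
        _require(self.n0_level >= 0, f"initial density n0_level must be >= 0, got {self.n0_level}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the model, in SI units."""

    geometry: FiberGeometry = field(default_factory=FiberGeometry)
    friction: FrictionSet = field(default_factory=FrictionSet)
    garment: GarmentSkin = field(default_factory=GarmentSkin)
    transport: TransportParams = field(default_factory=TransportParams)

    def to_flat_dict(self) -> dict[str, float]:
        """Flat {field-name: SI value} mapping (the config-file schema)."""
        out: dict[str, float] = {}
        for group in (self.geometry, self.friction, self.garment, self.transport):
            for f in dataclasses.fields(group):
                out[f.name] = getattr(group, f.name)
        return out

    def replace(self, **kwargs: float) -> "ModelParams":
        """Return a copy with flat fields replaced (e.g. ``replace(p=200.0)``)."""
        merged = self.to_flat_dict()
        for key, value in kwargs.items():
            if key not in merged:
                raise ParameterError(f"unknown parameter {key!r}")
            merged[key] = float(value)
        return _from_flat(merged)


_FIELD_GROUPS = {
    "geometry": ("d", "l", "rho"),
    "friction": ("mu_SL", "mu_HL_plus", "mu_HL_minus"),
    "garment": ("p", "R", "alpha", "eta"),
    "transport": ("L", "T", "A", "n0_level"),
}


def _from_flat(flat: Mapping[str, float]) -> ModelParams:
    groups = {}
    for group, names in _FIELD_GROUPS.items():
        groups[group] = {name: flat[name] for name in names}
    return ModelParams(
        geometry=FiberGeometry(**groups["geometry"]),
        friction=FrictionSet(**groups["friction"]),
        garment=GarmentSkin(**groups["garment"]),
        transport=TransportParams(**groups["transport"]),
    )


def default_params() -> ModelParams:
    """The nominal parameter set of the analysis, in SI units.

    A = 1 fibers/m/s, d = 1e-5 m, l = 1e-3 m, L = 0.1 m, n0 = 100 /m,
    p = 100 Pa, T = 6 s, alpha = 1e-5, eta = 1.84e-5 Pa s, mu_HL+ = 0.1,
    rho = 450 kg/m^3; plus mu_HL- = 2 mu_HL+ = 0.2, mu_SL = 0.3, R = 0.47 m.
    """
    return ModelParams()


def load_params(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> ModelParams:
    """Load a parameter set: defaults, updated by a config file, updated by overrides.

    Parameters
    ----------
    path:
        Flat YAML file; keys are the flat field names, values numbers (SI)
        or strings with a unit suffix. ``None`` or an empty file yields the
        defaults.
    overrides:
        Final key/value overrides (e.g. from CLI flags), same value syntax.

    Raises
    ------
    FileNotFoundError
        If *path* is given but does not exist.
    ParameterError
        On unknown keys, malformed values, or violated physical bounds.
    """
    flat = default_params().to_flat_dict()

    def merge(mapping: Mapping[str, Any], origin: str) -> None:
        for key, value in mapping.items():
            if key not in flat:
                raise ParameterError(f"unknown parameter {key!r} in {origin}")
            flat[key] = parse_quantity(value)

    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ParameterError(f"config file {path} must be a flat key/value mapping")
        merge(loaded, str(path))
    if overrides:
        merge(overrides, "overrides")
    return _from_flat(flat)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write the resolved SI parameter set as a flat YAML file.

    ``load_params(save_params(...))`` round-trips bit-exactly: values are
    written with full float repr.
    """
    path = Path(path)
    flat = params.to_flat_dict()
    lines = [f"{key}: {value!r}" for key, value in flat.items()]
    path.write_text("\n".join(lines) + "\n")


def heuristic_source_rate(params: ModelParams) -> float:
    """Source rate from the one-fiber-per-breath heuristic: A = 1/(T L).

    One fiber dislodged onto the domain of length L per breathing cycle of
    period T gives A = 1/(T L) ≈ 1.67 fibers/m/s at the defaults — the same
    order of magnitude as the nominal A = 1.
    """
    return 1.0 / (params.transport.T * params.transport.L)


def is_close_params(a: ModelParams, b: ModelParams, rel: float = 0.0) -> bool:
    """Field-wise equality (exact when rel == 0)."""
    fa, fb = a.to_flat_dict(), b.to_flat_dict()
    return all(math.isclose(fa[k], fb[k], rel_tol=rel, abs_tol=0.0) for k in fa)
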