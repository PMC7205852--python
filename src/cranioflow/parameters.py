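"""Model parameters: the fitted physiological set plus fixed structural constants.

The craniospinal circuit is parameterised by 24 named physiological
quantities (baseline elastances, resistances, inertances, the reference
tissue pressure, nonlinearity/asymmetry shape coefficients) that a
calibration may adjust per individual, plus a small set of structural
constants (unstressed volumes, downstream venous pressure, compensatory
gain, switch/clip smoothing widths) that are held fixed.

Two presets are shipped: ``table2_mean`` (population-mean values) and
``table2_H`` (the values calibrated for one individual, H).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError

__all__ = [
    "ModelParameters",
    "FITTED_NAMES",
    "STRUCTURAL_NAMES",
    "PARAM_ORDER",
    "load_preset",
    "PRESETS",
]

#: Names of the individually adjustable physiological parameters, in the
#: canonical packing order used by the ODE kernel.
FITTED_NAMES = (
    "e_a0",      # baseline arterial elastance, mmHg/ml
    "R_av0",     # baseline arteriovenous resistance, mmHg*s/ml
    "R_v0",      # baseline venous outflow resistance, mmHg*s/ml
    "e_c0",      # baseline craniospinal-CSF elastance, mmHg/ml
    "e_s",       # spinal compartment elastance, mmHg/ml
    "L_cs",      # baseline foramen-magnum CSF inertance, mmHg*s^2/ml
    "R_cs",      # baseline foramen-magnum CSF resistance, mmHg*s/ml
    "rho_l",     # density-scaled advective loss coefficient (dimensionless)
    "p_0",       # reference tissue / extraspinal pressure, mmHg
    "b_Ls",      # directional asymmetry of CSF inertance
    "a_Rs",      # directional asymmetry of CSF resistance
    "L_v",       # venous outflow inertance, mmHg*s^2/ml
    "tau_reg",   # compensatory-displacement time constant, s
    "k_ea",      # arterial elastance nonlinearity coefficient
    "n_ea",      # arterial elastance nonlinearity inner exponent
    "m_ea",      # arterial elastance nonlinearity outer exponent
    "n_Rav",     # arteriovenous collapse logistic steepness
    "m_Rav",     # arteriovenous resistance volume exponent
    "e_v1",      # venous distension coefficient, mmHg/ml^m_ev1
    "e_v2",      # venous collapse coefficient, mmHg/ml^m_ev2
    "m_ev1",     # venous distension exponent
    "m_ev2",     # venous collapse exponent
    "m_Rv",      # venous Starling-resistance exponent
    "k_ec",      # CSF elastance nonlinearity coefficient
)

#: Structural constants: fixed by design, never calibrated.
STRUCTURAL_NAMES = (
    "V_an",        # unstressed arterial volume, ml
    "V_vn",        # unstressed venous volume, ml
    "V_sn",        # unstressed spinal CSF volume, ml
    "p_out",       # downstream venous pressure, mmHg
    "G_comp",      # compensatory-displacement gain, ml/mmHg
    "eps_q",       # CSF direction-switch smoothing half-width, ml/s
    "eps_p",       # Starling pressure-gap clip, mmHg
    "c_geo",       # advective-loss geometry constant, mmHg*s^2/ml^2 per unit rho_l
    "c_collapse",  # arteriovenous collapse-factor amplitude
    "r_v_cap",     # upper clip on venous resistance, as a multiple of R_v0
)

PARAM_ORDER = FITTED_NAMES + STRUCTURAL_NAMES

_EXPONENT_NAMES = frozenset(
    {"n_ea", "m_ea", "n_Rav", "m_Rav", "m_ev1", "m_ev2", "m_Rv"}
)
_NONNEG_NAMES = frozenset({"k_ea", "k_ec", "a_Rs", "b_Ls", "rho_l"})
_POSITIVE_NAMES = frozenset(FITTED_NAMES) - _EXPONENT_NAMES - _NONNEG_NAMES


@dataclass
class ModelParameters:
    """The full parameter set of the craniospinal circuit model.

    Field defaults are the population-mean preset.  Use
    :meth:`preset` for the shipped presets, :meth:`replace` for
    modified copies and :meth:`to_array` for the packed vector consumed
    by the ODE kernel.
    """

    e_a0: float = 3.33
    R_av0: float = 12.54
    R_v0: float = 0.54
    e_c0: float = 101.17
    e_s: float = 3.38
    L_cs: float = 0.10
    R_cs: float = 0.60
    rho_l: float = 6.03
    p_0: float = 13.66
    b_Ls: float = 0.01
    a_Rs: float = 0.37
    L_v: float = 0.14
    tau_reg: float = 1.31
    k_ea: float = 0.05
    n_ea: float = 23.0
    m_ea: float = 1.95
    n_Rav: float = 36.0
    m_Rav: float = 2.0
    e_v1: float = 1.0
    e_v2: float = 1.48
    m_ev1: float = 1.89
    m_ev2: float = 1.87
    m_Rv: float = 2.89
    k_ec: float = 1.56
    # structural constants
    V_an: float = 15.0
    V_vn: float = 70.0
    V_sn: float = 30.0
    p_out: float = 5.0
    G_comp: float = 0.1
    eps_q: float = 0.05
    eps_p: float = 0.1
    c_geo: float = 1e-3
    c_collapse: float = 10.0
    r_v_cap: float = 300.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`DomainError` on any invariant violation."""
        for name in _POSITIVE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise DomainError(f"parameter {name} must be strictly positive, got {v}")
        for name in _EXPONENT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise DomainError(f"exponent {name} must be >= 0, got {v}")
        for name in _NONNEG_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise DomainError(f"coefficient {name} must be >= 0, got {v}")
        for name in ("V_an", "V_vn", "V_sn", "G_comp", "eps_q", "eps_p", "r_v_cap"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise DomainError(f"structural constant {name} must be > 0, got {v}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def preset(cls, name: str) -> "ModelParameters":
        """Return a shipped preset (``table2_mean`` or ``table2_H``)."""
        try:
            values = PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None
        return cls(**values)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (validates)."""
        return dataclasses.replace(self, **changes)

    # -- packing for the ODE kernel -------------------------------------------

    def to_array(self) -> np.ndarray:
        """Pack into a float64 vector in :data:`PARAM_ORDER` order."""
        return np.array([getattr(self, n) for n in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_ORDER),):
            raise DomainError(
                f"expected packed vector of length {len(PARAM_ORDER)}, got {arr.shape}"
            )
        return cls(**dict(zip(PARAM_ORDER, arr.tolist())))

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        """Flat dict of fitted parameters plus a ``fixed`` block."""
        d = {n: getattr(self, n) for n in FITTED_NAMES}
        d["fixed"] = {n: getattr(self, n) for n in STRUCTURAL_NAMES}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        kw = {k: v for k, v in d.items() if k != "fixed"}
        kw.update(d.get("fixed", {}))
        unknown = set(kw) - set(PARAM_ORDER)
        if unknown:
            raise DomainError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**kw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: Shipped presets: population-mean values and the individual-H calibration.
PRESETS: dict[str, dict] = {
    "table2_mean": {},
    "table2_H": {
        "e_a0": 3.0,
        "R_av0": 9.1,
        "R_v0": 0.65,
        "e_c0": 90.0,
        "e_s": 3.5,
        "L_cs": 0.08,
        "R_cs": 0.45,
        "rho_l": 2.0,
        "p_0": 9.6,
        "b_Ls": 0.015,
        "a_Rs": 0.6,
        "L_v": 0.14,
        "tau_reg": 1.0,
        "k_ea": 0.005,
        "n_ea": 23.0,
        "m_ea": 1.95,
        "n_Rav": 36.0,
        "m_Rav": 2.0,
        "e_v1": 1.0,
        "e_v2": 1.0,
        "m_ev1": 2.0,
        "m_ev2": 2.0,
        "m_Rv": 2.0,
        "k_ec": 1.0,
    },
}


def load_preset(name: str) -> ModelParameters:
    """Convenience alias for :meth:`ModelParameters.preset`."""
    return ModelParameters.preset(name)
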