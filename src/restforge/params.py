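"""Parameter set of the four-variable minimal ventricular action-potential model.

The model has three phenomenological transmembrane currents (fast inward,
slow inward, slow outward) gated by Heaviside switches and 28 named
parameters.  The canonical serialization order is :data:`PARAM_NAMES`;
every array-based routine in this package (integration kernels, the genetic
algorithm, population clustering) indexes parameters by that order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "BOFCParams",
    "make_base_params",
    "resting_state",
    "param_fold_change",
]

#: Canonical parameter order.  Dimensionless thresholds and gate midpoints
#: first, then time constants (ms), then slope factors.
PARAM_NAMES: tuple[str, ...] = (
    "u_o",
    "u_u",
    "theta_v",
    "theta_w",
    "theta_v_minus",
    "theta_o",
    "tau_v1_minus",
    "tau_v2_minus",
    "tau_v_plus",
    "tau_w1_minus",
    "tau_w2_minus",
    "k_w_minus",
    "u_w_minus",
    "tau_w_plus",
    "tau_fi",
    "tau_o1",
    "tau_o2",
    "tau_so1",
    "tau_so2",
    "k_so",
    "u_so",
    "tau_s1",
    "tau_s2",
    "k_s",
    "u_s",
    "tau_si",
    "tau_w_inf",
    "w_inf_star",
)

_TIME_CONSTANTS = tuple(n for n in PARAM_NAMES if n.startswith("tau_"))


@dataclass(frozen=True)
class BOFCParams:
    """The 28 parameters of the minimal ventricular model.

    Thresholds/midpoints and the transmembrane variable are dimensionless;
    all ``tau_*`` entries are time constants in milliseconds.
    """

    u_o: float
    u_u: float
    theta_v: float
    theta_w: float
    theta_v_minus: float
    theta_o: float
    tau_v1_minus: float
    tau_v2_minus: float
    tau_v_plus: float
    tau_w1_minus: float
    tau_w2_minus: float
    k_w_minus: float
    u_w_minus: float
    tau_w_plus: float
    tau_fi: float
    tau_o1: float
    tau_o2: float
    tau_so1: float
    tau_so2: float
    k_so: float
    u_so: float
    tau_s1: float
    tau_s2: float
    k_s: float
    u_s: float
    tau_si: float
    tau_w_inf: float
    w_inf_star: float

    def __post_init__(self) -> None:
        for name in _TIME_CONSTANTS:
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} is not finite")

    # -- serialization ------------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Flat float64 vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "BOFCParams":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} entries, got {vec.size}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "BOFCParams":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise KeyError(f"missing parameter(s): {', '.join(missing)}")
        extra = set(d) - set(PARAM_NAMES)
        if extra:
            raise KeyError(f"unknown parameter(s): {', '.join(sorted(extra))}")
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BOFCParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs: float) -> "BOFCParams":
        d = self.to_dict()
        d.update(kwargs)
        return BOFCParams.from_dict(d)


#: Endocardial parameter column of the published minimal ventricular model.
_ENDO = {
    "u_o": 0.0,
    "u_u": 1.56,
    "theta_v": 0.3,
    "theta_w": 0.13,
    "theta_v_minus": 0.2,
    "theta_o": 0.006,
    "tau_v1_minus": 75.0,
    "tau_v2_minus": 10.0,
    "tau_v_plus": 1.4506,
    "tau_w1_minus": 6.0,
    "tau_w2_minus": 140.0,
    "k_w_minus": 200.0,
    "u_w_minus": 0.016,
    "tau_w_plus": 280.0,
    "tau_fi": 0.1,
    "tau_o1": 470.0,
    "tau_o2": 6.0,
    "tau_so1": 40.0,
    "tau_so2": 1.2,
    "k_so": 2.0,
    "u_so": 0.65,
    "tau_s1": 2.7342,
    "tau_s2": 2.0,
    "k_s": 2.0994,
    "u_s": 0.9087,
    "tau_si": 2.9013,
    "tau_w_inf": 0.0273,
    "w_inf_star": 0.78,
}


def make_base_params() -> BOFCParams:
    """Baseline endocardial parameter set of the minimal ventricular model."""
    return BOFCParams(**_ENDO)


def resting_state(params: BOFCParams) -> np.ndarray:
    """Exact resting fixed point ``(u, v, w, s)`` of the model.

    At ``u = u_o`` the gates settle to v = 1, w = 1 and
    ``s = (1 + tanh(k_s (u_o - u_s))) / 2`` (a small positive value, since
    the s-gate steady state is a smooth sigmoid).  All four time
    derivatives vanish there with zero stimulus.
    """
    s_rest = 0.5 * (1.0 + math.tanh(params.k_s * (params.u_o - params.u_s)))
    return np.array([params.u_o, 1.0, 1.0, s_rest], dtype=np.float64)


def param_fold_change(params: BOFCParams, base: BOFCParams) -> np.ndarray:
    """Element-wise ratio params/base in canonical order.

    A base entry of zero is only tolerated when the compared entry is also
    zero (the parameter is unchanged; ratio reported as 1).  A nonzero
    value over a zero base is undefined and raises.
    """
    p = params.to_vector()
    b = base.to_vector()
    out = np.empty_like(p)
    for i, (pi, bi) in enumerate(zip(p, b)):
        if bi == 0.0:
            if pi != 0.0:
                raise ValueError(
                    f"base parameter {PARAM_NAMES[i]} is zero but compared "
                    f"value is {pi}; fold change undefined"
                )
            out[i] = 1.0
        else:
            out[i] = pi / bi
    return out
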