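"""Model parameters: phi coefficients, temperature, collision frequency,
and the reference measure.

The equilibrium distribution over aggregation graphs is the Boltzmann/ERGM
form

    Pr(G = g) ∝ exp(theta . t(g)) * h(g),      theta = -phi' / (k_B * T)

where ``phi'`` is the Hamiltonian coefficient vector (the edge term carries
``phi_e + k_B*T``, all others their bare phi) and ``h`` is the reference
measure capturing entropic effects of hidden degrees of freedom.  The
default is the counting measure, ``log h == 0``.  Reduced units ``k_B = 1``,
``T = 1`` are the default; the collision frequency ``A`` sets the event-rate
scale of the kinetic model, so simulated time is reported in units of
inverse collision rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Union

import numpy as np

from .graph import AggregationGraph

#: parameter-file keys for the nine phi coefficients, in canonical order
PHI_KEYS = (
    "phi_e",
    "phi_2s",
    "phi_NSP1",
    "phi_NSP2",
    "phi_ESP0",
    "phi_ESP1",
    "phi_C5",
    "phi_C6",
    "phi_C7",
)

RefMeasure = Union[str, Callable[[AggregationGraph], float]]


@dataclass(frozen=True)
class ModelParams:
    """Coefficients and thermodynamic constants of the network Hamiltonian.

    Parameters
    ----------
    phi_e, phi_2s, phi_NSP1, phi_NSP2, phi_ESP0, phi_ESP1, phi_C5, phi_C6, phi_C7
        Signed energy coefficients of the nine bonding-motif statistics.
    T, k_B
        Temperature and Boltzmann constant; reduced units (both 1) by default.
    A
        Collision frequency, events per unit time (> 0); every transition
        rate lies in (0, A).
    ref_measure
        ``"counting"`` (log h == 0) or a callable ``g -> log h(g)``.
    """

    phi_e: float = 0.0
    phi_2s: float = 0.0
    phi_NSP1: float = 0.0
    phi_NSP2: float = 0.0
    phi_ESP0: float = 0.0
    phi_ESP1: float = 0.0
    phi_C5: float = 0.0
    phi_C6: float = 0.0
    phi_C7: float = 0.0
    T: float = 1.0
    k_B: float = 1.0
    A: float = 1.0
    ref_measure: RefMeasure = "counting"

    def __post_init__(self):
        if self.T <= 0 or self.k_B <= 0:
            raise ValueError("T and k_B must be positive")
        if self.A <= 0:
            raise ValueError(f"collision frequency A must be > 0, got {self.A}")
        if isinstance(self.ref_measure, str) and self.ref_measure != "counting":
            raise ValueError(
                f"unknown reference-measure mode {self.ref_measure!r}; "
                "use 'counting' or pass a callable g -> log h(g)"
            )

    # -- derived quantities ---------------------------------------------
    @property
    def beta(self) -> float:
        return 1.0 / (self.k_B * self.T)

    @property
    def phi(self) -> np.ndarray:
        """Bare phi vector in canonical statistic order."""
        return np.array(
            [
                self.phi_e,
                self.phi_2s,
                self.phi_NSP1,
                self.phi_NSP2,
                self.phi_ESP0,
                self.phi_ESP1,
                self.phi_C5,
                self.phi_C6,
                self.phi_C7,
            ]
        )

    @property
    def coeffs(self) -> np.ndarray:
        """Hamiltonian coefficients: phi with the edge term shifted by k_B*T."""
        c = self.phi
        c[0] += self.k_B * self.T
        return c

    @property
    def theta(self) -> np.ndarray:
        """Natural ERGM parameters theta = -coeffs / (k_B * T)."""
        return -self.coeffs * self.beta

    # -- reference measure ----------------------------------------------
    def log_h(self, g: AggregationGraph) -> float:
        if self.ref_measure == "counting":
            return 0.0
        return float(self.ref_measure(g))

    @property
    def counting_measure(self) -> bool:
        return self.ref_measure == "counting"

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PHI_KEYS}
        d.update(T=self.T, k_B=self.k_B, A=self.A)
        d["ref_measure"] = (
            self.ref_measure if isinstance(self.ref_measure, str) else "custom"
        )
        return d

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)
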