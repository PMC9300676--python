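"""ODE model of the dual-attP GFP/mCherry co-expression circuit.

A high-copy substrate plasmid carries two intact attP variants (attP1, attP2)
downstream of a promoter. An attP1-mediated inversion commits the plasmid to
GFP expression; an attP2-mediated inversion commits it to mCherry. Both
channels are irreversible and race for free recombinase. After either
inversion the plasmid retains one intact att site that can still bind enzyme
without reacting — a decoy. Sequestration by decoys (and by the substrate's
own sites) lowers the free enzyme concentration, so slow att variants do not
just change the GFP:mCherry ratio: by sequestering less enzyme they can
*increase* total expression (product inhibition).

States: S (unflipped plasmid), P1 (GFP-state), P2 (mCherry-state), and the
reporter pools GFP, mCherry. Enzyme binding is treated as a rapid
equilibrium with per-site strength proportional to the site's own rate
constant:

    E_free = E_total / (1 + Kd_scale * (k1*(S + P2) + k2*(S + P1)))
    dS/dt  = -(r1 + r2) * S,   r_m = rate_calibration * k_m * E_free
    dP1/dt = r1 * S,           dP2/dt = r2 * S
    dGFP/dt = a_G * P1 - d * GFP,   dmCherry/dt = a_R * P2 - d * mCherry
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "CircuitParams",
    "Trajectory",
    "simulate_circuit",
    "expression_grid",
    "K_LOW",
    "K_MEDIUM",
    "K_HIGH",
]

# WT-relative rate presets mirroring the tested low/medium/high attP variants
# (single disrupting mutation / wild type / triple-enhancer sequence).
K_LOW = 0.02
K_MEDIUM = 1.0
K_HIGH = 10.0


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the co-expression circuit.

    k1, k2 are WT-relative flipping rate constants (dimensionless; ``k2 = 0``
    encodes "no attP2"); ``rate_calibration`` converts them to min^-1 at unit
    free enzyme. ``Kd_scale`` sets the strength of enzyme sequestration by
    intact att sites; the default puts the system in the product-inhibition
    regime where a slower attP2 measurably raises total expression.
    Concentrations are in arbitrary units with P_total = 1.
    """

    k1: float = K_MEDIUM
    k2: float = 0.0
    E_total: float = 1.0
    P_total: float = 1.0
    Kd_scale: float = 5.0
    rate_calibration: float = 0.02  # min^-1 per unit k per unit free enzyme
    a_G: float = 1.0
    a_R: float = 1.0
    d: float = 0.0  # reporter dilution/degradation, min^-1
    t_end: float = 720.0  # minutes (12 h endpoint)
    dt_report: float = 5.0

    def __post_init__(self):
        vals = (
            self.k1, self.k2, self.E_total, self.P_total, self.Kd_scale,
            self.rate_calibration, self.a_G, self.a_R, self.d,
            self.t_end, self.dt_report,
        )
        if any(v < 0 for v in vals):
            raise ValueError("all circuit parameters must be non-negative")
        if self.P_total <= 0:
            raise ValueError("P_total must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Trajectory:
    """Time course of the circuit species on the uniform reporting grid."""

    t: np.ndarray
    S: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    E_free: np.ndarray
    GFP: np.ndarray
    mCherry: np.ndarray
    params: CircuitParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.t, "S": self.S, "P1": self.P1, "P2": self.P2,
                "E_free": self.E_free, "GFP": self.GFP, "mCherry": self.mCherry,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _free_enzyme(S, P1, P2, p: CircuitParams):
    load = p.Kd_scale * (p.k1 * (S + P2) + p.k2 * (S + P1))
    return p.E_total / (1.0 + load)


def simulate_circuit(params: CircuitParams) -> Trajectory:
    """Integrate the circuit ODEs (adaptive stiff solver, rtol 1e-8).

    Plasmid conservation S + P1 + P2 = P_total is asserted on the reported
    grid (1e-6 relative), never enforced by substitution.
    """
    p = params

    def rhs(t, y):
        S, P1, P2, G, R = y
        E = _free_enzyme(S, P1, P2, p)
        r1 = p.rate_calibration * p.k1 * E
        r2 = p.rate_calibration * p.k2 * E
        return [
            -(r1 + r2) * S,
            r1 * S,
            r2 * S,
            p.a_G * P1 - p.d * G,
            p.a_R * P2 - p.d * R,
        ]

    t_eval = np.arange(0.0, p.t_end + 0.5 * p.dt_report, p.dt_report)
    sol = solve_ivp(
        rhs,
        (0.0, p.t_end),
        [p.P_total, 0.0, 0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"circuit integration failed ({sol.message}); params={p}")
    S, P1, P2, G, R = sol.y
    total = S + P1 + P2
    if np.max(np.abs(total - p.P_total)) > 1e-6 * p.P_total:
        raise RuntimeError(f"plasmid conservation violated; params={p}")
    return Trajectory(
        t=sol.t, S=S, P1=P1, P2=P2,
        E_free=_free_enzyme(S, P1, P2, p),
        GFP=G, mCherry=R, params=p,
    )


def expression_grid(
    k1_values: Sequence[float],
    k2_values: Sequence[float],
    params: CircuitParams = CircuitParams(),
) -> pd.DataFrame:
    """Endpoint GFP/mCherry over a grid of (k1, k2) rate-constant pairs.

    Returns one row per pair with endpoint GFP, mCherry, their total, and the
    mCherry:GFP ratio (inf when GFP is 0). ``k2 = 0`` encodes a circuit with
    no attP2 site.
    """
    if not len(k1_values) or not len(k2_values):
        raise ValueError("k1_values and k2_values must be non-empty")
    rows = []
    for k1 in k1_values:
        for k2 in k2_values:
            traj = simulate_circuit(replace(params, k1=float(k1), k2=float(k2)))
            g, r = float(traj.GFP[-1]), float(traj.mCherry[-1])
            rows.append(
                {
                    "k1": float(k1),
                    "k2": float(k2),
                    "GFP_end": g,
                    "mCherry_end": r,
                    "total": g + r,
                    "mCherry_GFP_ratio": r / g if g > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)
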