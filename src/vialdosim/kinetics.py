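"""Closed-form branching Bateman kinetics for the ²¹³Bi chain.

The chain starts from pure ²¹³Bi (daughters at zero unless explicitly
seeded).  Activities follow the classical Bateman solution written per
linear path through the branching graph, with one numerically essential
special case: the 4.2 μs half-life of ²¹³Po makes its Bateman
coefficients catastrophically ill-conditioned on any laboratory time
grid, so ²¹³Po is carried as

    A_Po(t) = b_β · A_Bi(t) · (1 − exp(−λ_Po t))

i.e. transient equilibrium with its parent, exact for a two-member
sub-chain when λ_Po ≫ λ_Bi (relative error < 1e−6 here, of order
λ_Bi/λ_Po ≈ 1.5e−9).  For the same reason ²⁰⁹Pb ingrowth through the
β branch treats ²¹³Po as an instantaneous pass-through.

All activities are in MBq, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nuclides import DecayChain, load_chain

__all__ = [
    "ActivityCurve",
    "IntegratedActivity",
    "activities",
    "integrated_activities",
    "default_time_grid",
]


@dataclass
class ActivityCurve:
    """Per-nuclide activities A_n(t) on a shared time grid."""

    time_grid_s: np.ndarray
    activity_MBq: dict[str, np.ndarray]
    initial_activity_MBq: float

    def at(self, nuclide: str, t_s: float) -> float:
        """Linearly interpolated activity of one nuclide at time t."""
        return float(np.interp(t_s, self.time_grid_s, self.activity_MBq[nuclide]))


@dataclass
class IntegratedActivity:
    """Time-integrated activities Ã_n(T) = ∫₀ᵀ A_n dt, in MBq·s."""

    horizon_s: float
    integral_MBq_s: dict[str, float]


def default_time_grid(t_max_s: float = 7200.0, n: int = 600) -> np.ndarray:
    """Logarithmic-then-linear grid on [0, t_max].

    The first quarter of the points covers [0, 60 s] logarithmically
    (resolving the 2.16 min ²⁰⁹Tl ingrowth), the rest is linear.
    """
    if t_max_s <= 0:
        raise ValueError("t_max_s must be positive")
    if t_max_s <= 60.0:
        return np.concatenate([[0.0], np.geomspace(1e-3, t_max_s, n - 1)])
    n_log = n // 4
    log_part = np.concatenate([[0.0], np.geomspace(1e-3, 60.0, n_log - 1)])
    lin_part = np.linspace(60.0, t_max_s, n - n_log + 1)[1:]
    return np.concatenate([log_part, lin_part])


def _branch_fraction(chain: DecayChain, parent: str, daughter: str) -> float:
    for br in chain[parent].branches:
        if br.daughter == daughter:
            return br.fraction
    return 0.0


def _two_member_daughter_activity(
    A0: float, lam1: float, lam2: float, b: float, t: np.ndarray
) -> np.ndarray:
    """Activity of daughter 2 fed by parent 1 (branch fraction b), pure
    parent at t=0: A₂(t) = b·A₀·λ₂/(λ₂−λ₁)·(e^{−λ₁t} − e^{−λ₂t})."""
    return b * A0 * lam2 / (lam2 - lam1) * (np.exp(-lam1 * t) - np.exp(-lam2 * t))


def _three_member_terminal_activity(
    A0: float, lam1: float, lam2: float, lam3: float, b12: float, b23: float, t: np.ndarray
) -> np.ndarray:
    """Bateman activity of member 3 of a linear chain 1→2→3, pure member 1
    at t=0, with branch fractions on each step."""
    n1_0 = A0 / lam1  # in MBq/λ units; only ratios matter
    c = b12 * b23 * lam1 * lam2 * n1_0
    terms = (
        np.exp(-lam1 * t) / ((lam2 - lam1) * (lam3 - lam1))
        + np.exp(-lam2 * t) / ((lam1 - lam2) * (lam3 - lam2))
        + np.exp(-lam3 * t) / ((lam1 - lam3) * (lam2 - lam3))
    )
    return lam3 * c * terms


def activities(
    chain: DecayChain | None,
    A0_MBq: float,
    time_grid_s: np.ndarray,
) -> ActivityCurve:
    """Closed-form activities of Bi-213, Po-213, Tl-209 and Pb-209.

    Parameters
    ----------
    chain
        Decay chain (``None`` loads the embedded default).
    A0_MBq
        Initial ²¹³Bi activity; daughters start at zero.
    time_grid_s
        Strictly increasing grid starting at 0.
    """
    if chain is None:
        chain = load_chain()
    t = np.asarray(time_grid_s, dtype=float)
    if A0_MBq < 0:
        raise ValueError("A0_MBq must be non-negative")
    if t.ndim != 1 or t.size < 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing and start at 0")

    lam = {n.name: n.decay_constant_per_s for n in chain.nuclides}
    b_beta = _branch_fraction(chain, "Bi-213", "Po-213")
    b_alpha = _branch_fraction(chain, "Bi-213", "Tl-209")

    A_bi = A0_MBq * np.exp(-lam["Bi-213"] * t)
    # transient-equilibrium form; exact to O(λ_Bi/λ_Po)
    A_po = b_beta * A_bi * (1.0 - np.exp(-lam["Po-213"] * t))
    A_tl = _two_member_daughter_activity(
        A0_MBq, lam["Bi-213"], lam["Tl-209"], b_alpha, t
    )
    # Pb-209 fed through Po-213 (instantaneous) and through Tl-209
    A_pb = _two_member_daughter_activity(
        A0_MBq, lam["Bi-213"], lam["Pb-209"], b_beta, t
    ) + _three_member_terminal_activity(
        A0_MBq, lam["Bi-213"], lam["Tl-209"], lam["Pb-209"], b_alpha, 1.0, t
    )
    zero = t == 0.0  # cancel roundoff dust in the Bateman terms at t=0
    A_tl = np.where(zero, 0.0, np.clip(A_tl, 0.0, None))
    A_pb = np.where(zero, 0.0, np.clip(A_pb, 0.0, None))
    return ActivityCurve(
        time_grid_s=t,
        activity_MBq={
            "Bi-213": A_bi,
            "Po-213": A_po,
            "Tl-209": A_tl,
            "Pb-209": A_pb,
        },
        initial_activity_MBq=A0_MBq,
    )


def _int_exp(lam: float, T: float) -> float:
    """∫₀ᵀ e^{−λt} dt."""
    return (1.0 - np.exp(-lam * T)) / lam


def integrated_activities(
    chain: DecayChain | None,
    A0_MBq: float,
    T_s: float,
) -> IntegratedActivity:
    """Analytic time-integrated activities over [0, T]."""
    if chain is None:
        chain = load_chain()
    if T_s < 0:
        raise ValueError("T_s must be non-negative")
    if T_s == 0:
        return IntegratedActivity(0.0, {n: 0.0 for n in chain.names})

    lam = {n.name: n.decay_constant_per_s for n in chain.nuclides}
    b_beta = _branch_fraction(chain, "Bi-213", "Po-213")
    b_alpha = _branch_fraction(chain, "Bi-213", "Tl-209")
    l1, lpo, ltl, lpb = lam["Bi-213"], lam["Po-213"], lam["Tl-209"], lam["Pb-209"]

    I_bi = A0_MBq * _int_exp(l1, T_s)
    # ∫ b·A_Bi·(1−e^{−λPo t}) dt
    I_po = b_beta * A0_MBq * (_int_exp(l1, T_s) - _int_exp(l1 + lpo, T_s))
    I_tl = b_alpha * A0_MBq * ltl / (ltl - l1) * (_int_exp(l1, T_s) - _int_exp(ltl, T_s))
    c = b_alpha * l1 * ltl * (A0_MBq / l1)
    I_pb_tl = lpb * c * (
        _int_exp(l1, T_s) / ((ltl - l1) * (lpb - l1))
        + _int_exp(ltl, T_s) / ((l1 - ltl) * (lpb - ltl))
        + _int_exp(lpb, T_s) / ((l1 - lpb) * (ltl - lpb))
    )
    I_pb_po = b_beta * A0_MBq * lpb / (lpb - l1) * (_int_exp(l1, T_s) - _int_exp(lpb, T_s))
    return IntegratedActivity(
        horizon_s=T_s,
        integral_MBq_s={
            "Bi-213": float(I_bi),
            "Po-213": float(I_po),
            "Tl-209": float(I_tl),
            "Pb-209": float(I_pb_po + I_pb_tl),
        },
    )
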