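"""Developmental-strategy classification from population trait means.

Six viable strategies exist for a two-type filament whose traits are
(p_keep, p_diff, n_keep, n_diff), judged against an effective-zero
threshold (default 0.05):

  I    terminal differentiation, photosynthetic germline, non-dividing
       nitrogen-fixing soma
  II   photosynthetic germline with dividing nitrogen-fixing soma
  III  reversible differentiation (both types divide and differentiate)
  IV   symbiosis (both types divide, neither differentiates)
  V    nitrogen-fixing germline with dividing photosynthetic soma
  VI   terminal differentiation, nitrogen-fixing germline, non-dividing
       photosynthetic soma

A keep-trait at zero means the type never accumulates resources and so
never divides; a diff-trait of a non-dividing type is unconstrained (its
daughters never exist) and is ignored.  Combinations in which neither type
divides, or a dividing type cannot be (re)generated, are nonviable and
reported as "unclassified".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import TraitVector

__all__ = ["Strategy", "StrategyCall", "classify", "classify_grid", "call_from_trajectory"]

DEFAULT_THRESHOLD = 0.05


class Strategy(enum.Enum):
    I = "I_terminal_P_germ"
    II = "II_terminal_P_germ_dividing_soma"
    III = "III_reversible"
    IV = "IV_symbiosis"
    V = "V_terminal_N_germ_dividing_soma"
    VI = "VI_terminal_N_germ"
    UNCLASSIFIED = "unclassified"

    @property
    def color(self) -> str:
        return {
            "I": "violet",
            "II": "blue",
            "III": "green",
            "IV": "yellow",
            "V": "orange",
            "VI": "red",
            "UNCLASSIFIED": "grey",
        }[self.name]


@dataclass(frozen=True)
class StrategyCall:
    label: Strategy
    trait_means: TraitVector
    threshold: float

    def __str__(self) -> str:
        return self.label.name


def _label(pk: bool, pd_: bool, nk: bool, nd: bool) -> Strategy:
    """Strategy from effective-zero booleans (True = trait effectively 0)."""
    if pk and not nk and not nd:
        return Strategy.VI
    if not pk and not pd_ and nk:
        return Strategy.I
    if not pk and not pd_ and not nk and nd:
        return Strategy.II
    if not pk and not pd_ and not nk and not nd:
        return Strategy.III
    if not pk and pd_ and not nk and nd:
        return Strategy.IV
    if not pk and pd_ and not nk and not nd:
        return Strategy.V
    return Strategy.UNCLASSIFIED


def classify(
    trait_means: TraitVector, threshold: float = DEFAULT_THRESHOLD
) -> StrategyCall:
    """Map trait means to exactly one developmental strategy."""
    t = trait_means
    for name in ("p_keep", "p_diff", "n_keep", "n_diff"):
        v = getattr(t, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"trait mean {name}={v} outside [0, 1]")
    z = lambda x: x <= threshold
    label = _label(z(t.p_keep), z(t.p_diff), z(t.n_keep), z(t.n_diff))
    return StrategyCall(label, t, threshold)


def classify_grid(traits: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Vectorised classification of an (n, 4) array of trait means;
    returns an array of Strategy values (used for truth-table audits)."""
    traits = np.asarray(traits, dtype=float).reshape(-1, 4)
    z = traits <= threshold
    pk, pd_, nk, nd = z.T
    out = np.full(len(traits), Strategy.UNCLASSIFIED, dtype=object)
    out[pk & ~nk & ~nd] = Strategy.VI
    out[~pk & ~pd_ & nk] = Strategy.I
    out[~pk & ~pd_ & ~nk & nd] = Strategy.II
    out[~pk & ~pd_ & ~nk & ~nd] = Strategy.III
    out[~pk & pd_ & ~nk & nd] = Strategy.IV
    out[~pk & pd_ & ~nk & ~nd] = Strategy.V
    return out


def call_from_trajectory(
    traj: pd.DataFrame,
    window: float = 0.1,
    threshold: float = DEFAULT_THRESHOLD,
) -> StrategyCall:
    """Classify the strategy a run evolved to, from trait means averaged
    over the final ``window`` fraction of recorded generations."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if not (0.0 < window <= 1.0):
        raise ValueError("window must be in (0, 1]")
    k = max(1, int(round(window * len(traj))))
    tail = traj.iloc[-k:]
    means = TraitVector(
        float(np.clip(tail["mean_p_keep"].mean(), 0, 1)),
        float(np.clip(tail["mean_p_diff"].mean(), 0, 1)),
        float(np.clip(tail["mean_n_keep"].mean(), 0, 1)),
        float(np.clip(tail["mean_n_diff"].mean(), 0, 1)),
    )
    return classify(means, threshold)
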