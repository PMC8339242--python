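"""Break-even thresholds and optimal-strategy prediction for a size dyad.

Comparing the relevant pair of reward-matrix entries at normalized sizes
(x = 1, rho = y/x) yields four break-even equations, one per combination of
focal role (larger/smaller player) and opponent behavior (dove/hawk):

* larger vs dove:   x^2 y^2 = x^2 (x-y)  ->  y^2 + y - x = 0.  At x=1 the
  positive root is phi = (sqrt(5)-1)/2 ~ 0.618, the golden section: the
  larger player exploits a smaller dove below 62% of its size and cooperates
  above it.
* larger vs hawk:   y (x-y)^2 = 1.  At x=1 the real root is ~1.7549, outside
  (0, 1): a larger player always meets a smaller hawk with aggression, and
  would only relent once "reversely surpassed" by ~75%.
* smaller vs dove:  x^2 y^2 = y (x-y)^2  ->  y^2 - (x^2+2x) y + x^2 = 0.  At
  x=1 the non-extraneous root is 1 - phi ~ 0.382, the Fibonacci retracement
  mark separating cooperation (below) from cheating (above).
* smaller vs hawk:  x^2 (x-y) = 1  ->  y = x - 1/x^2, which is 0 at x=1:
  resistance (payoff 1) dominates surrender everywhere in (0, 1).

Note on naming: here "golden ratio" follows the reciprocal convention
phi = (sqrt(5)-1)/2 ~ 0.618 (the conventional golden ratio is its
reciprocal, ~1.618); the mathematics is unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .descriptors import SizePair, relativized_matrix

#: Golden-section threshold: positive root of y^2 + y - 1 = 0.
PHI = (math.sqrt(5.0) - 1.0) / 2.0

#: Fibonacci retracement mark: 1 - PHI, root of y^2 - 3y + 1 = 0 in (0, 1).
FIB_MARK = 1.0 - PHI


@dataclass(frozen=True)
class Thresholds:
    """The four hypothesis constants at normalized size x = 1."""

    phi: float  # golden-section break-even, larger vs dove
    hawk_shift: float  # reverse-surpass root, larger vs hawk (> 1)
    fib_mark: float  # Fibonacci mark, smaller vs dove
    surrender_point: float  # break-even, smaller vs hawk (= 0)

    def as_dict(self) -> dict:
        return {
            "phi": self.phi,
            "hawk_shift": self.hawk_shift,
            "fib_mark": self.fib_mark,
            "surrender_point": self.surrender_point,
        }


@dataclass(frozen=True)
class StrategyDecision:
    """Predicted optimal strategy for one player of a dyad.

    ``decision`` is always the argmax of the two relevant reward-matrix
    entries at normalized sizes; ``threshold`` is the break-even size ratio
    that separates the two branches.
    """

    focal_role: str  # "larger" | "smaller"
    opponent_type: str  # "dove" | "hawk"
    decision: str  # cooperate | aggress | cheat | resist | surrender-dominated
    payoff_chosen: float
    payoff_rejected: float
    threshold: float


def breakeven_larger_vs_dove(x: float) -> float:
    """Break-even size y of a smaller dove, from y^2 + y - x = 0.

    Closed form ``(-1 + sqrt(1 + 4x)) / 2``; at x=1 this is the golden
    section phi ~ 0.618.
    """
    if x <= 0:
        raise ValueError(f"trait value must be positive, got x={x}")
    return (-1.0 + math.sqrt(1.0 + 4.0 * x)) / 2.0


def breakeven_larger_vs_hawk(x: float, xtol: float = 1e-12) -> float:
    """Break-even size y of a smaller hawk, the real root of y (x-y)^2 = 1.

    The root exceeds x (at x=1 it is ~1.7549), so within the admissible
    region 0 < y < x the larger player never benefits from non-aggression.
    Solved by bracketed Brent root-finding; deterministic.
    """
    if x <= 0:
        raise ValueError(f"trait value must be positive, got x={x}")

    def f(y):
        return y * (x - y) ** 2 - 1.0

    # f(x) = -1 < 0 and f is increasing in y for y > x; double the bracket
    # until a sign change appears.
    lo, hi = x, x + 1.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi = x + 2.0 * (hi - x)
    else:  # pragma: no cover - f grows cubically, cannot happen
        raise RuntimeError(
            f"no sign change found for y*(x-y)^2 = 1 with x={x}; "
            f"last bracket [{lo}, {hi}]"
        )
    return brentq(f, lo, hi, xtol=xtol)


def breakeven_smaller_vs_dove(x: float) -> float:
    """Break-even size of the smaller player against a larger dove.

    The non-extraneous root (the one in (0, x)) of
    ``y^2 - (x^2 + 2x) y + x^2 = 0``; at x=1 this is 1 - phi ~ 0.382.
    """
    if x <= 0:
        raise ValueError(f"trait value must be positive, got x={x}")
    b = x * x + 2.0 * x
    disc = math.sqrt(b * b - 4.0 * x * x)
    return (b - disc) / 2.0


def breakeven_smaller_vs_hawk(x: float) -> float:
    """Break-even size of the smaller player against a larger hawk.

    From ``x^2 (x - y) = 1``: y = x - 1/x^2, exactly 0 at x = 1.  For any
    y above this the resistance payoff (1) dominates surrender.
    """
    if x <= 0:
        raise ValueError(f"trait value must be positive, got x={x}")
    return x - 1.0 / (x * x)


def thresholds() -> Thresholds:
    """The four hypothesis constants, computed (not hard-coded) at x = 1."""
    return Thresholds(
        phi=breakeven_larger_vs_dove(1.0),
        hawk_shift=breakeven_larger_vs_hawk(1.0),
        fib_mark=breakeven_smaller_vs_dove(1.0),
        surrender_point=breakeven_smaller_vs_hawk(1.0),
    )


def predict_strategy(
    pair: SizePair, focal_role: str, opponent_type: str
) -> StrategyDecision:
    """Predict the focal player's optimal strategy against a fixed opponent.

    Sizes are normalized to x = 1 internally (the break-evens are not
    scale-invariant; decisions depend only on rho = y/x).  The decision is
    the argmax of the two relevant reward-matrix entries; exact ties resolve
    to the cooperative / non-aggressive branch.

    Parameters
    ----------
    pair
        The dyad (larger player X, smaller player Y).
    focal_role
        "larger" (X chooses a row) or "smaller" (Y chooses a column).
    opponent_type
        The opponent's fixed behavior, "dove" or "hawk".
    """
    if focal_role not in ("larger", "smaller"):
        raise ValueError(f"focal_role must be 'larger' or 'smaller', got {focal_role!r}")
    if opponent_type not in ("dove", "hawk"):
        raise ValueError(f"opponent_type must be 'dove' or 'hawk', got {opponent_type!r}")

    m = relativized_matrix(pair.normalized())
    th = thresholds()

    if focal_role == "larger" and opponent_type == "dove":
        # row dove (cooperate, e_dd) vs row hawk (aggress, e_hd)
        coop, aggr = m.e_dd, m.e_hd
        if coop >= aggr:
            return StrategyDecision("larger", "dove", "cooperate", coop, aggr, th.phi)
        return StrategyDecision("larger", "dove", "aggress", aggr, coop, th.phi)

    if focal_role == "larger" and opponent_type == "hawk":
        # row dove (e_dh) vs row hawk (e_hh); e_dh < 1 for all rho in (0,1)
        coop, aggr = m.e_dh, m.e_hh
        if coop >= aggr:  # pragma: no cover - unreachable for rho < 1
            return StrategyDecision("larger", "hawk", "cooperate", coop, aggr, th.hawk_shift)
        return StrategyDecision("larger", "hawk", "aggress", aggr, coop, th.hawk_shift)

    if focal_role == "smaller" and opponent_type == "dove":
        # column choice against X-dove: the matrix compares e_dd with e_dh.
        # Below the Fibonacci mark e_dh wins and the smaller player
        # cooperates with its benefactor; above it e_dd wins and the smaller
        # player extracts benefit by cheating.
        if m.e_dh >= m.e_dd:
            return StrategyDecision(
                "smaller", "dove", "cooperate", m.e_dh, m.e_dd, th.fib_mark
            )
        return StrategyDecision("smaller", "dove", "cheat", m.e_dd, m.e_dh, th.fib_mark)

    # smaller vs hawk: column dove (surrender, e_hd) vs column hawk
    # (resist, e_hh = 1); resistance dominates everywhere in (0, 1).
    if m.e_hh >= m.e_hd:
        return StrategyDecision(
            "smaller", "hawk", "resist", m.e_hh, m.e_hd, th.surrender_point
        )
    return StrategyDecision(  # pragma: no cover - unreachable for rho in (0,1)
        "smaller", "hawk", "surrender-dominated", m.e_hd, m.e_hh, th.surrender_point
    )
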