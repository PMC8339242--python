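"""Size-based dyadic interaction descriptors and the relativized reward matrix.

Two individuals of body size ``x > y > 0`` define four interaction-strength
descriptors:

* mutualism   ``z_mu = x*y / (x - y)`` — the product of sizes (similarity
  proxy for a fixed sum), scale-adjusted by the size gap;
* antagonism  ``z_an = 1 / (x*y*(x - y))`` — the inverse product, with the
  same gap adjustment;
* aggression  ``z_ag = x / y`` — dominance of the larger over the smaller;
* altruism    ``z_al = (x - y) / x`` — the gap relative to the larger.

Dividing every descriptor by the antagonism strength yields the well-behaved
2x2 reward matrix whose hawk/hawk entry is exactly 1:

=============  ==================  ==================
               Y dove              Y hawk
=============  ==================  ==================
X dove         ``x^2 y^2``         ``y (x - y)^2``
X hawk         ``x^2 (x - y)``     ``1``
=============  ==================  ==================

X (the larger player) chooses rows, Y (the smaller) chooses columns.  The
dyad with ``x == y`` is undefined (division by zero); construction enforces a
configurable relative degeneracy guard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Default relative degeneracy guard: a dyad is rejected when (x - y)/x < eps.
EPS_REL_DEFAULT = 1e-9


class DegenerateDyadError(ValueError):
    """Raised for dyads whose sizes are equal (or nearly so).

    The descriptors divide by ``x - y``, so a zero gap is a genuine
    singularity of the theory, not a numerical nuisance.
    """

    def __init__(self, id_x, id_y, x, y, eps):
        self.id_x, self.id_y = id_x, id_y
        super().__init__(
            f"degenerate dyad ({id_x!r}, {id_y!r}): sizes {x!r} and {y!r} "
            f"differ by less than eps={eps!r} in relative terms; "
            "the interaction descriptors are undefined at x == y"
        )


@dataclass(frozen=True)
class SizePair:
    """An ordered dyad: ``x`` is the larger player's trait, ``y`` the smaller's.

    Use :meth:`from_traits` to build from unordered input; it sorts the two
    individuals and records which id ended up larger.
    """

    x: float
    y: float
    id_x: str = "X"
    id_y: str = "Y"
    eps: float = field(default=EPS_REL_DEFAULT, compare=False)

    def __post_init__(self):
        if not (self.x > 0 and self.y > 0):
            raise ValueError(
                f"trait values must be positive, got x={self.x}, y={self.y} "
                f"for dyad ({self.id_x!r}, {self.id_y!r})"
            )
        if self.y >= self.x or (self.x - self.y) / self.x < self.eps:
            raise DegenerateDyadError(self.id_x, self.id_y, self.x, self.y, self.eps)

    @classmethod
    def from_traits(cls, id_a, value_a, id_b, value_b, eps=EPS_REL_DEFAULT):
        """Build a pair from two (id, trait) records in either order.

        Ties are rejected as degenerate rather than jittered: silent
        perturbation would corrupt downstream ratio statistics.
        """
        if value_a >= value_b:
            return cls(float(value_a), float(value_b), str(id_a), str(id_b), eps=eps)
        return cls(float(value_b), float(value_a), str(id_b), str(id_a), eps=eps)

    @property
    def ratio(self) -> float:
        """The smaller/larger size ratio rho = y/x, in (0, 1)."""
        return self.y / self.x

    def normalized(self) -> "SizePair":
        """The same dyad rescaled so that x = 1 (decisions depend only on rho)."""
        return SizePair(1.0, self.y / self.x, self.id_x, self.id_y, eps=self.eps)


@dataclass(frozen=True)
class InteractionDescriptors:
    """The four dyadic interaction strengths for one size pair."""

    z_mu: float  # mutualism
    z_an: float  # antagonism
    z_ag: float  # aggression (> 1)
    z_al: float  # altruism (< 1)


@dataclass(frozen=True)
class RewardMatrix:
    """Antagonism-relativized 2x2 reward matrix; hawk/hawk entry is 1."""

    e_dd: float  # X dove / Y dove   = x^2 y^2
    e_dh: float  # X dove / Y hawk   = y (x-y)^2
    e_hd: float  # X hawk / Y dove   = x^2 (x-y)
    e_hh: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([[self.e_dd, self.e_dh], [self.e_hd, self.e_hh]])


def compute_descriptors(pair: SizePair) -> InteractionDescriptors:
    """Evaluate the four interaction descriptors for a dyad."""
    x, y = pair.x, pair.y
    gap = x - y
    return InteractionDescriptors(
        z_mu=x * y / gap,
        z_an=1.0 / (x * y * gap),
        z_ag=x / y,
        z_al=gap / x,
    )


def relativized_matrix(pair: SizePair) -> RewardMatrix:
    """The reward matrix with every entry divided by the antagonism strength."""
    x, y = pair.x, pair.y
    gap = x - y
    return RewardMatrix(
        e_dd=x * x * y * y,
        e_dh=y * gap * gap,
        e_hd=x * x * gap,
        e_hh=1.0,
    )


def descriptor_table(
    traits: Mapping[str, float] | pd.Series,
    eps: float = EPS_REL_DEFAULT,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All-pairs (or selected-pairs) descriptor and reward-matrix table.

    Parameters
    ----------
    traits
        Mapping of individual id to positive trait value.
    eps
        Relative degeneracy guard passed to :class:`SizePair`.
    pairs
        Optional iterable of id pairs; defaults to all n(n-1)/2 combinations.

    Returns
    -------
    DataFrame with one row per dyad: id_x, id_y, x, y, the four descriptors
    and the four reward-matrix entries.  Degenerate dyads raise; callers that
    want to skip them should pre-filter (see ``interaction_networks``).
    """
    traits = pd.Series(traits, dtype=float)
    if pairs is None:
        pairs = itertools.combinations(traits.index, 2)
    rows = []
    for id_a, id_b in pairs:
        p = SizePair.from_traits(id_a, traits[id_a], id_b, traits[id_b], eps=eps)
        d = compute_descriptors(p)
        m = relativized_matrix(p)
        rows.append(
            {
                "id_x": p.id_x,
                "id_y": p.id_y,
                "x": p.x,
                "y": p.y,
                "z_mu": d.z_mu,
                "z_an": d.z_an,
                "z_ag": d.z_ag,
                "z_al": d.z_al,
                "e_dd": m.e_dd,
                "e_dh": m.e_dh,
                "e_hd": m.e_hd,
                "e_hh": m.e_hh,
            }
        )
    return pd.DataFrame(rows)
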