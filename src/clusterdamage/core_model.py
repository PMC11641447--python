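"""Event multiplicities and multinomial weights from energy imparted.

The model treats the energy imparted ``epsilon`` to a nucleosome-scale
(5 x 5 nm, ~73 bp) target volume as driving an integer number of
damage-capable events ``J_TOT = floor(epsilon / epsilon_th)``.  Each event is
one of four types:

* ``A`` -- direct ionization of a sugar-phosphate moiety (a strand break),
* ``B`` -- ionization of water producing an OH radical,
* ``C`` -- direct ionization of a DNA base (base damage),
* ``D`` -- energy imparted to histones or other molecules (no lesion).

The joint distribution of event-type counts at fixed ``J_TOT`` is
multinomial with probabilities ``(p_A, p_B, p_C, p_D)`` estimated from the
fractional molecular weight of each component of the nucleosome.

The per-event energy threshold is not a sharp value: it is modelled as a
normal distribution (default mean 17.5 eV, s.d. 5 eV) truncated below at a
physical cut-off, and every epsilon-dependent probability is computed as an
expectation over a fixed, deterministic discretization of that distribution
(:func:`threshold_nodes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, NamedTuple, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ParameterError",
    "EventProbabilities",
    "ThresholdDistribution",
    "Composition",
    "total_events",
    "threshold_nodes",
    "enumerate_compositions",
    "multinomial_weight",
]

#: default cap on the number of events per site; energies above
#: ``j_cap * epsilon_th`` (~1 keV) are clamped.  Direct ion traversals of a
#: 5 nm site reach several hundred eV, so the cap is set where the lesion
#: spectrum has already saturated in the DSB(++) category and further events
#: no longer change the classified outcome.
DEFAULT_J_CAP = 60


class ParameterError(ValueError):
    """Raised when a model parameter violates its contract."""


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class EventProbabilities:
    """First-order event-type probabilities ``(p_A, p_B, p_C, p_D)``.

    Defaults (0.2, 0.2, 0.2, 0.4) are the fractional-molecular-weight
    estimates for a nucleosome: DNA sugar-phosphate, water, DNA bases and
    histone protein respectively.  They must sum to one.
    """

    p_a: float = 0.2
    p_b: float = 0.2
    p_c: float = 0.2
    p_d: float = 0.4

    def __post_init__(self) -> None:
        for name, value in zip(("p_a", "p_b", "p_c", "p_d"), self.as_tuple()):
            _check_probability(name, value)
        total = self.p_a + self.p_b + self.p_c + self.p_d
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(
                f"event probabilities must sum to 1 (got {total!r})"
            )

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.p_a, self.p_b, self.p_c, self.p_d)


@dataclass(frozen=True)
class ThresholdDistribution:
    """Normal distribution of the per-event energy threshold (eV).

    ``sd_ev = 0`` degenerates to a point mass at ``mean_ev``.  The
    distribution is truncated below at ``lower_cut_ev`` (default 7.5 eV,
    two standard deviations under the mean) because a non-positive or very
    small threshold is unphysical -- OH-radical production itself requires
    ~13 eV.  ``n_nodes`` controls the quadrature used by
    :func:`threshold_nodes`.
    """

    mean_ev: float = 17.5
    sd_ev: float = 5.0
    lower_cut_ev: float = 7.5
    n_nodes: int = 9

    def __post_init__(self) -> None:
        if self.mean_ev <= 0:
            raise ParameterError(f"mean_ev must be positive, got {self.mean_ev!r}")
        if self.sd_ev < 0:
            raise ParameterError(f"sd_ev must be non-negative, got {self.sd_ev!r}")
        if self.lower_cut_ev <= 0:
            raise ParameterError(
                f"lower_cut_ev must be positive, got {self.lower_cut_ev!r}"
            )
        if self.n_nodes < 1:
            raise ParameterError(f"n_nodes must be >= 1, got {self.n_nodes!r}")


class Composition(NamedTuple):
    """Counts of each event type at fixed total multiplicity."""

    j_a: int
    j_b: int
    j_c: int
    j_d: int

    @property
    def j_tot(self) -> int:
        return self.j_a + self.j_b + self.j_c + self.j_d


def total_events(epsilon: float, epsilon_th: float, j_cap: int | None = None) -> int:
    """Number of damage-capable events for energy imparted ``epsilon``.

    Implements ``J_TOT = Integer(epsilon / epsilon_th)`` as the floor, so
    the count is zero below threshold.  ``j_cap``, if given, clamps the
    result (defaulting behaviour of callers uses :data:`DEFAULT_J_CAP`).
    """
    if epsilon_th <= 0:
        raise ParameterError(f"epsilon_th must be positive, got {epsilon_th!r}")
    if epsilon < 0:
        raise ParameterError(f"epsilon must be non-negative, got {epsilon!r}")
    j = int(math.floor(epsilon / epsilon_th))
    if j_cap is not None:
        j = min(j, int(j_cap))
    return j


def threshold_nodes(dist: ThresholdDistribution) -> List[Tuple[float, float]]:
    """Deterministic quadrature nodes ``(epsilon_th, weight)`` for the threshold.

    Nodes are placed symmetrically about the mean, spanning four standard
    deviations on either side, weighted by the normal density; nodes below
    ``lower_cut_ev`` are dropped and the remaining weights renormalised to
    one.  With ``sd_ev = 0`` (or a single node) this is a point mass at the
    mean.
    """
    if dist.sd_ev == 0.0 or dist.n_nodes == 1:
        return [(dist.mean_ev, 1.0)]
    n = dist.n_nodes
    span = 4.0 * dist.sd_ev
    xs = dist.mean_ev + span * (2.0 * np.arange(n) - (n - 1)) / (n - 1)
    ws = stats.norm.pdf(xs, loc=dist.mean_ev, scale=dist.sd_ev)
    keep = xs >= dist.lower_cut_ev
    xs, ws = xs[keep], ws[keep]
    if xs.size == 0:
        raise ParameterError(
            "no quadrature node survives the lower cut "
            f"(lower_cut_ev={dist.lower_cut_ev!r})"
        )
    ws = ws / ws.sum()
    return [(float(x), float(w)) for x, w in zip(xs, ws)]


def enumerate_compositions(j_tot: int) -> List[Composition]:
    """All 4-part compositions of ``j_tot`` in lexicographic order.

    The list has ``C(j_tot + 3, 3)`` entries.
    """
    if j_tot < 0:
        raise ParameterError(f"j_tot must be non-negative, got {j_tot!r}")
    out: List[Composition] = []
    for a in range(j_tot + 1):
        for b in range(j_tot - a + 1):
            for c in range(j_tot - a - b + 1):
                out.append(Composition(a, b, c, j_tot - a - b - c))
    return out


def multinomial_weight(c: Composition, p: EventProbabilities) -> float:
    """Multinomial probability of the event composition ``c``.

    ``J_TOT! / (J_A! J_B! J_C! J_D!) * p_A^J_A p_B^J_B p_C^J_C p_D^J_D``;
    over all compositions of a fixed ``j_tot`` these weights sum to one.
    """
    if min(c) < 0:
        raise ParameterError(f"composition counts must be non-negative, got {c!r}")
    coeff = math.factorial(c.j_tot) // (
        math.factorial(c.j_a)
        * math.factorial(c.j_b)
        * math.factorial(c.j_c)
        * math.factorial(c.j_d)
    )
    return (
        coeff
        * p.p_a**c.j_a
        * p.p_b**c.j_b
        * p.p_c**c.j_c
        * p.p_d**c.j_d
    )
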