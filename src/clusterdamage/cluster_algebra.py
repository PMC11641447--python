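"""Operator algebra resolving event compositions into lesion-class spectra.

Each strand-break-producing event (a direct ``A`` event, or the ``r1``
branch of a radical ``B`` event) adds one single-strand break (SSB) to the
73 bp segment.  When the k-th break is added it either lands outside the
clustering window of every existing break (probability ``q0(k)``, creating
a new isolated SSB) or attaches to an existing lesion (total probability
``2 q1(k) = 1 - q0(k)``, split equally between the two strands).  The
attachment weight is distributed equally over the existing break-bearing
lesions; attaching to a lesion upgrades it:

=============  ==========================================
target lesion  upgrade (same strand / opposite strand)
=============  ==========================================
SSB(S)         SSB(+) / DSB(S)        (equal split)
SSB(+)         SSB(++) / DSB(+)       (equal split)
SSB(++)        SSB(+++) / DSB(++)     (equal split)
SSB(+++)       SSB(+++) / DSB(++)     (equal split; >3 same-strand
                                       breaks stay grouped)
DSB(S)         DSB(+)                 (either strand)
DSB(+)         DSB(++)
DSB(++)        DSB(++)                (absorbing)
=============  ==========================================

``B`` events branch three ways: SSB with probability ``r1`` (then cluster
as above), base damage with ``r2``, nothing with ``r3``.  ``C`` events add
one base damage; ``D`` events are inert.

Because the base-damage and inert branches never touch the strand-break
state, the spectrum of any event composition factorises exactly: the break
side is the pure-A spectrum ``A_n`` at the total break count ``n``, and the
number of breaks contributed by the ``B`` events is binomial in ``r1``.
Propagation therefore only ever walks the pure-A chain (cached per
geometry), and mixtures over compositions at fixed ``J_TOT`` reduce to
closed-form trinomial weights over ``(n_breaks, n_bd)``.

The ``paper_approx`` mode reproduces the truncations used to make the
high-order closed forms tractable by hand: products of three or more ``B``
factors keep strand-break terms only to second order in ``r1`` (the dropped
weight moves to the inert branch), and beyond fourth order in the breaks the
cubic and higher attachment powers are tallied into the most complex lesion
(hence into the DSB(++) and grouped-SSB classes).  The exact numeric
propagation is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, NamedTuple, Tuple

from .core_model import (
    Composition,
    EventProbabilities,
    ParameterError,
    enumerate_compositions,
    multinomial_weight,
)

__all__ = [
    "ClusterGeometry",
    "RadicalFates",
    "LesionState",
    "LesionSpectrum",
    "EMPTY_STATE",
    "PRINTED_Q0_TABLE",
    "apply_A_step",
    "apply_B_step",
    "apply_C_step",
    "resolve_composition",
    "damage_probabilities",
    "lesion_spectrum",
    "dsb_bd_colocation",
    "marginals",
]

#: Monte-Carlo estimates of q0(J) for the 73 bp segment with a 10 bp window,
#: J = 2..7.  This printed ladder is the normative input to the algebra.
PRINTED_Q0_TABLE: Mapping[int, float] = {
    2: 0.87,
    3: 0.74,
    4: 0.60,
    5: 0.475,
    6: 0.35,
    7: 0.12,
}

_PRUNE = 1e-16  # weights below this are dropped; results are renormalised


@dataclass(frozen=True)
class RadicalFates:
    """OH-radical outcome probabilities.

    ``r1`` -- conversion to a strand break; ``r2`` -- conversion to base
    damage; ``r3`` -- no lesion.  Defaults derive from a 20%/80%
    sugar-phosphate/base interaction split combined with a 65% conversion
    probability: ``r1 = 0.2 * 0.65 = 0.13``, ``r2 = 0.8 * 0.65 = 0.52``.
    """

    r1: float = 0.13
    r2: float = 0.52
    r3: float = 0.35

    def __post_init__(self) -> None:
        for name, value in (("r1", self.r1), ("r2", self.r2), ("r3", self.r3)):
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if abs(self.r1 + self.r2 + self.r3 - 1.0) > 1e-12:
            raise ParameterError(
                f"r1 + r2 + r3 must equal 1, got {self.r1 + self.r2 + self.r3!r}"
            )

    @classmethod
    def from_interaction_split(
        cls,
        sugar_fraction: float = 0.20,
        base_fraction: float = 0.80,
        conversion: float = 0.65,
    ) -> "RadicalFates":
        """Build fates from the radical interaction split and conversion rate."""
        r1 = sugar_fraction * conversion
        r2 = base_fraction * conversion
        return cls(r1=r1, r2=r2, r3=1.0 - r1 - r2)

    def with_r2_zero(self) -> "RadicalFates":
        """Variant with the base-damage branch moved into the inert branch."""
        return RadicalFates(r1=self.r1, r2=0.0, r3=self.r2 + self.r3)


@dataclass(frozen=True)
class ClusterGeometry:
    """Segment geometry and the isolated-placement probability ladder.

    ``q0(k)`` is the probability that the k-th strand break added to the
    segment does not fall within ``window_bp`` of any existing break.  The
    first break always lands isolated, so ``q0(1) = 1``.  Beyond the last
    tabulated multiplicity the ladder is extended linearly and clipped at
    zero (for the default table it reaches zero at J = 8, consistent with
    q0 ~ 0 at large break numbers).  ``q0_constant`` overrides the ladder
    with a single value for k >= 2 -- the "symbolic" mode in which the
    closed-form expansions hold exactly.
    """

    n_bp: int = 73
    window_bp: int = 10
    q0_table: Mapping[int, float] = field(
        default_factory=lambda: dict(PRINTED_Q0_TABLE)
    )
    q0_constant: float | None = None

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ParameterError(f"n_bp must be >= 1, got {self.n_bp!r}")
        if self.window_bp < 0:
            raise ParameterError(f"window_bp must be >= 0, got {self.window_bp!r}")
        if self.q0_constant is not None and not (0.0 <= self.q0_constant <= 1.0):
            raise ParameterError(
                f"q0_constant must lie in [0, 1], got {self.q0_constant!r}"
            )
        last = None
        for j in sorted(self.q0_table):
            v = self.q0_table[j]
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"q0_table[{j}] must lie in [0, 1], got {v!r}")
            if last is not None and v > last + 1e-12:
                raise ParameterError("q0_table must be non-increasing in J")
            last = v

    @classmethod
    def constant(cls, q0_value: float, **kwargs) -> "ClusterGeometry":
        """Geometry with q0 held constant for every k >= 2 (symbolic mode)."""
        return cls(q0_constant=q0_value, **kwargs)

    def q0(self, k: int) -> float:
        """Probability the k-th break is isolated from all earlier breaks."""
        if k <= 1:
            return 1.0
        if self.q0_constant is not None:
            return self.q0_constant
        if k in self.q0_table:
            return self.q0_table[k]
        keys = sorted(self.q0_table)
        if not keys:
            raise ParameterError("empty q0_table and no q0_constant")
        if k < keys[0]:
            return self.q0_table[keys[0]]
        if len(keys) == 1:
            return self.q0_table[keys[0]]
        # linear extrapolation from the last two tabulated points, clipped
        j1, j2 = keys[-2], keys[-1]
        slope = (self.q0_table[j2] - self.q0_table[j1]) / (j2 - j1)
        return min(1.0, max(0.0, self.q0_table[j2] + slope * (k - j2)))

    def q1(self, k: int) -> float:
        """Per-strand attachment probability, ``(1 - q0(k)) / 2``."""
        return 0.5 * (1.0 - self.q0(k))

    def _cache_key(self) -> Tuple:
        return (
            self.n_bp,
            self.window_bp,
            tuple(sorted(self.q0_table.items())),
            self.q0_constant,
        )


class LesionState(NamedTuple):
    """Multiset of lesion classes on one segment.

    ``ssb_iso`` counts isolated simple SSBs (the m of SSB(Sm));
    ``ssb_plus``/``ssb_pp``/``ssb_ppp`` count same-strand clusters of
    2/3/>=4 breaks; ``dsb_s``/``dsb_plus``/``dsb_pp`` count opposite-strand
    clusters of 2/3/>=4 breaks; ``bd`` counts base damages.
    """

    ssb_iso: int = 0
    ssb_plus: int = 0
    ssb_pp: int = 0
    ssb_ppp: int = 0
    dsb_s: int = 0
    dsb_plus: int = 0
    dsb_pp: int = 0
    bd: int = 0

    @property
    def n_lesions(self) -> int:
        """Number of break-bearing lesions (base damage excluded)."""
        return (
            self.ssb_iso
            + self.ssb_plus
            + self.ssb_pp
            + self.ssb_ppp
            + self.dsb_s
            + self.dsb_plus
            + self.dsb_pp
        )

    @property
    def min_breaks(self) -> int:
        """Lower bound on constituent strand breaks (DSB++/SSB+++ hold >= 4)."""
        return (
            self.ssb_iso
            + 2 * self.ssb_plus
            + 3 * self.ssb_pp
            + 4 * self.ssb_ppp
            + 2 * self.dsb_s
            + 3 * self.dsb_plus
            + 4 * self.dsb_pp
        )

    @property
    def n_dsb(self) -> int:
        return self.dsb_s + self.dsb_plus + self.dsb_pp

    @property
    def n_ssb_lesions(self) -> int:
        return self.ssb_iso + self.ssb_plus + self.ssb_pp + self.ssb_ppp


EMPTY_STATE = LesionState()


class LesionSpectrum:
    """Normalized probability distribution over :class:`LesionState`."""

    __slots__ = ("entries",)

    def __init__(self, entries: Mapping[LesionState, float], *, check: bool = True):
        self.entries: Dict[LesionState, float] = dict(entries)
        if check:
            total = sum(self.entries.values())
            if self.entries and abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"lesion spectrum must be normalized, sums to {total!r}"
                )
            for state, prob in self.entries.items():
                if prob < -1e-15:
                    raise ParameterError(f"negative probability for {state!r}")

    def __getitem__(self, state: LesionState) -> float:
        return self.entries.get(state, 0.0)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def total(self) -> float:
        return sum(self.entries.values())

    def prob(self, predicate: Callable[[LesionState], bool]) -> float:
        """Total probability of states satisfying ``predicate``."""
        return sum(p for s, p in self.entries.items() if predicate(s))

    def expect(self, func: Callable[[LesionState], float]) -> float:
        """Expectation of ``func`` over the spectrum."""
        return sum(p * func(s) for s, p in self.entries.items())

    def total_variation(self, other: "LesionSpectrum") -> float:
        keys = set(self.entries) | set(other.entries)
        return 0.5 * sum(abs(self[k] - other[k]) for k in keys)

    def shift_bd(self, n: int) -> "LesionSpectrum":
        """Spectrum with every state's base-damage count incremented by ``n``."""
        return LesionSpectrum(
            {s._replace(bd=s.bd + n): p for s, p in self.entries.items()},
            check=False,
        )


_StateDict = Dict[LesionState, float]


def _attach_outcomes(state: LesionState) -> List[Tuple[LesionState, float]]:
    """Outcomes of attaching a new break, as fractions of the attach weight.

    The 2*q1 attachment weight is distributed equally over the existing
    break-bearing lesions; SSB-class targets then split equally between the
    same-strand and opposite-strand upgrade.
    """
    L = state.n_lesions
    w = 1.0 / L
    out: List[Tuple[LesionState, float]] = []
    if state.ssb_iso:
        f = state.ssb_iso * w * 0.5
        out.append((state._replace(ssb_iso=state.ssb_iso - 1,
                                   ssb_plus=state.ssb_plus + 1), f))
        out.append((state._replace(ssb_iso=state.ssb_iso - 1,
                                   dsb_s=state.dsb_s + 1), f))
    if state.ssb_plus:
        f = state.ssb_plus * w * 0.5
        out.append((state._replace(ssb_plus=state.ssb_plus - 1,
                                   ssb_pp=state.ssb_pp + 1), f))
        out.append((state._replace(ssb_plus=state.ssb_plus - 1,
                                   dsb_plus=state.dsb_plus + 1), f))
    if state.ssb_pp:
        f = state.ssb_pp * w * 0.5
        out.append((state._replace(ssb_pp=state.ssb_pp - 1,
                                   ssb_ppp=state.ssb_ppp + 1), f))
        out.append((state._replace(ssb_pp=state.ssb_pp - 1,
                                   dsb_pp=state.dsb_pp + 1), f))
    if state.ssb_ppp:
        f = state.ssb_ppp * w * 0.5
        out.append((state, f))  # same strand: stays in the grouped class
        out.append((state._replace(ssb_ppp=state.ssb_ppp - 1,
                                   dsb_pp=state.dsb_pp + 1), f))
    if state.dsb_s:
        out.append((state._replace(dsb_s=state.dsb_s - 1,
                                   dsb_plus=state.dsb_plus + 1),
                    state.dsb_s * w))
    if state.dsb_plus:
        out.append((state._replace(dsb_plus=state.dsb_plus - 1,
                                   dsb_pp=state.dsb_pp + 1),
                    state.dsb_plus * w))
    if state.dsb_pp:
        out.append((state, state.dsb_pp * w))  # absorbing
    return out


def _attach_most_complex(state: LesionState) -> List[Tuple[LesionState, float]]:
    # high-order approximation: the whole attachment weight targets the most
    # complex existing lesion (with its usual upgrade split), so cubic and
    # higher attachment powers tally into the DSB(++)/grouped-SSB classes
    if state.dsb_pp:
        return [(state, 1.0)]
    if state.dsb_plus:
        return [(state._replace(dsb_plus=state.dsb_plus - 1,
                                dsb_pp=state.dsb_pp + 1), 1.0)]
    if state.ssb_ppp:
        return [(state, 0.5),
                (state._replace(ssb_ppp=state.ssb_ppp - 1,
                                dsb_pp=state.dsb_pp + 1), 0.5)]
    if state.ssb_pp:
        return [(state._replace(ssb_pp=state.ssb_pp - 1,
                                ssb_ppp=state.ssb_ppp + 1), 0.5),
                (state._replace(ssb_pp=state.ssb_pp - 1,
                                dsb_pp=state.dsb_pp + 1), 0.5)]
    if state.dsb_s:
        return [(state._replace(dsb_s=state.dsb_s - 1,
                                dsb_plus=state.dsb_plus + 1), 1.0)]
    if state.ssb_plus:
        return [(state._replace(ssb_plus=state.ssb_plus - 1,
                                ssb_pp=state.ssb_pp + 1), 0.5),
                (state._replace(ssb_plus=state.ssb_plus - 1,
                                dsb_plus=state.dsb_plus + 1), 0.5)]
    return [(state._replace(ssb_iso=state.ssb_iso - 1,
                            ssb_plus=state.ssb_plus + 1), 0.5),
            (state._replace(ssb_iso=state.ssb_iso - 1,
                            dsb_s=state.dsb_s + 1), 0.5)]


def _add(d: _StateDict, state: LesionState, p: float) -> None:
    if p > _PRUNE:
        d[state] = d.get(state, 0.0) + p


def _a_step_states(entries: Mapping[LesionState, float], geom: ClusterGeometry,
                   k_fixed: int | None = None, breaks_before: int | None = None,
                   approx: bool = False) -> _StateDict:
    """One A-operator step on a weighted state dict.

    ``k_fixed`` is the ordinal of the break being added (``q0`` index); if
    ``None`` it is derived per state from the constituent break count.
    ``breaks_before`` (needed only in approx mode) is the number of breaks
    already present; it equals ``k - 1`` along the pure-A chain.
    """
    out: _StateDict = {}
    for state, p in entries.items():
        k = k_fixed if k_fixed is not None else state.min_breaks + 1
        q0 = geom.q0(k)
        isolated = state._replace(ssb_iso=state.ssb_iso + 1)
        if state.n_lesions == 0:
            _add(out, isolated, p)
            continue
        _add(out, isolated, p * q0)
        attach = 1.0 - q0
        if attach <= 0.0:
            continue
        nb = breaks_before if breaks_before is not None else state.min_breaks
        if approx and k > 4 and (nb - state.n_lesions) >= 2:
            for new_state, frac in _attach_most_complex(state):
                _add(out, new_state, p * attach * frac)
        else:
            for new_state, frac in _attach_outcomes(state):
                _add(out, new_state, p * attach * frac)
    return out


# cache of pure-A spectra A_0, A_1, ... per (geometry, mode)
_A_CACHE: Dict[Tuple, List[_StateDict]] = {}


def _pure_a_chain(geom: ClusterGeometry, approx: bool, n: int) -> List[_StateDict]:
    """Spectra of 0..n pure strand breaks (cached, extended on demand)."""
    key = (geom._cache_key(), approx)
    chain = _A_CACHE.setdefault(key, [{EMPTY_STATE: 1.0}])
    while len(chain) <= n:
        i = len(chain)  # adding the i-th break
        chain.append(
            _a_step_states(chain[i - 1], geom, k_fixed=i,
                           breaks_before=i - 1, approx=approx)
        )
    return chain


def _b_weight_map(j_b: int, fates: RadicalFates, approx: bool,
                  drop_r2: bool) -> Dict[Tuple[int, int], float]:
    """Joint weights over (breaks, base damages) produced by ``j_b`` B events.

    Exact mode: each event is an independent (r1, r2, r3) trinomial.  In
    ``paper_approx`` mode events beyond the second drop their break branch
    into the inert one (terms above second order in r1 are not kept).  With
    ``drop_r2`` the base-damage branch is removed without reassigning its
    weight (sub-normalised, conditioning on "no radical base damage").
    """
    weights: Dict[Tuple[int, int], float] = {(0, 0): 1.0}
    for step in range(1, j_b + 1):
        r1, r2, r3 = fates.r1, fates.r2, fates.r3
        if approx and step > 2:
            r3 += r1
            r1 = 0.0
        if drop_r2:
            r2 = 0.0
        nxt: Dict[Tuple[int, int], float] = {}
        for (m, u), w in weights.items():
            if r1 > 0.0:
                nxt[(m + 1, u)] = nxt.get((m + 1, u), 0.0) + w * r1
            if r2 > 0.0:
                nxt[(m, u + 1)] = nxt.get((m, u + 1), 0.0) + w * r2
            if r3 > 0.0:
                nxt[(m, u)] = nxt.get((m, u), 0.0) + w * r3
        weights = nxt
    return weights


def _assemble(weight_map: Mapping[Tuple[int, int], float],
              geom: ClusterGeometry, approx: bool,
              renormalize: bool = True) -> LesionSpectrum:
    """Sum ``w(n, bd) * A_n`` with the base-damage shift applied."""
    max_n = max((n for n, _ in weight_map), default=0)
    chain = _pure_a_chain(geom, approx, max_n)
    mixed: _StateDict = {}
    for (n, bd), w in weight_map.items():
        if w <= _PRUNE:
            continue
        for state, p in chain[n].items():
            key = state._replace(bd=bd) if bd else state
            mixed[key] = mixed.get(key, 0.0) + w * p
    if renormalize and mixed:
        total = sum(mixed.values())
        if total > 0:
            mixed = {s: p / total for s, p in mixed.items()}
    return LesionSpectrum(mixed, check=renormalize)


# ---------------------------------------------------------------------------
# public operator steps
# ---------------------------------------------------------------------------


def apply_A_step(spec: LesionSpectrum, geom: ClusterGeometry,
                 k: int | None = None) -> LesionSpectrum:
    """Apply one direct strand-break (``A``) operator to a spectrum.

    ``k`` is the total SSB count after this addition, used for the
    ``q0(k)`` lookup; if omitted it is derived per state from the
    constituent break count.
    """
    if k is not None and k < 1:
        raise ParameterError(f"k must be >= 1, got {k!r}")
    out = _a_step_states(spec.entries, geom, k_fixed=k)
    total = sum(out.values())
    return LesionSpectrum({s: p / total for s, p in out.items()})


def apply_B_step(spec: LesionSpectrum, geom: ClusterGeometry,
                 fates: RadicalFates, k: int | None = None,
                 mode: str = "exact", b_index: int = 1) -> LesionSpectrum:
    """Apply one OH-radical (``B``) operator: r1 break / r2 BD / r3 nothing.

    In ``paper_approx`` mode a step with ``b_index > 2`` drops its break
    branch into the inert one (the r1^3-and-above truncation).
    """
    _check_mode(mode)
    r1, r2, r3 = fates.r1, fates.r2, fates.r3
    if mode == "paper_approx" and b_index > 2:
        r3 += r1
        r1 = 0.0
    out: _StateDict = {}
    if r1 > 0.0:
        for state, p in _a_step_states(spec.entries, geom, k_fixed=k).items():
            _add(out, state, p * r1)
    for state, p in spec.entries.items():
        if r2 > 0.0:
            _add(out, state._replace(bd=state.bd + 1), p * r2)
        if r3 > 0.0:
            _add(out, state, p * r3)
    total = sum(out.values())
    return LesionSpectrum({s: p / total for s, p in out.items()})


def apply_C_step(spec: LesionSpectrum) -> LesionSpectrum:
    """Apply one direct base-damage (``C``) operator: BD count + 1."""
    return spec.shift_bd(1)


def _check_mode(mode: str) -> None:
    if mode not in ("exact", "paper_approx"):
        raise ParameterError(f"mode must be 'exact' or 'paper_approx', got {mode!r}")


def resolve_composition(c: Composition | Tuple[int, int, int, int],
                        geom: ClusterGeometry, fates: RadicalFates,
                        mode: str = "exact",
                        _drop_r2: bool = False) -> LesionSpectrum:
    """Resolve an event composition into a lesion-class spectrum.

    Equivalent to applying ``j_a`` A-steps, then ``j_b`` B-steps, then
    ``j_c`` C-steps (``D`` events are inert; the heterogeneous order of the
    factors does not affect the outcome).  With ``_drop_r2=True`` the
    radical base-damage branch is removed without reassigning its weight,
    yielding the sub-normalised spectrum used by :func:`dsb_bd_colocation`.
    """
    c = Composition(*c)
    if min(c) < 0:
        raise ParameterError(f"composition counts must be non-negative, got {c!r}")
    _check_mode(mode)
    approx = mode == "paper_approx"
    weight_map = {
        (c.j_a + m, u + c.j_c): w
        for (m, u), w in _b_weight_map(c.j_b, fates, approx, _drop_r2).items()
    }
    return _assemble(weight_map, geom, approx, renormalize=not _drop_r2)


# ---------------------------------------------------------------------------
# marginal damage probabilities
# ---------------------------------------------------------------------------


def marginals(spec: LesionSpectrum) -> Dict[str, float]:
    """Per-category marginal probabilities and expected counts of a spectrum.

    Reported lesion classes fold SSB(+++) into the grouped SSB(++)
    category.  ``ratio_*`` entries use per-lesion expected counts; the
    complex fractions are expected-count fractions within the class.
    Ratios are NaN when their denominator vanishes.
    """
    acc = dict.fromkeys((
        "p_ssb_s1", "p_ssb_s2", "p_ssb_s3plus", "p_ssb_plus", "p_ssb_pp",
        "p_dsb_s", "p_dsb_plus", "p_dsb_pp", "p_dsb_any", "p_dsb_no_bd",
        "p_bd_1", "p_bd_2", "p_bd_3", "p_bd_gt3", "p_bd_any",
        "e_ssb_iso", "e_ssb_plus", "e_ssb_pp",
        "e_dsb_s", "e_dsb_plus", "e_dsb_pp",
        "e_ssb_breaks", "e_bd",
    ), 0.0)
    for s, p in spec.items():
        if s.ssb_iso == 1:
            acc["p_ssb_s1"] += p
        elif s.ssb_iso == 2:
            acc["p_ssb_s2"] += p
        elif s.ssb_iso >= 3:
            acc["p_ssb_s3plus"] += p
        if s.ssb_plus >= 1:
            acc["p_ssb_plus"] += p
        if s.ssb_pp + s.ssb_ppp >= 1:
            acc["p_ssb_pp"] += p
        if s.dsb_s >= 1:
            acc["p_dsb_s"] += p
        if s.dsb_plus >= 1:
            acc["p_dsb_plus"] += p
        if s.dsb_pp >= 1:
            acc["p_dsb_pp"] += p
        ndsb = s.dsb_s + s.dsb_plus + s.dsb_pp
        if ndsb >= 1:
            acc["p_dsb_any"] += p
            if s.bd == 0:
                acc["p_dsb_no_bd"] += p
        if s.bd == 1:
            acc["p_bd_1"] += p
        elif s.bd == 2:
            acc["p_bd_2"] += p
        elif s.bd == 3:
            acc["p_bd_3"] += p
        elif s.bd > 3:
            acc["p_bd_gt3"] += p
        if s.bd >= 1:
            acc["p_bd_any"] += p
        acc["e_ssb_iso"] += p * s.ssb_iso
        acc["e_ssb_plus"] += p * s.ssb_plus
        acc["e_ssb_pp"] += p * (s.ssb_pp + s.ssb_ppp)
        acc["e_dsb_s"] += p * s.dsb_s
        acc["e_dsb_plus"] += p * s.dsb_plus
        acc["e_dsb_pp"] += p * s.dsb_pp
        acc["e_ssb_breaks"] += p * (
            s.ssb_iso + 2 * s.ssb_plus + 3 * s.ssb_pp + 4 * s.ssb_ppp
        )
        acc["e_bd"] += p * s.bd
    acc["e_dsb_total"] = acc["e_dsb_s"] + acc["e_dsb_plus"] + acc["e_dsb_pp"]
    acc["e_ssb_lesions"] = acc["e_ssb_iso"] + acc["e_ssb_plus"] + acc["e_ssb_pp"]
    nssb = acc["e_ssb_lesions"]
    ndsb = acc["e_dsb_total"]
    acc["ratio_dsb_ssb"] = ndsb / nssb if nssb > 0 else math.nan
    acc["ratio_bd_ssb"] = acc["e_bd"] / nssb if nssb > 0 else math.nan
    acc["frac_complex_dsb"] = (
        (acc["e_dsb_plus"] + acc["e_dsb_pp"]) / ndsb if ndsb > 0 else math.nan
    )
    acc["frac_complex_ssb"] = (
        (acc["e_ssb_plus"] + acc["e_ssb_pp"]) / nssb if nssb > 0 else math.nan
    )
    return acc


def _mixture_weight_map(j_tot: int, p: EventProbabilities, fates: RadicalFates,
                        mode: str, drop_r2: bool
                        ) -> Dict[Tuple[int, int], float]:
    """Weights over (breaks, base damages) for the composition mixture.

    In exact mode every event is independently a break
    (``p_A + p_B r1``), a base damage (``p_C + p_B r2``) or nothing, so the
    weights are a closed-form trinomial.  The approx-mode truncation makes
    the B events order-dependent, so there the mixture runs over (j_A, j_B)
    pairs with the per-pair B weights.
    """
    approx = mode == "paper_approx"
    if not approx:
        beta = p.p_a + p.p_b * fates.r1
        gamma = p.p_c + (0.0 if drop_r2 else p.p_b * fates.r2)
        delta = p.p_d + p.p_b * fates.r3
        out: Dict[Tuple[int, int], float] = {}
        for n in range(j_tot + 1):
            for u in range(j_tot - n + 1):
                k = j_tot - n - u
                w = (
                    math.comb(j_tot, n) * math.comb(j_tot - n, u)
                    * beta**n * gamma**u * delta**k
                )
                if w > _PRUNE:
                    out[(n, u)] = w
        return out
    out = {}
    pcd = p.p_c + p.p_d
    for a in range(j_tot + 1):
        for b in range(j_tot - a + 1):
            rest = j_tot - a - b
            w_ab = (
                math.comb(j_tot, a) * math.comb(j_tot - a, b)
                * p.p_a**a * p.p_b**b * pcd**rest
            )
            if w_ab <= _PRUNE:
                continue
            frac_c = p.p_c / pcd if pcd > 0 else 0.0
            bw = _b_weight_map(b, fates, approx=True, drop_r2=drop_r2)
            for cc in range(rest + 1):
                w_c = math.comb(rest, cc) * frac_c**cc * (1 - frac_c)**(rest - cc)
                if w_c <= _PRUNE:
                    continue
                for (m, u), w_b in bw.items():
                    key = (a + m, u + cc)
                    out[key] = out.get(key, 0.0) + w_ab * w_c * w_b
    return out


def lesion_spectrum(j_tot: int, p: EventProbabilities, geom: ClusterGeometry,
                    fates: RadicalFates, mode: str = "exact",
                    _drop_r2: bool = False) -> LesionSpectrum:
    """Full lesion-class spectrum at fixed ``j_tot`` (compositions mixed)."""
    if j_tot < 0:
        raise ParameterError(f"j_tot must be non-negative, got {j_tot!r}")
    _check_mode(mode)
    wm = _mixture_weight_map(j_tot, p, fates, mode, _drop_r2)
    return _assemble(wm, geom, mode == "paper_approx",
                     renormalize=not _drop_r2)


def damage_probabilities(j_tot: int, p: EventProbabilities,
                         geom: ClusterGeometry, fates: RadicalFates,
                         mode: str = "exact") -> Dict[str, float]:
    """Marginal damage probabilities at fixed total event count ``j_tot``.

    Equals the multinomial-weighted sum of resolved compositions of
    ``j_tot``; returns the per-category marginals (see :func:`marginals`).
    """
    return marginals(lesion_spectrum(j_tot, p, geom, fates, mode))


def dsb_bd_colocation(j_tot: int, p: EventProbabilities, geom: ClusterGeometry,
                      fates: RadicalFates, mode: str = "exact") -> Dict[str, float]:
    """DSB probability with and without co-located base damage.

    Returns ``p_dsb`` (full parameters), ``p_dsb_r2_to_r3`` (radical BD
    branch folded into the inert branch -- provably equal to ``p_dsb``
    since neither branch produces breaks, reported for completeness),
    ``p_dsb_no_radical_bd`` (the sub-normalised estimate obtained by
    zeroing ``r2`` without reassigning its weight, i.e. the joint
    probability of at least one DSB and no radical-induced BD), and
    ``p_dsb_no_bd`` (the direct marginal of at least one DSB with no BD of
    either origin).
    """
    full = lesion_spectrum(j_tot, p, geom, fates, mode)
    m = marginals(full)
    variant = lesion_spectrum(j_tot, p, geom, fates.with_r2_zero(), mode)
    sub = lesion_spectrum(j_tot, p, geom, fates, mode, _drop_r2=True)
    return {
        "p_dsb": m["p_dsb_any"],
        "p_dsb_r2_to_r3": marginals(variant)["p_dsb_any"],
        "p_dsb_no_radical_bd": sub.prob(lambda s: s.n_dsb >= 1),
        "p_dsb_no_bd": m["p_dsb_no_bd"],
    }
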