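"""Dyadic parental-investment game behind a veil of ignorance over parentage.

Two co-breeding mothers have each produced one offspring into a communal
litter.  Offspring enter postnatal care at initial sizes ``x_hi >= x_lo``
(prenatal investment); the mother who tends an offspring adds postnatal
effort ``y``, giving it survival ``b(x + y)`` at a personal fecundity cost
``c(k, y)``.  The condition parameter ``k > 0`` sets how steeply the cost of
care rises with effort, so a *lower* ``k`` means a mother in better
condition.  The default payoff family is

    b(t) = t * (1 - t / 2)   on 0 <= t <= 1,
    c(k, y) = k * y**2,

with total investment capped at ``b``'s domain (``x + y <= 1``).

When birth is perfectly synchronous, a veil of ignorance hides parentage:
each of the two pups is a mother's own with probability one half, and a
relative's (coefficient of relatedness ``r``) otherwise, so she values every
pup at the expected relatedness ``(1 + r) / 2``.  Without the veil she
values her own pup at 1 and the other mother's at ``r``.

For a dyad there are exactly two care assignments.  By convention ``"s1"``
has the first-listed mother tending the smaller offspring ``x_lo`` and
``"s2"`` has her tending ``x_hi``; when the first mother is the one in
worse condition (higher ``k``), ``s1``/``s2`` correspond to the outcomes
labelled 1/2 in the zone diagrams.  Because each mother's objective is
separable in her own effort, the profile of individually optimal efforts is
the Nash equilibrium of the care game.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "DomainError",
    "ParameterError",
    "DisagreementError",
    "Mode",
    "BenefitSpec",
    "CostSpec",
    "MotherParams",
    "OffspringParams",
    "Dyad",
    "make_dyad",
    "Assignment",
    "InformationState",
    "CareEquilibrium",
    "Classification",
    "ZoneGrid",
    "eval_benefit",
    "eval_cost",
    "care_weight",
    "optimal_investment",
    "solve_equilibrium",
    "mother_fitness",
    "classify_preferences",
    "scan_zone_grid",
    "variance_trajectory",
]

#: Fitness differences smaller than this are treated as ties ("boundary").
DEFAULT_TIE_TOL = 1e-9


class DomainError(ValueError):
    """An investment or payoff argument fell outside the model's domain."""


class ParameterError(ValueError):
    """A structural parameter (grid bounds, k, x, r, ...) is invalid."""


class DisagreementError(ValueError):
    """A mutually preferred outcome was requested where none exists."""


class Mode(str, enum.Enum):
    VEIL = "veil"
    NO_VEIL = "no_veil"


@dataclass(frozen=True)
class BenefitSpec:
    """Offspring survival as a function of total (pre + post natal) investment.

    ``family="quadratic"`` is ``b(t) = t (1 - t/2)``; ``family="custom"``
    evaluates ``func`` instead.  ``domain_max`` caps total investment:
    the benefit is undefined beyond it and care is constrained so that
    ``x + y <= domain_max``.
    """

    family: str = "quadratic"
    func: Optional[Callable[[float], float]] = None
    domain_max: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("quadratic", "custom"):
            raise ParameterError(f"unknown benefit family {self.family!r}")
        if self.family == "custom" and self.func is None:
            raise ParameterError("custom benefit family requires func")
        if not self.domain_max > 0:
            raise ParameterError("domain_max must be positive")

    def __call__(self, total_investment: float) -> float:
        return eval_benefit(self, total_investment)


@dataclass(frozen=True)
class CostSpec:
    """Cost of postnatal effort ``y`` to a mother with condition parameter ``k``.

    The default family is ``c(k, y) = k y**2`` (accelerating in effort,
    steeper for mothers in worse condition).
    """

    family: str = "quadratic_in_y"
    func: Optional[Callable[[float, float], float]] = None

    def __post_init__(self) -> None:
        if self.family not in ("quadratic_in_y", "custom"):
            raise ParameterError(f"unknown cost family {self.family!r}")
        if self.family == "custom" and self.func is None:
            raise ParameterError("custom cost family requires func")

    def __call__(self, k: float, y: float) -> float:
        return eval_cost(self, k, y)


@dataclass(frozen=True)
class MotherParams:
    id: str
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ParameterError(f"mother {self.id!r}: k must be > 0, got {self.k}")


@dataclass(frozen=True)
class OffspringParams:
    id: str
    x: float
    parent_id: Optional[str] = None
    domain_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.x < self.domain_max:
            raise ParameterError(
                f"offspring {self.id!r}: x must lie in (0, {self.domain_max}), got {self.x}"
            )


@dataclass(frozen=True)
class InformationState:
    mode: Mode = Mode.VEIL
    r: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError(f"relatedness r must lie in [0, 1], got {self.r}")


@dataclass(frozen=True)
class Assignment:
    """A bijection mother id -> offspring id (one of the dyad's two)."""

    name: str
    mapping: tuple[tuple[str, str], ...]

    def offspring_of(self, mother_id: str) -> str:
        for m, o in self.mapping:
            if m == mother_id:
                return o
        raise KeyError(mother_id)

    def carer_of(self, offspring_id: str) -> str:
        for m, o in self.mapping:
            if o == offspring_id:
                return m
        raise KeyError(offspring_id)


@dataclass(frozen=True)
class Dyad:
    """Two mothers and two offspring; offspring sorted so ``x_hi >= x_lo``."""

    mothers: tuple[MotherParams, MotherParams]
    offspring: tuple[OffspringParams, OffspringParams]
    benefit: BenefitSpec = field(default_factory=BenefitSpec)
    cost: CostSpec = field(default_factory=CostSpec)

    def __post_init__(self) -> None:
        if len(self.mothers) != 2 or len(self.offspring) != 2:
            raise ParameterError("a dyad has exactly two mothers and two offspring")
        hi, lo = sorted(self.offspring, key=lambda o: -o.x)
        object.__setattr__(self, "offspring", (hi, lo))

    @property
    def x_hi(self) -> OffspringParams:
        return self.offspring[0]

    @property
    def x_lo(self) -> OffspringParams:
        return self.offspring[1]

    def assignments(self) -> dict[str, Assignment]:
        """The two possible care assignments.

        ``s1``: first mother tends the smaller offspring; ``s2``: first
        mother tends the larger.
        """
        m1, m2 = self.mothers
        return {
            "s1": Assignment("s1", ((m1.id, self.x_lo.id), (m2.id, self.x_hi.id))),
            "s2": Assignment("s2", ((m1.id, self.x_hi.id), (m2.id, self.x_lo.id))),
        }

    def own_care_name(self) -> Optional[str]:
        """Which of s1/s2 has each mother tending her own offspring (if parented)."""
        if any(o.parent_id is None for o in self.offspring):
            return None
        for name, a in self.assignments().items():
            if all(
                next(o for o in self.offspring if o.id == a.offspring_of(m.id)).parent_id
                == m.id
                for m in self.mothers
            ):
                return name
        return None


def make_dyad(
    k1: float,
    k2: float,
    x_hi: float,
    x_lo: float,
    parented: bool = False,
    mother1_owns: Optional[str] = None,
    benefit: Optional[BenefitSpec] = None,
    cost: Optional[CostSpec] = None,
) -> Dyad:
    """Convenience constructor from scalar parameters.

    With ``parented=True``, ``mother1_owns`` is ``"hi"`` or ``"lo"``.
    """
    benefit = benefit if benefit is not None else BenefitSpec()
    cost = cost if cost is not None else CostSpec()
    p_hi = p_lo = None
    if parented:
        if mother1_owns not in ("hi", "lo"):
            raise ParameterError("mother1_owns must be 'hi' or 'lo' when parented")
        p_hi, p_lo = ("m1", "m2") if mother1_owns == "hi" else ("m2", "m1")
    return Dyad(
        mothers=(MotherParams("m1", k1), MotherParams("m2", k2)),
        offspring=(
            OffspringParams("o_hi", x_hi, parent_id=p_hi, domain_max=benefit.domain_max),
            OffspringParams("o_lo", x_lo, parent_id=p_lo, domain_max=benefit.domain_max),
        ),
        benefit=benefit,
        cost=cost,
    )


@dataclass(frozen=True)
class CareEquilibrium:
    """Equilibrium of the care game under one assignment.

    ``y`` maps mother id to her postnatal effort, ``t`` maps offspring id
    to its total investment ``x + y(carer)``, ``survival`` to ``b(t)``, and
    ``fitness`` maps mother id to her expected (inclusive) fitness.
    """

    assignment: Assignment
    y: dict[str, float]
    t: dict[str, float]
    survival: dict[str, float]
    fitness: dict[str, float]


@dataclass(frozen=True)
class Classification:
    """Outcome of comparing both mothers' payoffs across the two assignments.

    ``label`` is ``agreement_s1``/``agreement_s2`` when both mothers
    strictly prefer the same assignment, ``disagreement`` when their
    preferences oppose, and ``boundary`` when any comparison falls within
    the tie tolerance.  ``own_care_assignment`` names which of s1/s2 is
    own-care when parentage is known.
    """

    label: str
    preferred: dict[str, Optional[str]]
    equilibria: dict[str, CareEquilibrium]
    own_care_assignment: Optional[str] = None

    @property
    def agreed_assignment(self) -> Optional[str]:
        if self.label.startswith("agreement_"):
            return self.label.removeprefix("agreement_")
        return None


@dataclass(frozen=True)
class ZoneGrid:
    """Zone classification over a grid of parental (dk) and offspring (dx) asymmetries."""

    k_mean: float
    x_mean: float
    dk_values: np.ndarray
    dx_values: np.ndarray
    labels: np.ndarray  # shape (len(dx_values), len(dk_values)), dtype object
    info: InformationState

    def label_at(self, dk: float, dx: float) -> str:
        i = int(np.argmin(np.abs(self.dx_values - dx)))
        j = int(np.argmin(np.abs(self.dk_values - dk)))
        if not (
            math.isclose(self.dx_values[i], dx, abs_tol=1e-12)
            and math.isclose(self.dk_values[j], dk, abs_tol=1e-12)
        ):
            raise ParameterError(f"(dk={dk}, dx={dx}) is not a grid node")
        return str(self.labels[i, j])

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "dk": float(dk),
                "dx": float(dx),
                "k1": self.k_mean + dk / 2,
                "k2": self.k_mean - dk / 2,
                "x_hi": self.x_mean + dx / 2,
                "x_lo": self.x_mean - dx / 2,
                "label": str(self.labels[i, j]),
            }
            for i, dx in enumerate(self.dx_values)
            for j, dk in enumerate(self.dk_values)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# payoff primitives


def eval_benefit(spec: BenefitSpec, total_investment: float) -> float:
    """Survival-scale benefit ``b(total_investment)``."""
    t = float(total_investment)
    if not 0.0 <= t <= spec.domain_max + 1e-12:
        raise DomainError(
            f"total investment {t} outside benefit domain [0, {spec.domain_max}]"
        )
    t = min(t, spec.domain_max)
    if spec.family == "quadratic":
        return t * (1.0 - t / 2.0)
    return float(spec.func(t))


def eval_cost(spec: CostSpec, k: float, y: float) -> float:
    """Fecundity cost ``c(k, y)`` of postnatal effort ``y``."""
    if not k > 0:
        raise DomainError(f"cost parameter k must be > 0, got {k}")
    if y < 0:
        raise DomainError(f"postnatal effort y must be >= 0, got {y}")
    if spec.family == "quadratic_in_y":
        return k * y * y
    return float(spec.func(k, y))


def care_weight(info: InformationState, relationship: str = "own") -> float:
    """Expected valuation weight a mother places on an offspring's survival.

    Behind the veil, either pup is hers with probability one half, so every
    pup is worth ``(1 + r) / 2`` regardless of ``relationship``.  Without
    the veil her own pup ("own") is worth 1 and the other mother's
    ("other") is worth ``r``.
    """
    if relationship not in ("own", "other"):
        raise ParameterError(f"relationship must be 'own' or 'other', got {relationship!r}")
    if info.mode is Mode.VEIL:
        return (1.0 + info.r) / 2.0
    return 1.0 if relationship == "own" else info.r


def optimal_investment(
    x: float,
    k: float,
    w: float,
    benefit: Optional[BenefitSpec] = None,
    cost: Optional[CostSpec] = None,
) -> float:
    """Effort ``y*`` maximising ``w b(x + y) - c(k, y)`` s.t. ``0 <= y <= cap - x``.

    For the default quadratic families the interior first-order condition
    gives the closed form ``y* = w (1 - x) / (w + 2 k)`` (clipped to the
    constraints); custom families fall back to bounded numeric maximisation.
    """
    benefit = benefit if benefit is not None else BenefitSpec()
    cost = cost if cost is not None else CostSpec()
    if not 0 < x < benefit.domain_max + 1e-12:
        raise DomainError(f"x must lie in (0, {benefit.domain_max}), got {x}")
    if not k > 0:
        raise DomainError(f"k must be > 0, got {k}")
    if not 0.0 <= w <= 1.0:
        raise DomainError(f"valuation weight must lie in [0, 1], got {w}")
    if w == 0.0:
        return 0.0
    cap = benefit.domain_max - x
    if (
        benefit.family == "quadratic"
        and cost.family == "quadratic_in_y"
        and benefit.domain_max == 1.0
    ):
        # stationarity of w*(x+y)*(1-(x+y)/2) - k*y^2 in y
        y = w * (1.0 - x) / (w + 2.0 * k)
        return float(min(max(y, 0.0), cap))
    return _numeric_optimal(x, k, w, benefit, cost)


def _numeric_optimal(x, k, w, benefit, cost):
    from scipy.optimize import minimize_scalar

    cap = benefit.domain_max - x
    if cap <= 0:
        return 0.0
    res = minimize_scalar(
        lambda y: -(w * eval_benefit(benefit, x + y) - eval_cost(cost, k, y)),
        bounds=(0.0, cap),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# equilibrium and preference structure


def _valuation(dyad: Dyad, info: InformationState, mother: MotherParams,
               offspring: OffspringParams) -> float:
    if info.mode is Mode.VEIL:
        return care_weight(info, "own")
    if offspring.parent_id is None:
        raise ParameterError(
            "no-veil analysis requires parent_id on every offspring"
        )
    return care_weight(info, "own" if offspring.parent_id == mother.id else "other")


def solve_equilibrium(
    dyad: Dyad, assignment: Assignment, info: InformationState
) -> CareEquilibrium:
    """Equilibrium efforts, totals, survivals and fitnesses under one assignment.

    Each mother's payoff is separable in her own effort, so the profile of
    individually optimal efforts (each maximising her valuation-weighted
    benefit to the offspring she tends, net of her own cost) is the unique
    Nash equilibrium; best-response iteration converges to it in one step.
    """
    by_id = {o.id: o for o in dyad.offspring}
    y: dict[str, float] = {}
    t: dict[str, float] = {}
    for m in dyad.mothers:
        off = by_id[assignment.offspring_of(m.id)]
        w = _valuation(dyad, info, m, off)
        y_m = optimal_investment(off.x, m.k, w, dyad.benefit, dyad.cost)
        y[m.id] = y_m
        t[off.id] = off.x + y_m
    survival = {oid: eval_benefit(dyad.benefit, tv) for oid, tv in t.items()}
    fitness = {}
    for m in dyad.mothers:
        total = sum(
            _valuation(dyad, info, m, by_id[oid]) * s for oid, s in survival.items()
        )
        fitness[m.id] = total - eval_cost(dyad.cost, m.k, y[m.id])
    return CareEquilibrium(assignment=assignment, y=y, t=t, survival=survival,
                           fitness=fitness)


def mother_fitness(equilibrium: CareEquilibrium) -> tuple[float, ...]:
    """Per-mother expected fitness, in the dyad's mother order."""
    return tuple(equilibrium.fitness[m] for m, _ in equilibrium.assignment.mapping)


def classify_preferences(
    dyad: Dyad, info: InformationState, tie_tol: float = DEFAULT_TIE_TOL
) -> Classification:
    """Compare each mother's equilibrium fitness across the two assignments.

    Under the veil the assignments are the two ways of splitting the litter;
    without the veil they are own-care versus exchange (parentage required).
    """
    assignments = dyad.assignments()
    eqs = {name: solve_equilibrium(dyad, a, info) for name, a in assignments.items()}
    preferred: dict[str, Optional[str]] = {}
    any_tie = False
    for m in dyad.mothers:
        d = eqs["s1"].fitness[m.id] - eqs["s2"].fitness[m.id]
        if abs(d) <= tie_tol:
            preferred[m.id] = None
            any_tie = True
        else:
            preferred[m.id] = "s1" if d > 0 else "s2"
    if any_tie:
        label = "boundary"
    else:
        choices = set(preferred.values())
        label = f"agreement_{choices.pop()}" if len(choices) == 1 else "disagreement"
    return Classification(
        label=label,
        preferred=preferred,
        equilibria=eqs,
        own_care_assignment=dyad.own_care_name(),
    )


def scan_zone_grid(
    k_mean: float = 1.0,
    x_mean: float = 0.2,
    dk_max: float = 1.5,
    dx_max: float = 0.3,
    resolution: int = 31,
    info: Optional[InformationState] = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ZoneGrid:
    """Classify preferences on a (dk, dx) asymmetry grid at fixed means.

    Node (dk, dx) is the dyad with ``k1 = k_mean + dk/2`` (the worse-
    condition mother listed first), ``k2 = k_mean - dk/2``, ``x_hi = x_mean
    + dx/2`` and ``x_lo = x_mean - dx/2``.
    """
    info = info if info is not None else InformationState(Mode.VEIL, 0.0)
    if resolution < 2:
        raise ParameterError("resolution must be >= 2")
    if not k_mean - dk_max / 2 > 0:
        raise ParameterError(
            f"k_mean - dk_max/2 must stay positive (k_mean={k_mean}, dk_max={dk_max})"
        )
    if not (0 < x_mean - dx_max / 2 and x_mean + dx_max / 2 < 1):
        raise ParameterError(
            f"offspring sizes must stay inside (0, 1) (x_mean={x_mean}, dx_max={dx_max})"
        )
    dk_values = np.linspace(0.0, dk_max, resolution)
    dx_values = np.linspace(0.0, dx_max, resolution)
    labels = np.empty((resolution, resolution), dtype=object)
    for i, dx in enumerate(dx_values):
        for j, dk in enumerate(dk_values):
            if dx == 0.0 and dk == 0.0:
                labels[i, j] = "boundary"
                continue
            x_hi = x_mean + dx / 2
            x_lo = max(x_mean - dx / 2, 1e-9)
            dyad = make_dyad(k_mean + dk / 2, k_mean - dk / 2, x_hi, x_lo)
            labels[i, j] = classify_preferences(dyad, info, tie_tol).label
    return ZoneGrid(k_mean, x_mean, dk_values, dx_values, labels, info)


def variance_trajectory(
    dyad: Dyad,
    info: InformationState,
    outcome_policy: str,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> tuple[float, float]:
    """Offspring-size inequality before and after postnatal care.

    Returns the population variance (divide by n = 2) of the two initial
    sizes and of the two equilibrium totals under the named outcome.
    ``equal_mixture`` averages the two outcomes' post-care variances
    (conflict resolved either way with equal probability);
    ``mutually_preferred`` requires the dyad to sit in a zone of agreement.
    """
    policies = ("forced_s1", "forced_s2", "equal_mixture", "mutually_preferred")
    if outcome_policy not in policies:
        raise ParameterError(f"outcome_policy must be one of {policies}")
    xs = np.array([o.x for o in dyad.offspring])
    pre = float(np.var(xs))
    eqs = {
        name: solve_equilibrium(dyad, a, info)
        for name, a in dyad.assignments().items()
    }
    post_var = {
        name: float(np.var(np.array(list(eq.t.values())))) for name, eq in eqs.items()
    }
    if outcome_policy == "forced_s1":
        post = post_var["s1"]
    elif outcome_policy == "forced_s2":
        post = post_var["s2"]
    elif outcome_policy == "equal_mixture":
        post = 0.5 * (post_var["s1"] + post_var["s2"])
    else:
        cls = classify_preferences(dyad, info, tie_tol)
        if cls.agreed_assignment is None:
            raise DisagreementError(
                "no mutually preferred outcome: dyad is not in a zone of agreement "
                f"(classification: {cls.label})"
            )
        post = post_var[cls.agreed_assignment]
    return pre, post
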