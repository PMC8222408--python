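"""Kin-selected exchange of offspring without a veil of ignorance.

When parentage is known, a mother weights her own offspring's survival at 1
and her co-breeder's at the coefficient of relatedness ``r``.  "Exchange"
is the assignment in which each mother tends the *other* mother's
offspring; it is mutually agreeable when both mothers' inclusive fitness is
strictly higher under exchange than under own-care, with each mother
investing optimally given her valuation of the pup she tends.

At ``r = 0`` own-care is always preferred.  As ``r`` rises, exchange can
become agreeable, but only for high relatedness and large initial size
asymmetries between the young: this module locates the minimal such ``r``
by coarse scan plus bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    Dyad,
    InformationState,
    Mode,
    ParameterError,
    make_dyad,
    solve_equilibrium,
)

__all__ = [
    "ThresholdResult",
    "parented_dyad",
    "exchange_mutually_preferred",
    "exchange_threshold",
]

OWNER_CONFIGS = ("superior_owns_larger", "inferior_owns_larger")


@dataclass(frozen=True)
class ThresholdResult:
    """Minimal relatedness at which exchange becomes mutually agreeable.

    ``r_star`` is ``None`` when exchange is never preferred on [0, 1].
    ``crossings`` lists every preference flip found by the coarse scan; a
    single entry means the preference is monotone in ``r`` on the scan.
    """

    r_star: Optional[float]
    search_tol: float
    crossings: tuple[float, ...] = ()

    @property
    def monotone(self) -> bool:
        return len(self.crossings) <= 1


def parented_dyad(
    x_hi: float,
    x_lo: float,
    k_sup: float,
    k_inf: float,
    owner_config: str = "superior_owns_larger",
) -> Dyad:
    """Dyad with parentage links for the no-veil kin analysis.

    ``k_sup < k_inf`` name the better- and worse-condition mothers (they
    are not reordered; pass them as intended).  ``owner_config`` says which
    mother bore the larger offspring.  The superior mother is listed first.
    """
    if owner_config not in OWNER_CONFIGS:
        raise ParameterError(f"owner_config must be one of {OWNER_CONFIGS}")
    owns = "hi" if owner_config == "superior_owns_larger" else "lo"
    return make_dyad(k_sup, k_inf, x_hi, x_lo, parented=True, mother1_owns=owns)


def exchange_mutually_preferred(dyad: Dyad, r: float) -> bool:
    """True iff both mothers strictly prefer exchange over own-care at relatedness ``r``."""
    own_name = dyad.own_care_name()
    if own_name is None:
        raise ParameterError("exchange analysis requires a fully parented dyad")
    info = InformationState(Mode.NO_VEIL, r)
    assignments = dyad.assignments()
    ex_name = "s2" if own_name == "s1" else "s1"
    f_own = solve_equilibrium(dyad, assignments[own_name], info).fitness
    f_ex = solve_equilibrium(dyad, assignments[ex_name], info).fitness
    return all(f_ex[m.id] > f_own[m.id] for m in dyad.mothers)


def exchange_threshold(
    x_hi: float,
    x_lo: float,
    k_sup: float,
    k_inf: float,
    owner_config: str = "superior_owns_larger",
    tol: float = 1e-4,
    scan_step: float = 0.01,
) -> ThresholdResult:
    """Smallest ``r`` in [0, 1] at which exchange is mutually agreeable.

    A coarse scan at ``scan_step`` brackets every preference flip; the
    first False->True bracket is then bisected to ``tol``.  If the scan
    finds no True value the result's ``r_star`` is ``None``; if it finds
    more than one flip, all crossing points are reported alongside the
    first threshold.
    """
    if not tol > 0:
        raise ParameterError("tol must be positive")
    dyad = parented_dyad(x_hi, x_lo, k_sup, k_inf, owner_config)
    rs = np.arange(0.0, 1.0 + scan_step / 2, scan_step)
    rs[-1] = min(rs[-1], 1.0)
    flags = [exchange_mutually_preferred(dyad, float(r)) for r in rs]
    crossings = []
    for i in range(1, len(rs)):
        if flags[i] != flags[i - 1]:
            lo, hi = float(rs[i - 1]), float(rs[i])
            lo_flag = flags[i - 1]
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if exchange_mutually_preferred(dyad, mid) == lo_flag:
                    lo = mid
                else:
                    hi = mid
            crossings.append(0.5 * (lo + hi))
    if not any(flags):
        return ThresholdResult(r_star=None, search_tol=tol, crossings=tuple(crossings))
    if flags[0]:
        return ThresholdResult(r_star=0.0, search_tol=tol, crossings=tuple(crossings))
    return ThresholdResult(
        r_star=float(crossings[0]), search_tol=tol, crossings=tuple(crossings)
    )


def threshold_sweep(
    size_ratios: "list[float]",
    x_lo: float = 0.1,
    k_sup: float = 0.5,
    k_inf: float = 1.5,
    owner_config: str = "superior_owns_larger",
    tol: float = 1e-4,
):
    """Threshold as a function of the size ratio ``x_hi / x_lo`` (tidy rows)."""
    import pandas as pd

    rows = []
    for ratio in size_ratios:
        x_hi = x_lo * ratio
        res = exchange_threshold(x_hi, x_lo, k_sup, k_inf, owner_config, tol)
        rows.append(
            {
                "x_hi": x_hi,
                "x_lo": x_lo,
                "size_ratio": ratio,
                "k_sup": k_sup,
                "k_inf": k_inf,
                "owner_config": owner_config,
                "r_star": res.r_star,
            }
        )
    return pd.DataFrame(rows)
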