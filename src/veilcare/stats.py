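"""Inequality and design statistics for communal-litter provisioning studies.

The centrepiece is the *relative within-litter variance*: for each communal
litter (breeding attempt) the variance of pup weights within the litter,
divided by the total variance of pup weights across all retained litters.
Litters with fewer than four pups are excluded.  Manipulated and
unmanipulated litters are compared with a Mann-Whitney test whose p-value
is computed by full enumeration of labelings at small sample sizes.

Also here: maternal percentage weight change over fixed windows around
birth, per-pup escorting-received proportions, and a recovery report that
ties a simulated study's estimates back to the generator's configured
effects via cluster bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WeightWindowSpec",
    "InequalityResult",
    "MWResult",
    "maternal_weight_change",
    "escorting_received",
    "relative_within_litter_variance",
    "mann_whitney_exact",
    "recovery_report",
]

#: Largest combined sample size for which the Mann-Whitney null is enumerated.
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class WeightWindowSpec:
    """Day windows (inclusive, relative to birth = day 0) for maternal weights.

    Within each window the *latest* record is used.
    """

    baseline: tuple[int, int] = (-74, -67)
    pregnancy: tuple[int, int] = (-30, -5)
    post_pregnancy: tuple[int, int] = (5, 19)
    escorting: tuple[int, int] = (30, 90)

    def window(self, phase: str) -> tuple[int, int]:
        try:
            return getattr(self, phase)
        except AttributeError:
            raise ValueError(
                f"phase must be one of 'pregnancy', 'post_pregnancy', 'escorting'; "
                f"got {phase!r}"
            ) from None


@dataclass(frozen=True)
class InequalityResult:
    """Per-litter relative within-litter variances and exclusions."""

    values: dict
    excluded: tuple
    total_variance: float
    ddof: int
    min_litter_size: int
    stratum: Optional[str] = None
    group_labels: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "litter_id": str(lid),
                "relative_variance": v,
                "label": self.group_labels.get(lid),
                "stratum": self.stratum,
            }
            for lid, v in self.values.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MWResult:
    """Mann-Whitney U with exact (enumeration) or normal-approximation p."""

    u: float
    p_one_sided: float
    p_two_sided: float
    method: str
    alternative: str = "two-sided"
    n1: int = 0
    n2: int = 0


def maternal_weight_change(
    weights,
    phase: str,
    birth_day: float = 0.0,
    spec: Optional[WeightWindowSpec] = None,
) -> float:
    """Percentage weight change from the pre-pregnancy baseline to ``phase``.

    ``weights`` is a sequence of ``(day, weight)`` pairs or a DataFrame with
    ``day_rel_birth`` and ``weight_g`` columns; days are taken relative to
    ``birth_day``.  The latest record inside each window is used; returns
    NaN when either window holds no record.
    """
    spec = spec if spec is not None else WeightWindowSpec()
    if isinstance(weights, pd.DataFrame):
        days = weights["day_rel_birth"].to_numpy(dtype=float)
        w = weights["weight_g"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(weights), dtype=float)
        if arr.size == 0:
            return float("nan")
        days, w = arr[:, 0], arr[:, 1]
    days = days - birth_day

    def latest(window):
        lo, hi = window
        mask = (days >= lo) & (days <= hi)
        if not mask.any():
            return None
        i = np.flatnonzero(mask)
        return float(w[i[np.argmax(days[i])]])

    base = latest(spec.baseline)
    target = latest(spec.window(phase))
    if base is None or target is None:
        return float("nan")
    if base <= 0:
        raise ValueError(f"non-positive baseline weight {base}")
    return 100.0 * (target - base) / base


def escorting_received(observations: pd.DataFrame, pup_id: str) -> float:
    """Proportion of visits on which the pup was observed being escorted."""
    rows = observations[observations["pup_id"] == pup_id]
    if len(rows) == 0:
        return float("nan")
    return float(rows["escorted"].astype(bool).mean())


def relative_within_litter_variance(
    litters: "Mapping[object, Sequence[float]] | pd.DataFrame",
    min_litter_size: int = 4,
    ddof: int = 0,
    litter_col: str = "litter_id",
    weight_col: str = "weight_g",
    stratum: Optional[str] = None,
    group_labels: Optional[Mapping] = None,
) -> InequalityResult:
    """Within-litter weight variance relative to total variance across litters.

    Litters with fewer than ``min_litter_size`` pups are excluded before
    anything is computed; the total-variance denominator is taken over the
    pups of the *retained* litters.  ``ddof=0`` (population variance) is
    the default convention; ``ddof=1`` switches to sample variance.
    """
    if isinstance(litters, pd.DataFrame):
        grouped = {
            lid: sub[weight_col].to_numpy(dtype=float)
            for lid, sub in litters.groupby(litter_col, sort=True)
        }
    else:
        grouped = {lid: np.asarray(v, dtype=float) for lid, v in litters.items()}
    excluded = tuple(l for l, v in grouped.items() if len(v) < min_litter_size)
    retained = {l: v for l, v in grouped.items() if len(v) >= min_litter_size}
    if not retained:
        raise ValueError(
            f"no litters with >= {min_litter_size} pups remain after exclusion"
        )
    pooled = np.concatenate(list(retained.values()))
    total = float(np.var(pooled, ddof=ddof))
    if total <= 0:
        raise ValueError("total variance across litters is zero; statistic undefined")
    values = {l: float(np.var(v, ddof=ddof)) / total for l, v in retained.items()}
    return InequalityResult(
        values=values,
        excluded=excluded,
        total_variance=total,
        ddof=ddof,
        min_litter_size=min_litter_size,
        stratum=stratum,
        group_labels=dict(group_labels or {}),
    )


@lru_cache(maxsize=None)
def _null_u_values(n1: int, n2: int) -> np.ndarray:
    """U for every one of the C(n1+n2, n1) equally likely rank labelings."""
    offset = n1 * (n1 + 1) / 2
    return np.array(
        [sum(c) - offset for c in combinations(range(1, n1 + n2 + 1), n1)]
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2)


def mann_whitney_exact(a, b, alternative: str = "two-sided") -> MWResult:
    """Mann-Whitney test with exact enumeration at small sample sizes.

    ``U`` counts pairs where an ``a`` value exceeds a ``b`` value (ties
    half).  With no ties and ``n1 + n2 <= 12``, p-values come from full
    enumeration of all C(n1+n2, n1) labelings; otherwise from a normal
    approximation with tie correction (the result is flagged via
    ``method``).  The two-sided p doubles the smaller tail, capped at 1.

    ``alternative``: "two-sided", "greater" (a tends larger) or "less".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2

    if not has_ties and n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        us = _null_u_values(n1, n2)
        total = len(us)
        p_le = np.count_nonzero(us <= u) / total
        p_ge = np.count_nonzero(us >= u) / total
        method = "exact_enumeration"
    else:
        mu = n1 * n2 / 2
        all_vals = np.concatenate([a, b])
        _, counts = np.unique(all_vals, return_counts=True)
        n = n1 + n2
        tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        sigma = math.sqrt(n1 * n2 / 12 * (n + 1 - tie_term))
        if sigma == 0:
            p_le = p_ge = 1.0
        else:
            # continuity-corrected tails
            p_le = float(norm.cdf((u - mu + 0.5) / sigma))
            p_ge = float(norm.sf((u - mu - 0.5) / sigma))
        method = "normal_approx"

    p_min = min(p_le, p_ge)
    p_two = min(1.0, 2.0 * p_min)
    if alternative == "greater":
        p_one = p_ge
    elif alternative == "less":
        p_one = p_le
    else:
        p_one = p_min
    return MWResult(u=u, p_one_sided=float(p_one), p_two_sided=float(p_two),
                    method=method, alternative=alternative, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# recovery report


def _cluster_gap_ci(df, value_col, cat_a, cat_b, rng, n_boot, alpha):
    """Mean(cat_a) - mean(cat_b) with a cluster bootstrap over litters."""
    sub = df[df["category"].isin([cat_a, cat_b])].copy()
    sub = sub.dropna(subset=[value_col])
    if len(sub) == 0:
        return None
    clusters = sub.groupby(["group", "attempt"], sort=True)
    sums_a, ns_a, sums_b, ns_b = [], [], [], []
    for _, c in clusters:
        in_a = c["category"] == cat_a
        sums_a.append(c.loc[in_a, value_col].sum())
        ns_a.append(int(in_a.sum()))
        sums_b.append(c.loc[~in_a, value_col].sum())
        ns_b.append(int((~in_a).sum()))
    sums_a, ns_a = np.array(sums_a), np.array(ns_a)
    sums_b, ns_b = np.array(sums_b), np.array(ns_b)
    if ns_a.sum() == 0 or ns_b.sum() == 0:
        return None
    point = sums_a.sum() / ns_a.sum() - sums_b.sum() / ns_b.sum()
    C = len(ns_a)
    idx = rng.integers(0, C, size=(n_boot, C))
    na, nb = ns_a[idx].sum(axis=1), ns_b[idx].sum(axis=1)
    ok = (na > 0) & (nb > 0)
    gaps = (sums_a[idx].sum(axis=1)[ok] / na[ok]
            - sums_b[idx].sum(axis=1)[ok] / nb[ok])
    lo, hi = np.quantile(gaps, [alpha / 2, 1 - alpha / 2])
    return {"estimate": float(point), "ci_low": float(lo), "ci_high": float(hi),
            "n": int(ns_a.sum() + ns_b.sum())}


def _inequality_comparison(pups, weight_col, stratum, min_litter_size, ddof):
    df = pups.dropna(subset=[weight_col]).copy()
    df["litter_id"] = df["group"].astype(str) + "_a" + df["attempt"].astype(str)
    labels = (
        df.drop_duplicates("litter_id").set_index("litter_id")["manipulated"].to_dict()
    )
    res = relative_within_litter_variance(
        df, min_litter_size=min_litter_size, ddof=ddof,
        litter_col="litter_id", weight_col=weight_col,
        stratum=stratum, group_labels=labels,
    )
    manip = [v for l, v in res.values.items() if labels[l]]
    unmanip = [v for l, v in res.values.items() if not labels[l]]
    out = {
        "stratum": stratum,
        "n_manipulated_litters": len(manip),
        "n_unmanipulated_litters": len(unmanip),
        "n_excluded_litters": len(res.excluded),
        "median_manipulated": float(np.median(manip)) if manip else None,
        "median_unmanipulated": float(np.median(unmanip)) if unmanip else None,
    }
    if manip and unmanip:
        mw = mann_whitney_exact(manip, unmanip, alternative="greater")
        out.update({"mw_u": mw.u, "mw_p_one_sided_greater": mw.p_one_sided,
                    "mw_method": mw.method})
        out["elevated"] = out["median_manipulated"] > out["median_unmanipulated"]
    else:
        out.update({"mw_u": None, "mw_p_one_sided_greater": None,
                    "mw_method": None, "elevated": None})
    return out


def recovery_report(
    study,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    min_litter_size: int = 4,
    ddof: int = 0,
) -> dict:
    """Estimate the generator's configured effects back from a simulated study.

    Reports the treatment-control gaps in birth weight and 60-90 d weight
    (cluster bootstrap CIs over communal litters), the escorting-received
    gap, survival proportions per category, and the manipulated-versus-
    unmanipulated relative within-litter variance comparison in the two age
    strata, together with recovery flags.
    """
    rng = np.random.default_rng(seed)
    config = study.config
    pups = study.pups
    manip = pups[pups["manipulated"].astype(bool)]

    report: dict = {"seed": int(study.seed), "alpha": alpha}

    birth = _cluster_gap_ci(manip, "birth_weight_g", "treatment", "control",
                            rng, n_boot, alpha)
    w60 = _cluster_gap_ci(manip, "w60_g", "treatment", "control", rng, n_boot, alpha)

    esc = study.escorting
    if len(esc):
        prop = (esc.groupby("pup_id", sort=True)["escorted"].mean()
                .rename("escort_prop").reset_index())
        merged = manip.merge(prop, on="pup_id", how="left")
        escort_gap = _cluster_gap_ci(merged, "escort_prop", "control", "treatment",
                                     rng, n_boot, alpha)
    else:
        escort_gap = None

    survival = {}
    for period, col in (("90d", "surv_90d"), ("180d", "surv_180d"),
                        ("365d", "surv_365d")):
        by_cat = manip.groupby("category", sort=True)[col].mean().to_dict()
        survival[period] = {k: float(v) for k, v in by_cat.items()}

    inequality = {}
    flags = {}
    try:
        inequality["30_60d"] = _inequality_comparison(
            pups, "w30_g", "30_60d", min_litter_size, ddof)
        inequality["60_90d"] = _inequality_comparison(
            pups, "w60_g", "60_90d", min_litter_size, ddof)
    except ValueError as err:
        inequality["error"] = str(err)
        flags["inequality_comparison_possible"] = False

    report["birth_weight_gap_g"] = birth
    report["w60_weight_gap_g"] = w60
    report["escorting_received_gap"] = escort_gap
    report["survival_proportions"] = survival
    report["inequality"] = inequality

    if birth is not None:
        flags["birth_gap_ci_covers_configured"] = bool(
            birth["ci_low"] <= config.configured_birth_gap <= birth["ci_high"])
    if w60 is not None:
        flags["w60_gap_ci_covers_configured"] = bool(
            w60["ci_low"] <= config.configured_w60_gap <= w60["ci_high"])
    if escort_gap is not None:
        flags["control_pups_escorted_more"] = bool(escort_gap["estimate"] > 0)
    if "30_60d" in inequality and inequality["30_60d"]["elevated"] is not None:
        flags["inequality_elevated_30_60d"] = bool(inequality["30_60d"]["elevated"])
    if (
        "30_60d" in inequality
        and "60_90d" in inequality
        and inequality["30_60d"]["elevated"] is not None
        and inequality["60_90d"]["median_manipulated"] is not None
    ):
        lift_30 = (inequality["30_60d"]["median_manipulated"]
                   - inequality["30_60d"]["median_unmanipulated"])
        lift_60 = (inequality["60_90d"]["median_manipulated"]
                   - inequality["60_90d"]["median_unmanipulated"])
        flags["inequality_levelled_60_90d"] = bool(lift_60 < lift_30)
    report["configured"] = {
        "birth_gap_g": config.configured_birth_gap,
        "w60_gap_g": config.configured_w60_gap,
        "escort_bias_logodds": config.escort_bias_logodds,
    }
    report["flags"] = flags
    return report
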