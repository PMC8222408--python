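"""Seeded generator for split-plot gestational-provisioning experiments.

Emulates the structure of a cooperative-breeding field experiment in which
half of the pregnant females in each group are provisioned ("fed") during
pregnancy and the other half serve as within-group controls ("non-fed"),
with every manipulated communal breeding attempt followed by an
unmanipulated one.  The generator reproduces the design's moving parts:

* age-matched pairing of pregnant females with history-dependent
  reassignment (a female fed in one manipulated attempt is assigned the
  opposite category the next time she participates);
* randomized daily provisioning (0/50/100 g, a.m. or p.m.) averaging
  50 g/day;
* synchronized birth into a communal litter, with per-category pup birth
  weights (fed mothers bear heavier pups);
* escorting visits in which fed mothers bias their care toward the
  *control* pups (log-odds bonus), while non-fed mothers and males are
  unbiased;
* growth that converges across categories by 60-90 days; and
* survival with category-independent hazards.

All randomness flows from one master seed through per-group substreams, so
a fixed seed yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "assign_treatments",
    "provisioning_schedule",
    "simulate_breeding_attempt",
    "simulate_study",
]

MOTHER_COLUMNS = [
    "mother_id", "group", "attempt", "manipulated", "age_days", "treatment",
    "provision_days", "provision_total_g", "provision_mean_g",
]
PUP_COLUMNS = [
    "pup_id", "mother_id", "group", "attempt", "manipulated", "category",
    "birth_weight_g", "w30_g", "w30_age_d", "w60_g", "w60_age_d",
    "feeds_per_hour", "surv_90d", "surv_180d", "surv_365d",
]
ESCORT_COLUMNS = ["group", "attempt", "visit", "pup_id", "escort_id", "escorted"]
WEIGHT_COLUMNS = ["mother_id", "group", "attempt", "day_rel_birth", "weight_g"]


def _cat_field(treatment: float, control: float, unmanipulated: float) -> dict:
    return {"treatment": treatment, "control": control, "unmanipulated": unmanipulated}


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study design and its summaries.

    Weights are grams, times are days relative to birth (= day 0).  The
    stratum means (birth, 30-60 d, 60-90 d) are category means; pup weights
    additionally carry a shared communal-litter random effect
    (``litter_effect_sd``), a persistent within-litter residual
    (``birth_within_litter_sd``) and independent growth-stage noise
    (``growth_sd``).
    """

    n_groups: int = 7
    attempts_per_group: int = 10
    males_per_group: int = 8
    # breeding-female pool size varies between groups with the litter-size
    # distribution (mean 5.0, sd 2.6, truncated >= 2); most pool females are
    # pregnant in any given attempt
    females_per_attempt_mean: float = 5.0
    females_per_attempt_sd: float = 2.6
    min_females_per_attempt: int = 2
    max_females_per_group: int = 12
    # essentially every adult female breeds in every communal attempt;
    # turnover of the breeding pool comes from mortality and recruitment
    participation_prob: float = 1.0
    female_mortality_per_attempt: float = 0.07
    recruit_prob: float = 1.0

    # pup weights (g) by category
    birth_mean: dict = field(default_factory=lambda: _cat_field(164.9, 142.0, 142.0))
    w30_mean: dict = field(default_factory=lambda: _cat_field(315.5, 299.4, 299.4))
    w60_mean: dict = field(default_factory=lambda: _cat_field(413.6, 420.8, 420.8))
    birth_within_litter_sd: float = 12.0
    litter_effect_sd: float = 15.0
    growth_sd: float = 10.0

    # escorting (days 30-90)
    visits_per_attempt: int = 60
    escort_prob: float = 0.6
    escort_bias_logodds: float = 2.52
    feed_rate_mean: dict = field(default_factory=lambda: _cat_field(1.2, 2.8, 2.0))
    feed_rate_sd: float = 0.5

    # per-period survival probabilities (conditional on surviving the
    # previous period); category log-odds offsets default to zero
    survival_p: dict = field(
        default_factory=lambda: {"d90": 0.75, "d180": 0.85, "d365": 0.85}
    )
    survival_category_logodds: dict = field(
        default_factory=lambda: _cat_field(0.0, 0.0, 0.0)
    )

    # maternal weights (g) and percentage gains relative to baseline
    maternal_baseline_mean: float = 1100.0
    maternal_baseline_sd: float = 100.0
    pregnancy_gain_pct: dict = field(
        default_factory=lambda: {"fed": 24.1, "non_fed": 15.1, "unmanipulated": 15.1}
    )
    postpregnancy_gain_pct: dict = field(
        default_factory=lambda: {"fed": 4.36, "non_fed": -0.19, "unmanipulated": -0.19}
    )
    escorting_gain_pct: dict = field(
        default_factory=lambda: {"fed": 3.33, "non_fed": -1.95, "unmanipulated": -1.95}
    )
    maternal_weight_noise_sd: float = 15.0

    # provisioning
    provision_days_mean: float = 24.0
    provision_days_sd: float = 9.0

    # female ages at study start, days (1-8 years)
    age_min_days: int = 365
    age_max_days: int = 2920

    def __post_init__(self) -> None:
        for name in ("birth_mean", "w30_mean", "w60_mean", "feed_rate_mean"):
            for cat, v in getattr(self, name).items():
                if not v > 0:
                    raise ValueError(f"{name}[{cat}] must be positive, got {v}")
        for cat, p in self.survival_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival_p[{cat}] must lie in [0, 1], got {p}")
        if not 0.0 <= self.escort_prob <= 1.0:
            raise ValueError("escort_prob must lie in [0, 1]")

    @property
    def configured_birth_gap(self) -> float:
        return self.birth_mean["treatment"] - self.birth_mean["control"]

    @property
    def configured_w60_gap(self) -> float:
        return self.w60_mean["treatment"] - self.w60_mean["control"]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                cur = getattr(base, f.name)
                if isinstance(cur, dict) and isinstance(v, dict):
                    v = {**cur, **v}
                merged[f.name] = v
        return cls(**merged)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)


@dataclass
class SyntheticStudy:
    """Tidy tables produced by :func:`simulate_study`."""

    mothers: pd.DataFrame
    pups: pd.DataFrame
    escorting: pd.DataFrame
    weights: pd.DataFrame
    config: SimConfig
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
            "n_mother_rows": int(len(self.mothers)),
            "n_pups": int(len(self.pups)),
            "n_escort_rows": int(len(self.escorting)),
            "n_weight_rows": int(len(self.weights)),
        }

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in (
            ("mothers", self.mothers),
            ("pups", self.pups),
            ("escorting", self.escorting),
            ("weights", self.weights),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")
        paths.append(mpath)
        return paths

    @classmethod
    def from_csv(cls, in_dir: str | Path, config: Optional[SimConfig] = None
                 ) -> "SyntheticStudy":
        in_dir = Path(in_dir)
        frames = {
            name: pd.read_csv(in_dir / f"{name}.csv")
            for name in ("mothers", "pups", "escorting", "weights")
        }
        seed = -1
        mpath = in_dir / "manifest.json"
        if mpath.exists():
            seed = json.loads(mpath.read_text()).get("seed", -1)
        return cls(config=config or SimConfig(), seed=seed, **frames)


# ---------------------------------------------------------------------------
# design primitives


def _incompatible(h1: str, h2: str) -> bool:
    return h1 == h2 and h1 in ("previously_fed", "previously_non_fed")


def _opposite(history: str) -> str:
    return "non_fed" if history == "previously_fed" else "fed"


def assign_treatments(
    females: "list[tuple[str, float, str]]", rng: np.random.Generator
) -> dict[str, str]:
    """Assign pregnant females to fed / non-fed in age-matched pairs.

    ``females`` holds ``(id, age, history)`` with history in ``{"none",
    "previously_fed", "previously_non_fed"}``.  Females are sorted by age
    and paired adjacently.  A pair with no history splits at random; if one
    member has a history she takes the opposite of her previous category
    and her partner the complement; if both carry the *same* history the
    pair is re-formed with the next-nearest-aged compatible female.  Should
    no compatible partner exist, both members follow the opposite-of-
    previous rule (never feeding a previously fed female twice in a row
    takes precedence over the even split).  An odd leftover female is
    assigned at random if she has no history, else opposite to before.

    A final repair pass restores the half/half split where histories allow
    it; a previously fed female is never promoted back to fed, so in rare
    draws dominated by previously fed females the split may stay uneven.
    """
    order = sorted(females, key=lambda f: (f[1], f[0]))
    pool = list(order)
    pairs: list[tuple] = []
    while len(pool) >= 2:
        a = pool.pop(0)
        idx = 0
        if _incompatible(a[2], pool[0][2]):
            for j in range(1, len(pool)):
                if not _incompatible(a[2], pool[j][2]):
                    idx = j
                    break
        b = pool.pop(idx)
        pairs.append((a, b))
    leftover = pool[0] if pool else None

    assignment: dict[str, str] = {}
    for a, b in pairs:
        ha, hb = a[2], b[2]
        if ha == "none" and hb == "none":
            first_fed = bool(rng.integers(0, 2))
            assignment[a[0]] = "fed" if first_fed else "non_fed"
            assignment[b[0]] = "non_fed" if first_fed else "fed"
        elif ha != "none" and hb == "none":
            assignment[a[0]] = _opposite(ha)
            assignment[b[0]] = "fed" if assignment[a[0]] == "non_fed" else "non_fed"
        elif ha == "none" and hb != "none":
            assignment[b[0]] = _opposite(hb)
            assignment[a[0]] = "fed" if assignment[b[0]] == "non_fed" else "non_fed"
        else:
            # both have history; identical histories only when no compatible
            # re-pairing existed, in which case both take the opposite rule
            assignment[a[0]] = _opposite(ha)
            assignment[b[0]] = _opposite(hb)
    if leftover is not None:
        lid, _, hist = leftover
        if hist == "none":
            assignment[lid] = "fed" if rng.integers(0, 2) else "non_fed"
        else:
            assignment[lid] = _opposite(hist)

    # restore the half/half split where the history rules permit: a female
    # is never promoted to fed if she was fed in the previous manipulated
    # attempt she took part in
    history_of = {f[0]: f[2] for f in females}
    n_fed = sum(1 for v in assignment.values() if v == "fed")
    n_non = len(assignment) - n_fed
    while abs(n_fed - n_non) > 1:
        if n_fed > n_non:
            source, target = "fed", "non_fed"
            # demotion to non-fed never re-feeds anyone; prefer history-free
            tiers = (("none",), ("previously_non_fed",))
        else:
            source, target = "non_fed", "fed"
            # promotion to fed must never hit a previously fed female
            tiers = (("none",), ("previously_non_fed",))
        candidates = []
        for tier in tiers:
            candidates = sorted(
                fid for fid, cat in assignment.items()
                if cat == source and history_of[fid] in tier
            )
            if candidates:
                break
        if not candidates:
            break
        flip = candidates[int(rng.integers(0, len(candidates)))]
        assignment[flip] = target
        n_fed += 1 if target == "fed" else -1
        n_non += 1 if target == "non_fed" else -1
    return assignment


def provisioning_schedule(days: int, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized daily egg provisioning: 0/50/100 g (mean 50), a.m. or p.m."""
    if days < 1:
        raise ValueError("days must be >= 1")
    grams = rng.choice([0, 50, 100], size=days)
    session = rng.choice(["am", "pm"], size=days)
    return pd.DataFrame({"day": np.arange(1, days + 1), "grams": grams,
                         "session": session})


# ---------------------------------------------------------------------------
# attempt and study simulation


def _truncnorm_pos(rng, mean, sd, size=None, floor=1.0):
    v = rng.normal(mean, sd, size=size)
    return np.maximum(v, floor)


def simulate_breeding_attempt(
    config: SimConfig,
    group_state: dict,
    manipulated: bool,
    rng: np.random.Generator,
    attempt_index: int = 0,
):
    """Simulate one communal breeding attempt for a group.

    Returns ``(mother_rows, pup_rows, escort_rows, weight_rows)`` as lists
    of dicts, and mutates ``group_state`` (treatment histories).  Every
    pregnant female contributes one pup to the communal litter; pup
    category follows the mother's treatment.
    """
    pool = group_state["females"]
    group = group_state["group"]
    pregnant = rng.random(len(pool)) < config.participation_prob
    n_min = min(config.min_females_per_attempt, len(pool))
    if pregnant.sum() < n_min:
        extra = rng.permutation(np.flatnonzero(~pregnant))
        pregnant[extra[: n_min - pregnant.sum()]] = True
    mothers = [pool[i] for i in np.flatnonzero(pregnant)]

    if manipulated:
        females = [(m["id"], m["age_days"], m["history"]) for m in mothers]
        treatments = assign_treatments(females, rng)
    else:
        treatments = {m["id"]: "unmanipulated" for m in mothers}

    mother_rows, pup_rows, weight_rows = [], [], []
    cat_of = {"fed": "treatment", "non_fed": "control",
              "unmanipulated": "unmanipulated"}

    litter_effect = rng.normal(0.0, config.litter_effect_sd)
    pups = []
    for i, m in enumerate(mothers):
        treatment = treatments[m["id"]]
        provision_days = 0
        total_g = 0.0
        if treatment == "fed":
            provision_days = int(max(5, round(rng.normal(
                config.provision_days_mean, config.provision_days_sd))))
            sched = provisioning_schedule(provision_days, rng)
            total_g = float(sched["grams"].sum())
        mother_rows.append({
            "mother_id": m["id"], "group": group, "attempt": attempt_index,
            "manipulated": manipulated, "age_days": m["age_days"],
            "treatment": treatment, "provision_days": provision_days,
            "provision_total_g": total_g,
            "provision_mean_g": total_g / provision_days if provision_days else 0.0,
        })

        cat = cat_of[treatment]
        persistent = rng.normal(0.0, config.birth_within_litter_sd)
        birth_w = max(1.0, config.birth_mean[cat] + litter_effect + persistent)
        w30 = max(1.0, birth_w + (config.w30_mean[cat] - config.birth_mean[cat])
                  + rng.normal(0.0, config.growth_sd))
        w60 = max(1.0, w30 + (config.w60_mean[cat] - config.w30_mean[cat])
                  + rng.normal(0.0, config.growth_sd))
        s = {}
        alive = True
        offset = config.survival_category_logodds[cat]
        for period in ("d90", "d180", "d365"):
            if alive:
                p = config.survival_p[period]
                logit = np.log(p / (1 - p)) + offset if 0 < p < 1 else np.inf
                p_eff = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(logit) else p
                alive = bool(rng.random() < p_eff)
            s[period] = alive
        pup = {
            "pup_id": f"{group}_a{attempt_index}_p{i}", "mother_id": m["id"],
            "group": group, "attempt": attempt_index, "manipulated": manipulated,
            "category": cat, "birth_weight_g": birth_w,
            "w30_g": w30, "w30_age_d": int(rng.integers(30, 61)),
            "w60_g": w60, "w60_age_d": int(rng.integers(60, 91)),
            "feeds_per_hour": float(_truncnorm_pos(
                rng, config.feed_rate_mean[cat], config.feed_rate_sd, floor=0.0)),
            "surv_90d": s["d90"], "surv_180d": s["d180"], "surv_365d": s["d365"],
        }
        pups.append(pup)
        pup_rows.append(pup)

        # maternal weight series: baseline, mid+late pregnancy, post, escorting
        gain_key = treatment
        base = float(_truncnorm_pos(rng, config.maternal_baseline_mean,
                                    config.maternal_baseline_sd, floor=200.0))
        noise = config.maternal_weight_noise_sd
        records = [
            (int(rng.integers(-74, -66)), base),
            (-25, base * (1 + 0.5 * config.pregnancy_gain_pct[gain_key] / 100)
             + rng.normal(0, noise)),
            (int(rng.integers(-15, -4)),
             base * (1 + config.pregnancy_gain_pct[gain_key] / 100)
             + rng.normal(0, noise)),
            (int(rng.integers(5, 20)),
             base * (1 + config.postpregnancy_gain_pct[gain_key] / 100)
             + rng.normal(0, noise)),
            (int(rng.integers(60, 91)),
             base * (1 + config.escorting_gain_pct[gain_key] / 100)
             + rng.normal(0, noise)),
        ]
        for day, w in records:
            weight_rows.append({
                "mother_id": m["id"], "group": group, "attempt": attempt_index,
                "day_rel_birth": day, "weight_g": max(1.0, float(w)),
            })

    # escorting visits: adults are this attempt's mothers plus group males;
    # each escorting adult pairs with at most one pup per visit
    escort_rows = []
    adults = [(m["id"], treatments[m["id"]]) for m in mothers]
    adults += [(mid, "male") for mid in group_state["males"]]
    bias = float(np.exp(config.escort_bias_logodds))
    control_mask = np.array([p["category"] == "control" for p in pups])
    pup_ids = [p["pup_id"] for p in pups]
    n_pups = len(pups)
    for visit in range(config.visits_per_attempt):
        active = [a for a in adults if rng.random() < config.escort_prob]
        order = rng.permutation(len(active))
        available = np.ones(n_pups, dtype=bool)
        escort_of = {}
        for ai in order:
            if not available.any():
                break
            aid, role = active[ai]
            weights = np.where(control_mask & (role == "fed"), bias, 1.0)
            weights = weights * available
            p = weights / weights.sum()
            choice = int(rng.choice(n_pups, p=p))
            available[choice] = False
            escort_of[choice] = aid
        for pi in range(n_pups):
            escort_rows.append({
                "group": group, "attempt": attempt_index, "visit": visit,
                "pup_id": pup_ids[pi], "escort_id": escort_of.get(pi, ""),
                "escorted": pi in escort_of,
            })

    # carry treatment histories forward (manipulated attempts only)
    if manipulated:
        for m in mothers:
            m["history"] = ("previously_fed" if treatments[m["id"]] == "fed"
                            else "previously_non_fed")
    return mother_rows, pup_rows, escort_rows, weight_rows


def simulate_study(config: Optional[SimConfig] = None, seed: int = 0
                   ) -> SyntheticStudy:
    """Simulate a full multi-group study with alternating attempt types.

    Attempts alternate manipulated -> unmanipulated within each group, and
    females' treatment histories persist between manipulated attempts.
    """
    config = config if config is not None else SimConfig()
    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(config.n_groups)
    all_m, all_p, all_e, all_w = [], [], [], []
    for g in range(config.n_groups):
        rng = np.random.default_rng(group_seeds[g])
        group = f"g{g}"
        pool_size = int(np.clip(
            round(rng.normal(config.females_per_attempt_mean,
                             config.females_per_attempt_sd)),
            config.min_females_per_attempt, config.max_females_per_group))
        state = {
            "group": group,
            "females": [
                {
                    "id": f"{group}_f{i}",
                    "age_days": int(rng.integers(config.age_min_days,
                                                 config.age_max_days + 1)),
                    "history": "none",
                }
                for i in range(pool_size)
            ],
            "males": [f"{group}_m{i}" for i in range(config.males_per_group)],
        }
        for attempt in range(config.attempts_per_group):
            manipulated = attempt % 2 == 0
            m, p, e, w = simulate_breeding_attempt(
                config, state, manipulated, rng, attempt_index=attempt)
            all_m += m
            all_p += p
            all_e += e
            all_w += w
            # demographic turnover between attempts
            alive = rng.random(len(state["females"])) \
                >= config.female_mortality_per_attempt
            if alive.sum() < config.min_females_per_attempt:
                dead = rng.permutation(np.flatnonzero(~alive))
                need = config.min_females_per_attempt - int(alive.sum())
                alive[dead[:need]] = True
            state["females"] = [
                f for f, a in zip(state["females"], alive) if a
            ]
            state["n_recruited"] = state.get("n_recruited", 0)
            if (len(state["females"]) < pool_size
                    and rng.random() < config.recruit_prob):
                state["n_recruited"] += 1
                state["females"].append({
                    "id": f"{group}_r{state['n_recruited']}",
                    "age_days": 365,
                    "history": "none",
                })
            for f in state["females"]:
                f["age_days"] += 90
    return SyntheticStudy(
        mothers=pd.DataFrame(all_m, columns=MOTHER_COLUMNS),
        pups=pd.DataFrame(all_p, columns=PUP_COLUMNS),
        escorting=pd.DataFrame(all_e, columns=ESCORT_COLUMNS),
        weights=pd.DataFrame(all_w, columns=WEIGHT_COLUMNS),
        config=config,
        seed=seed,
    )
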