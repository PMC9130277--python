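"""Individual-based simulation of maternal reproductive careers.

Each simulated mother starts at her observed age at first birth with parity
one, and lives through repeated iterations of three life-history events, in
this order: the twinning outcome of the current birth (T), whether she will
reproduce again (parity progression, PP), and — if she continues — the
interval to the next birth (IBI).  The three events are drawn from fitted
GLMMs, conditionally on both fixed effects and the conditional modes of the
mother's and population's random intercepts.  Reproduction always ceases:
parity-progression probability is below one and is forced to zero once a
mother reaches the age cap (60 years by default); the interbirth interval is
bounded to [9, 360] months, with sub-9-month draws rejected and redrawn so
the fitted distribution keeps its shape on the observed support.

The 16 mechanism scenarios toggle four mechanisms by swapping which fitted
model generates each event:

===========  =======================================================
mechanism    active model / inactive model
===========  =======================================================
P            PP from model 4 (twin effect) / model 8 (no twin term)
I            IBI from model 5 / model 9
S + H        T from model 6 (age-parity polynomial + maternal RE)
S only       T from model 12 (polynomial, no maternal RE)
H only       T from model 10 (maternal RE, no polynomial)
neither      T from model 11 (intercept + population RE only)
===========  =======================================================
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Dataset
from .glmm import FittedModel, ModelSuite

__all__ = [
    "ScenarioSpec",
    "SimulationConfig",
    "ALL_SCENARIOS",
    "scenario_models",
    "simulate_dataset",
    "simulate_replicates",
    "realism_check",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Four mechanism toggles; canonical name is the subset of "PISH" active
    (in that order), or "0" when none is."""

    P: bool = False
    I: bool = False
    S: bool = False
    H: bool = False

    @property
    def name(self) -> str:
        s = "".join(c for c, on in zip("PISH", (self.P, self.I, self.S, self.H)) if on)
        return s or "0"

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        if name == "0":
            return cls()
        if set(name) - set("PISH") or len(set(name)) != len(name):
            raise ValueError(f"invalid scenario name {name!r}")
        return cls(**{c: c in name for c in "PISH"})

    def model_numbers(self):
        pp = 4 if self.P else 8
        ibi = 5 if self.I else 9
        if self.S and self.H:
            t = 6
        elif self.S:
            t = 12
        elif self.H:
            t = 10
        else:
            t = 11
        return pp, ibi, t


ALL_SCENARIOS = tuple(
    ScenarioSpec(*flags) for flags in itertools.product([False, True], repeat=4)
)


@dataclass
class SimulationConfig:
    """Caps and bounds of the career loop (months)."""

    age_cap_months: int = 720      # parity progression forced off at 60 y
    ibi_cap_months: int = 360      # maximum simulated interbirth interval
    ibi_min_months: int = 9        # draws below this are rejected and redrawn

    def __post_init__(self):
        if self.age_cap_months <= 0 or self.ibi_cap_months <= 0:
            raise ValueError("caps must be positive")
        if self.ibi_min_months >= self.ibi_cap_months:
            raise ValueError("ibi_min_months must be below ibi_cap_months")


def scenario_models(spec: ScenarioSpec, suite: ModelSuite):
    """Return the (PP, IBI, T) fitted-model triple implementing a scenario."""
    nums = spec.model_numbers()
    missing = [n for n in nums if n not in suite]
    if missing:
        raise ValueError(f"suite lacks models {missing} for scenario {spec.name}")
    return tuple(suite[n] for n in nums)


def _re_sum(fit: FittedModel, maternal_ids, population_ids):
    """Conditional-mode random-effect contribution per mother, one value per
    init mother (unknown levels contribute zero)."""
    u = np.zeros(len(maternal_ids))
    modes = fit.re_modes.get("maternal_id")
    if modes is not None:
        u = u + modes.reindex(maternal_ids).fillna(0.0).to_numpy()
    modes = fit.re_modes.get("population_id")
    if modes is not None:
        u = u + modes.reindex(population_ids).fillna(0.0).to_numpy()
    return u


def _fixed_eta(fit: FittedModel, age, parity, twin):
    df = pd.DataFrame({"age_months": age, "parity": parity, "twin": twin})
    return fit.linpred(df, random=())


def _draw_ibi(rng, mu, shape, config: SimulationConfig):
    """NB2 draws with rejection below the 9-month floor and a hard cap."""
    mu = np.asarray(mu, dtype=float)
    p = shape / (shape + mu)
    out = rng.negative_binomial(shape, p).astype(float)
    low = out < config.ibi_min_months
    for _ in range(1000):
        if not low.any():
            break
        out[low] = rng.negative_binomial(shape, p[low])
        low = out < config.ibi_min_months
    out = np.maximum(out, config.ibi_min_months)
    return np.minimum(out, config.ibi_cap_months)


def simulate_dataset(models, init_mothers: pd.DataFrame,
                     config: SimulationConfig | None = None,
                     seed=0, scenario_name=None, replicate=None) -> Dataset:
    """Simulate one full dataset of reproductive careers.

    ``models`` is the (PP, IBI, T) triple; ``init_mothers`` must carry
    ``maternal_id``, ``population_id`` and ``AFB_months``.  Returns a
    :class:`~twinfert.data.Dataset` with the same birth- and mother-level
    schema as the observed derived tables.
    """
    pp_fit, ibi_fit, t_fit = models
    config = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mids = init_mothers["maternal_id"].to_numpy()
    pops = init_mothers["population_id"].to_numpy()
    n = len(mids)
    u_pp = _re_sum(pp_fit, init_mothers["maternal_id"], init_mothers["population_id"])
    u_ibi = _re_sum(ibi_fit, init_mothers["maternal_id"], init_mothers["population_id"])
    u_t = _re_sum(t_fit, init_mothers["maternal_id"], init_mothers["population_id"])

    age = init_mothers["AFB_months"].to_numpy(dtype=float).copy()
    parity = np.ones(n)
    active = np.ones(n, dtype=bool)
    rec = {k: [] for k in ("idx", "age", "parity", "twin", "PP", "IBI")}

    while active.any():
        ix = np.flatnonzero(active)
        a, p = age[ix], parity[ix]

        eta_t = _fixed_eta(t_fit, a, p, np.zeros(len(ix))) + u_t[ix]
        twin = rng.random(len(ix)) < expit(eta_t)

        eta_pp = _fixed_eta(pp_fit, a, p, twin.astype(float)) + u_pp[ix]
        p_pp = expit(eta_pp)
        p_pp[a >= config.age_cap_months] = 0.0
        cont = rng.random(len(ix)) < p_pp

        ibi = np.full(len(ix), np.nan)
        if cont.any():
            jx = np.flatnonzero(cont)
            eta_ibi = _fixed_eta(ibi_fit, a[jx], p[jx],
                                 twin[jx].astype(float)) + u_ibi[ix[jx]]
            ibi[jx] = _draw_ibi(rng, np.exp(eta_ibi), ibi_fit.shape, config)

        rec["idx"].append(ix)
        rec["age"].append(a.copy())
        rec["parity"].append(p.copy().astype(int))
        rec["twin"].append(twin.astype(int))
        rec["PP"].append(cont.astype(int))
        rec["IBI"].append(ibi)

        age[ix[cont]] += ibi[np.flatnonzero(cont)]
        parity[ix[cont]] += 1
        active[:] = False
        active[ix[cont]] = True

    idx = np.concatenate(rec["idx"])
    births = pd.DataFrame({
        "maternal_id": mids[idx],
        "population_id": pops[idx],
        "age_months": np.concatenate(rec["age"]),
        "parity": np.concatenate(rec["parity"]),
        "twin": np.concatenate(rec["twin"]),
        "PP": np.concatenate(rec["PP"]),
        "IBI_months": np.concatenate(rec["IBI"]),
    }).sort_values(["population_id", "maternal_id", "parity"]).reset_index(drop=True)
    births["n_offspring"] = 1 + births["twin"]

    mothers = (births.groupby(["maternal_id", "population_id"], sort=True)
               .agg(births_total=("parity", "max"),
                    twin_total=("twin", "sum"),
                    AFB_months=("age_months", "min"))
               .reset_index())
    mothers["singleton_total"] = mothers["births_total"] - mothers["twin_total"]
    mothers["twinner"] = (mothers["twin_total"] >= 1).astype(int)

    if scenario_name is not None:
        births["scenario"] = scenario_name
        mothers["scenario"] = scenario_name
    if replicate is not None:
        births["replicate"] = replicate
        mothers["replicate"] = replicate
    return Dataset(births=births, mothers=mothers,
                   exclusions=pd.DataFrame(columns=["maternal_id",
                                                    "population_id",
                                                    "reason", "n_births"]))


def simulate_replicates(models, init_mothers, config=None, n_rep=1,
                        base_seed=0, scenario_name=None):
    """Independent replicates with per-replicate seed streams
    ``default_rng([base_seed, i])`` — reproducible given the base seed."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    out = []
    for i in range(n_rep):
        rng = np.random.default_rng([int(base_seed), i])
        out.append(simulate_dataset(models, init_mothers, config, seed=rng,
                                    scenario_name=scenario_name, replicate=i))
    return out


def realism_check(real: Dataset, simulated: list[Dataset]) -> pd.DataFrame:
    """Compare fertility/twinning summaries between the real data and the
    simulation replicates: real value vs replicate mean and 95% central
    range."""

    def metrics(ds: Dataset):
        return {
            "twinning_rate_permille": 1000 * ds.births["twin"].mean(),
            "twinner_rate_permille": 1000 * ds.mothers["twinner"].mean(),
            "mean_births": ds.mothers["births_total"].mean(),
            "mean_offspring": ds.births["n_offspring"].sum() / len(ds.mothers),
            "max_births": float(ds.mothers["births_total"].max()),
            "mean_AFB_months": ds.mothers["AFB_months"].mean(),
            "mean_IBI_months": ds.births["IBI_months"].mean(),
        }

    real_m = metrics(real)
    sims = pd.DataFrame([metrics(ds) for ds in simulated])
    rows = []
    for name, rv in real_m.items():
        col = sims[name]
        rows.append({
            "metric": name, "real": rv, "sim_mean": col.mean(),
            "sim_lo": col.quantile(0.025), "sim_hi": col.quantile(0.975),
        })
    return pd.DataFrame(rows)
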