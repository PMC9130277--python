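"""Synthetic parish-register generator with known ground truth.

The generator runs the same career loop as the simulator, but driven by
*chosen* parameters rather than fitted ones: each life-history event (parity
progression, interbirth interval, twinning) has an intercept, optional twin
effect, polynomial age/parity effects on a fixed standardised scale, and
Gaussian population and maternal intercepts — the maternal intercepts of the
three traits drawn jointly with a configurable correlation matrix so worlds
with positive or negative coupling between twinning propensity and intrinsic
fertility can be constructed.  Careers are then disaggregated into per-child
rows with concrete calendar dates (twins on the same or adjacent days), the
exact raw format the ingestion pipeline consumes, so twin identification and
filtering can be tested against known truth.

Presets
-------
``paper_like``
    Pre-industrial European regime: ~1.7% of births are twin deliveries with
    an age peak in the mid/late thirties and a parity-1 excess, mean ~4.8
    births per mother, age at first birth ~26 y, twin deliveries reducing
    subsequent parity progression and slightly shortening the next interval,
    and a weak negative correlation between twinning propensity and the
    maternal parity-progression effect.
``null_world``
    Twinning is a constant-probability coin flip: no age/parity effects, no
    maternal or population heterogeneity on twinning, no twin effects on
    parity progression or intervals.
``strong_P``
    Like paper_like but with a large negative twin effect on parity
    progression and no other twinning mechanism.
``H_positive`` / ``H_negative``
    Strong positive / negative correlation between the maternal twinning and
    parity-progression intercepts, with twin effects and age/parity effects
    on twinning switched off (pure heterogeneity worlds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .glmm import FittedModel, ModelSpec
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "TraitParams",
    "TruthParameters",
    "make_truth",
    "truth_models",
    "generate_dataset",
    "inject_defects",
]

# fixed standardisation used by all truth polynomials (age in months)
_POLY_TRANSFORM = {"age_center": 360.0, "age_scale": 96.0,
                   "parity_center": 3.5, "parity_scale": 2.5}


@dataclass(frozen=True)
class TraitParams:
    """One life-history event: linear predictor on its link scale."""

    intercept: float
    twin: float = 0.0                      # effect of a twin delivery (PP/IBI)
    poly: dict = field(default_factory=dict)   # name -> coef, e.g. "age^1.parity^0"
    sigma_maternal: float = 0.0
    sigma_population: float = 0.0
    shape: float | None = None             # NB2 dispersion (IBI only)

    def __post_init__(self):
        if self.sigma_maternal < 0 or self.sigma_population < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class TruthParameters:
    pp: TraitParams
    ibi: TraitParams
    t: TraitParams
    afb_mean_months: float = 132.0         # above the 15-year minimum
    afb_shape: float = 12.0
    afb_min_months: int = 180
    n_populations: int = 8
    # correlation matrix of the maternal intercepts, order (PP, IBI, T)
    maternal_corr: tuple = ((1.0, 0.0, 0.0),
                            (0.0, 1.0, 0.0),
                            (0.0, 0.0, 1.0))
    preset: str = "custom"


def _poly_order(poly: dict) -> int:
    order = 0
    for name in poly:
        i, j = name.split(".")
        order = max(order, int(i.split("^")[1]) + int(j.split("^")[1]))
    return order


_PAPER_LIKE = TruthParameters(
    pp=TraitParams(intercept=1.80, twin=-0.45,
                   poly={"age^1.parity^0": -1.30, "age^0.parity^1": -0.25,
                         "age^2.parity^0": -0.35},
                   sigma_maternal=0.70, sigma_population=0.20),
    ibi=TraitParams(intercept=np.log(26.0), twin=-0.035,
                    poly={"age^1.parity^0": -0.06, "age^0.parity^1": 0.11},
                    sigma_maternal=0.12, sigma_population=0.05, shape=5.0),
    t=TraitParams(intercept=-4.14,
                  poly={"age^1.parity^0": 0.45, "age^0.parity^1": -0.10,
                        "age^2.parity^0": -0.25},
                  sigma_maternal=0.60, sigma_population=0.25),
    maternal_corr=((1.0, 0.0, -0.30),
                   (0.0, 1.0, 0.30),
                   (-0.30, 0.30, 1.0)),
    preset="paper_like",
)


def make_truth(preset: str, seed: int = 0) -> TruthParameters:
    """Build the ground-truth parameter set for a named preset."""
    if preset == "paper_like":
        return _PAPER_LIKE
    if preset == "null_world":
        return replace(
            _PAPER_LIKE,
            pp=replace(_PAPER_LIKE.pp, twin=0.0),
            ibi=replace(_PAPER_LIKE.ibi, twin=0.0),
            t=TraitParams(intercept=-4.07),
            maternal_corr=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            preset="null_world")
    if preset == "strong_P":
        return replace(
            _PAPER_LIKE,
            pp=replace(_PAPER_LIKE.pp, twin=-1.5),
            ibi=replace(_PAPER_LIKE.ibi, twin=0.0),
            t=TraitParams(intercept=-4.07, sigma_population=0.1),
            maternal_corr=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
            preset="strong_P")
    if preset in ("H_positive", "H_negative"):
        rho = 0.6 if preset == "H_positive" else -0.6
        return replace(
            _PAPER_LIKE,
            pp=replace(_PAPER_LIKE.pp, twin=0.0),
            ibi=replace(_PAPER_LIKE.ibi, twin=0.0),
            t=TraitParams(intercept=-4.25, sigma_maternal=0.8,
                          sigma_population=0.1),
            maternal_corr=((1.0, 0.0, rho), (0.0, 1.0, 0.0), (rho, 0.0, 1.0)),
            preset=preset)
    raise ValueError(f"unknown preset {preset!r}")


def _trait_model(trait: TraitParams, which: str, re_modes: dict) -> FittedModel:
    """Wrap truth parameters as a fitted-model object the simulator accepts."""
    family = {"pp": "binomial", "ibi": "negbin", "t": "binomial"}[which]
    terms, names, coefs = [], ["(Intercept)"], [trait.intercept]
    if trait.twin != 0.0 and which in ("pp", "ibi"):
        terms.append("twin")
        names.append("twin")
        coefs.append(trait.twin)
    order = _poly_order(trait.poly)
    if order:
        terms.append("poly")
        for total in range(1, order + 1):
            for i in range(total, -1, -1):
                nm = f"age^{i}.parity^{total - i}"
                names.append(nm)
                coefs.append(trait.poly.get(nm, 0.0))
    res = tuple(k for k in ("maternal_id", "population_id")
                if k in re_modes and re_modes[k] is not None)
    spec = ModelSpec(f"truth_{which}", which.upper(), family,
                     tuple(terms), order or None, res)
    sigma2 = {}
    if "maternal_id" in res:
        sigma2["maternal_id"] = trait.sigma_maternal**2
    if "population_id" in res:
        sigma2["population_id"] = trait.sigma_population**2
    beta = pd.Series(coefs, index=names)
    return FittedModel(
        spec=spec, beta=beta, sigma2=sigma2, shape=trait.shape,
        loglik=np.nan, aic=np.nan,
        re_modes={k: re_modes[k] for k in res},
        se_beta=pd.Series(np.nan, index=names),
        design_info={"poly_transform": dict(_POLY_TRANSFORM)} if order else {},
        converged=True, n_obs=0, method="truth")


def truth_models(truth: TruthParameters, n_mothers: int, seed: int = 0):
    """Draw random effects and return ``(models, init_mothers, effects)``.

    ``models`` is the (PP, IBI, T) triple wrapping the truth parameters with
    the drawn per-mother and per-population intercepts; ``init_mothers``
    carries identities, populations and ages at first birth.
    """
    rng = np.random.default_rng(seed)
    mids = pd.Index([f"M{i:06d}" for i in range(n_mothers)])
    pops = pd.Index([f"pop{chr(65 + i)}" for i in range(truth.n_populations)])
    pop_of = rng.integers(0, truth.n_populations, size=n_mothers)

    sds = np.array([truth.pp.sigma_maternal, truth.ibi.sigma_maternal,
                    truth.t.sigma_maternal])
    corr = np.asarray(truth.maternal_corr, dtype=float)
    cov = np.outer(sds, sds) * corr
    # svd handles the positive-semidefinite case (traits with zero variance)
    u_mat = rng.multivariate_normal(np.zeros(3), cov, size=n_mothers,
                                    method="svd")

    traits = {"pp": truth.pp, "ibi": truth.ibi, "t": truth.t}
    u_pop = {k: rng.normal(0.0, tr.sigma_population, truth.n_populations)
             for k, tr in traits.items()}

    afb = truth.afb_min_months + rng.negative_binomial(
        truth.afb_shape,
        truth.afb_shape / (truth.afb_shape + truth.afb_mean_months),
        size=n_mothers)
    init = pd.DataFrame({"maternal_id": mids, "population_id": pops[pop_of],
                         "AFB_months": afb.astype(float)})

    models = []
    for col, key in enumerate(["pp", "ibi", "t"]):
        tr = traits[key]
        re_modes = {
            "maternal_id": (pd.Series(u_mat[:, col], index=mids)
                            if tr.sigma_maternal > 0 else None),
            "population_id": (pd.Series(u_pop[key], index=pops)
                              if tr.sigma_population > 0 else None),
        }
        models.append(_trait_model(tr, key, re_modes))
    effects = {"maternal": pd.DataFrame(u_mat, index=mids,
                                        columns=["u_pp", "u_ibi", "u_t"]),
               "population": pd.DataFrame(u_pop, index=pops)}
    return tuple(models), init, effects


def generate_dataset(truth: TruthParameters, n_mothers: int, seed: int = 0,
                     config: SimulationConfig | None = None):
    """Generate raw per-child records plus ground-truth tables.

    Returns ``(children, ground_truth)`` where ``children`` has the exact
    schema of the ingestion CSV (twins written out as individual children
    with same-or-adjacent-day dates) and ``ground_truth`` carries the birth
    and mother tables, drawn random effects and the truth parameters.
    """
    rng = np.random.default_rng(seed)
    models, init, effects = truth_models(truth, n_mothers,
                                         seed=rng.integers(2**31))
    ds = simulate_dataset(models, init, config or SimulationConfig(),
                          seed=np.random.default_rng(rng.integers(2**31)))

    mat_year = pd.Series(rng.integers(1700, 1851, size=n_mothers).astype(int),
                         index=init["maternal_id"])
    mat_month = pd.Series(rng.integers(1, 13, size=n_mothers).astype(int),
                          index=init["maternal_id"])

    b = ds.births
    my = mat_year.reindex(b["maternal_id"]).to_numpy()
    mm = mat_month.reindex(b["maternal_id"]).to_numpy()
    tot = mm - 1 + b["age_months"].to_numpy().astype(int)
    cy, cm = my + tot // 12, 1 + tot % 12
    day0 = rng.integers(1, 27, size=len(b))
    # twins expand to two children, same day or one day apart
    reps = np.where(b["twin"].to_numpy() == 1, 2, 1)
    idx = np.repeat(np.arange(len(b)), reps)
    sibling = np.concatenate([np.arange(r) for r in reps])
    offset1 = rng.random(len(b)) < 0.5
    day = day0[idx] + np.where(offset1[idx], sibling, 0)
    children = pd.DataFrame({
        "population_id": b["population_id"].to_numpy()[idx],
        "maternal_id": b["maternal_id"].to_numpy()[idx],
        "maternal_birth_year": my[idx], "maternal_birth_month": mm[idx],
        "child_birth_year": cy[idx], "child_birth_month": cm[idx],
        "child_birth_day": day, "followup_to_45": True,
    })
    children = children.sort_values(
        ["population_id", "maternal_id", "child_birth_year",
         "child_birth_month", "child_birth_day"]).reset_index(drop=True)
    ground_truth = {"births": ds.births, "mothers": ds.mothers,
                    "effects": effects, "truth": truth}
    return children, ground_truth


def inject_defects(children: pd.DataFrame, rates: dict, seed: int = 0):
    """Corrupt a fraction of families so the selection filters must drop them.

    ``rates`` maps defect name to the fraction of mothers affected:
    ``month_missing`` blanks one child's birth month, ``truncate_followup``
    clears the follow-up-to-45 flag, ``squeeze_gap`` moves a mother's second
    delivery to eight months after her first.  Defects are assigned to
    disjoint mothers; returns ``(corrupted, manifest)``.
    """
    for k, v in rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rate {k} outside [0, 1]")
    out = children.copy()
    rng = np.random.default_rng(seed)
    mothers = out["maternal_id"].unique()
    rng.shuffle(mothers)
    manifest = []
    pos = 0
    for defect in ("month_missing", "truncate_followup", "squeeze_gap"):
        k = int(round(rates.get(defect, 0.0) * len(mothers)))
        chosen = []
        while len(chosen) < k and pos < len(mothers):
            mid = mothers[pos]
            pos += 1
            rows = out.index[out["maternal_id"] == mid]
            if defect == "month_missing":
                out.loc[rows[0], "child_birth_month"] = pd.NA
            elif defect == "truncate_followup":
                out.loc[rows, "followup_to_45"] = False
            else:
                sub = out.loc[rows].sort_values(
                    ["child_birth_year", "child_birth_month",
                     "child_birth_day"])
                ym = (sub["child_birth_year"] * 12
                      + sub["child_birth_month"] - 1)
                events = sorted(ym.unique())
                if len(events) < 2:
                    continue  # single delivery: no gap to squeeze
                first, second = events[0], events[1]
                tgt = sub.index[ym == second]
                new = first + 8
                out.loc[tgt, "child_birth_year"] = new // 12
                out.loc[tgt, "child_birth_month"] = new % 12 + 1
            chosen.append(mid)
            manifest.append({"maternal_id": mid, "defect": defect})
    out["child_birth_month"] = out["child_birth_month"].astype("Int64")
    return out, pd.DataFrame(manifest, columns=["maternal_id", "defect"])
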