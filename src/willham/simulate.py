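"""Synthetic pedigrees and growth records with the model's exact structure.

The generator emulates a closed beef herd recorded over discrete
generations: a founder cohort, matings of previous-generation sires and
dams (few sires, many dams), and four correlated weight traits built
additively from contemporary-group, sex and dam-age fixed effects, direct
breeding values on all traits, maternal breeding values and permanent-
environment effects of the dam on the pre-weaning traits, and a jointly
normal residual.  Breeding values follow the pedigree exactly: founders are
N(0, G) and descendants are the parent average plus a Mendelian-sampling
deviation with covariance G * (0.5 - 0.25 (F_s + F_d)).

The default generating parameters are posterior-mean estimates published
for pasture-raised Polled Nellore (direct genetic block for all four
weights, maternal block for the two pre-weaning weights, permanent-
environment variances 12.77 and 15.87 kg^2, residual variances 389.64,
573.05, 411.57 and 561.91 kg^2); residual covariances between traits
default to zero since no published values exist.  They are a realistic
stand-in for study-scale truth, not the study's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, validate_pedigree
from .preprocess import TRAITS

__all__ = [
    "TrueParameters",
    "SimulationDesign",
    "simulate_pedigree",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "to_raw_records",
]

# posterior-mean direct (4) + maternal (2) genetic covariance block,
# order: w120a, w240a, w365a, w450a, w120m, w240m
DEFAULT_G = np.array(
    [
        [299.08, 466.46, 442.43, 426.17, -52.57, -75.56],
        [466.46, 905.33, 812.34, 755.04, -53.37, -164.18],
        [442.43, 812.34, 1075.63, 1083.93, 39.25, 21.11],
        [426.17, 755.04, 1083.93, 1142.78, 51.84, 52.44],
        [-52.57, -53.37, 39.25, 51.84, 53.30, 61.60],
        [-75.56, -164.18, 21.11, 52.44, 61.60, 128.37],
    ]
)
DEFAULT_P = np.diag([12.77, 15.87])
DEFAULT_R = np.diag([389.64, 573.05, 411.57, 561.91])


@dataclass
class TrueParameters:
    """Generating truth: covariance blocks, fixed-effect scales, missingness.

    ``herd_sd``/``year_sd``/``season_sd`` are the SDs (kg) of the normal
    draws that create the per-level fixed-effect tables; ``sex_effect`` is
    the male minus female difference per trait and ``dam_age_coef`` the
    linear dam-age slope (kg/year), nonzero by default only for the traits
    where cow age screens significant.  ``missing_rates`` mirror per-trait
    record counts of a weaning-recorded herd: nearly complete pre-weaning
    data, roughly a third of post-weaning weights missing.
    """

    G: np.ndarray = field(default_factory=lambda: DEFAULT_G.copy())
    P: np.ndarray = field(default_factory=lambda: DEFAULT_P.copy())
    R: np.ndarray = field(default_factory=lambda: DEFAULT_R.copy())
    traits: tuple[str, ...] = tuple(TRAITS)
    maternal_traits: tuple[str, ...] = ("w120", "w240")
    pe_traits: tuple[str, ...] = ("w120", "w240")
    trait_means: tuple[float, ...] = (121.6, 183.8, 215.5, 248.5)
    sex_effect: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    dam_age_coef: tuple[float, ...] = (1.5, 1.0, 0.0, 0.0)
    herd_sd: float = 8.0
    year_sd: float = 6.0
    season_sd: float = 5.0
    missing_rates: tuple[float, ...] = (0.08, 0.0, 0.36, 0.33)

    def validate(self) -> None:
        for name, M in (("G", self.G), ("P", self.P), ("R", self.R)):
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                raise ValueError(f"truth block {name} is not positive definite") from None
        if not all(0 <= r <= 1 for r in self.missing_rates):
            raise ValueError("missing_rates must lie in [0, 1]")


@dataclass
class SimulationDesign:
    """Demography of the simulated herd."""

    n_founders: int = 750
    n_generations: int = 5  # total generations including the founder cohort
    offspring_per_dam: int = 2
    # few sires, many dams — but enough sire families (hundreds across
    # generations) that the realized genetic variance is stable between runs
    dams_per_sire: int = 5
    n_herds: int = 7
    base_year: int = 1990
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_founders", "n_generations", "offspring_per_dam", "dams_per_sire", "n_herds"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


def simulate_pedigree(design: SimulationDesign) -> pd.DataFrame:
    """Simulate a discrete-generation pedigree.

    Returns a frame with columns animal, sire, dam, sex, generation.
    Generation 0 is the founder cohort (unknown parents); in each later
    generation every previous-generation dam produces ``offspring_per_dam``
    calves by a sire drawn from a sampled sire team of about one sire per
    ``dams_per_sire`` dams.  Acyclic by construction.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"X{counter:06d}"

    cohort = []
    for _ in range(design.n_founders):
        aid = new_id()
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((aid, "0", "0", sex, 0))
        cohort.append((aid, sex))

    for g in range(1, design.n_generations):
        males = [a for a, s in cohort if s == "M"]
        females = [a for a, s in cohort if s == "F"]
        if not males or not females:
            break
        n_sires = max(1, round(len(females) / design.dams_per_sire))
        sires = list(rng.choice(males, size=min(n_sires, len(males)), replace=False))
        nxt = []
        for dam in females:
            sire = sires[rng.integers(len(sires))]
            for _ in range(design.offspring_per_dam):
                aid = new_id()
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((aid, sire, dam, sex, g))
                nxt.append((aid, sex))
        cohort = nxt

    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])


def simulate_effects(
    ped: Pedigree, truth: TrueParameters, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Breeding values (direct + maternal dims) and pe effects per animal.

    Returns ``(bv, pe)`` with ``bv`` of shape (n, dim G) and ``pe`` of shape
    (n, dim P); pe effects are i.i.d. N(0, P) (only the dam rows are ever
    used downstream).
    """
    truth.validate()
    from .pedigree import inbreeding_coefficients

    n = ped.n
    dimG = truth.G.shape[0]
    L = np.linalg.cholesky(truth.G) if dimG else np.zeros((0, 0))
    F = inbreeding_coefficients(ped)
    bv = np.zeros((n, dimG))
    z = rng.standard_normal((n, dimG))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            bv[i] = z[i] @ L.T
            continue
        mean = np.zeros(dimG)
        if s >= 0 and d >= 0:
            mean = 0.5 * (bv[s] + bv[d])
            scale = 0.5 - 0.25 * (F[s] + F[d])
        else:
            p = s if s >= 0 else d
            mean = 0.5 * bv[p]
            scale = 0.75 - 0.25 * F[p]
        bv[i] = mean + np.sqrt(scale) * (z[i] @ L.T)

    dimP = truth.P.shape[0]
    if dimP:
        Lp = np.linalg.cholesky(truth.P)
        pe = rng.standard_normal((n, dimP)) @ Lp.T
    else:
        pe = np.zeros((n, 0))
    return bv, pe


_SEASON_MONTH = {1: 2, 2: 5, 3: 8, 4: 11}


def simulate_phenotypes(
    ped_df: pd.DataFrame,
    ped: Pedigree,
    bv: np.ndarray,
    pe: np.ndarray,
    truth: TrueParameters,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Adjusted-scale phenotype records for all non-founder animals.

    Each record gets a herd, a birth date (year = base year + generation,
    season uniform), a dam age at calving, and trait values composed
    additively per the model; residuals are drawn jointly from R, then
    trait values are masked completely at random at the truth's per-trait
    rates.  Records losing all traits are kept (they carry factors only and
    are dropped by preprocessing).
    """
    recs = ped_df[ped_df["generation"] > 0].reset_index(drop=True)
    n = len(recs)
    nt = len(truth.traits)

    herd_eff = rng.normal(0, truth.herd_sd, size=(design.n_herds, nt))
    years = sorted(recs["generation"].unique())
    year_eff = {g: rng.normal(0, truth.year_sd, size=nt) for g in years}
    season_eff = rng.normal(0, truth.season_sd, size=(4, nt))

    herd = rng.integers(0, design.n_herds, size=n)
    season = rng.integers(1, 5, size=n)
    dam_age = rng.uniform(3.0, 10.0, size=n)
    resid = rng.standard_normal((n, nt)) @ np.linalg.cholesky(truth.R).T

    a_idx = recs["animal"].map(ped.index).to_numpy()
    d_idx = recs["dam"].map(ped.index).to_numpy()

    direct = bv[a_idx][:, : nt]
    y = np.tile(truth.trait_means, (n, 1)).astype(float)
    y += herd_eff[herd]
    y += np.stack([year_eff[g] for g in recs["generation"]])
    y += season_eff[season - 1]
    y += np.outer((recs["sex"] == "M").to_numpy(float), truth.sex_effect)
    y += np.outer(dam_age - dam_age.mean(), truth.dam_age_coef)
    y += direct
    for j, t in enumerate(truth.maternal_traits):
        ti = truth.traits.index(t)
        y[:, ti] += bv[d_idx, nt + j]
    for j, t in enumerate(truth.pe_traits):
        ti = truth.traits.index(t)
        y[:, ti] += pe[d_idx, j]
    y += resid

    mask = rng.random((n, nt)) < np.asarray(truth.missing_rates)
    y[mask] = np.nan

    year = design.base_year + recs["generation"].to_numpy()
    month = np.vectorize(_SEASON_MONTH.get)(season)
    out = pd.DataFrame(
        {
            "animal": recs["animal"],
            "sire": recs["sire"],
            "dam": recs["dam"],
            "herd": (herd + 1).astype(str),
            "birth_date": [f"{yy}-{mm:02d}-15" for yy, mm in zip(year, month)],
            "sex": recs["sex"],
            "dam_age": np.round(dam_age, 2),
        }
    )
    for j, t in enumerate(truth.traits):
        out[t] = y[:, j]
    out["cg"] = out["herd"] + "-" + pd.Series(year).astype(str) + "-" + pd.Series(season).astype(str)
    return out


def to_raw_records(adjusted: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Back-transform adjusted records into raw weighing records.

    Inverts the adjustment formulas from (W120, W240, W365): the weaning
    age is drawn uniformly in [180, 300] d and the last weighing age in
    [420, 560] d, then BW, WW, AW are solved so that re-adjustment
    reproduces W120, W240, W365 exactly.  Because W365 and W450 both derive
    from the single post-weaning gain, W450 is the implied value
    ``W240 + 210 (W365 - W240)/125`` — exactly as in real data, where both
    are computed from the same pair of weighings.
    """
    df = adjusted.copy()
    n = len(df)
    wa = rng.integers(180, 301, size=n).astype(float)
    ia = rng.integers(420, 561, size=n).astype(float)
    pre = (df["w240"] - df["w120"]) / 120.0
    bw = df["w120"] - 120.0 * pre
    ww = bw + wa * pre
    post = (df["w365"] - df["w240"]) / 125.0
    aw = df["w240"] + (ia - 240.0) * post
    out = df[["animal", "sire", "dam", "herd", "birth_date", "sex", "dam_age"]].copy()
    out["bw"] = bw
    out["ww"] = ww
    out["weaning_age"] = np.where(ww.notna(), wa, np.nan)
    out["aw"] = aw
    out["last_age"] = np.where(aw.notna(), ia, np.nan)
    return out


def simulate_dataset(
    design: SimulationDesign, truth: TrueParameters | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, Pedigree]:
    """Pedigree frame, adjusted phenotype records and the Pedigree object.

    One call, one seed (``design.seed``), bit-reproducible.
    """
    truth = truth or TrueParameters()
    ped_df = simulate_pedigree(design)
    ped = validate_pedigree(ped_df[["animal", "sire", "dam"]].itertuples(index=False))
    rng = np.random.default_rng(design.seed + 1)
    bv, pe = simulate_effects(ped, truth, rng)
    records = simulate_phenotypes(ped_df, ped, bv, pe, truth, design, rng)
    return ped_df, records, ped
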