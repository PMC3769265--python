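"""Gibbs sampling of (co)variance components for the animal model.

The sampler alternates three blocks, in this fixed order each iteration:

1. *Residual augmentation* — unobserved trait values are latent; their
   residuals are drawn from the conditional normal of the residual
   covariance ``R`` given the record's observed-trait residuals.  With every
   record completed, all downstream conditionals take their textbook forms.
2. *Location effects* — fixed effects (flat prior), breeding values and
   permanent-environment effects are sampled single-site (equation by
   equation) from univariate normal full conditionals; the genetic prior is
   ``(a, m) ~ N(0, G (x) A)`` with the sparse ``A``-inverse entering the
   conditionals directly.
3. *Covariance matrices* — ``G | rest`` is inverse-Wishart with scale equal
   to the ``A``-inverse-weighted cross-products of the stacked effect
   vectors; ``P`` and ``R`` analogously from permanent-environment effects
   and (augmented) residuals.

With the ``flat`` prior (improper limit, density proportional to a
constant) the inverse-Wishart degrees of freedom are ``q - dim - 1``; a
proper ``weak`` preset is provided because the improper prior can yield an
improper posterior on very small data sets.

All randomness flows through one ``numpy.random.Generator`` seeded from
``ChainSettings.seed``; draw order is pinned by the sweep order above, so a
chain is bit-reproducible for a given package version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import invwishart

from ._kernels import location_sweep
from .model import ModelMatrices, missing_patterns
from .pedigree import RelationshipInverse

logger = logging.getLogger("willham.gibbs")

__all__ = [
    "CovarianceComponents",
    "PriorSpec",
    "ChainSettings",
    "PosteriorSamples",
    "GibbsState",
    "run_chain",
    "write_samples",
    "read_samples",
]


@dataclass
class CovarianceComponents:
    """Genetic, permanent-environment and residual covariance matrices (kg^2).

    ``g_labels`` names the rows of ``G`` as ``(trait, kind)`` pairs with kind
    ``"direct"`` or ``"maternal"``; ``P`` is indexed by ``pe_traits`` and
    ``R`` by ``traits``.
    """

    G: np.ndarray
    P: np.ndarray
    R: np.ndarray
    g_labels: list[tuple[str, str]]
    pe_traits: tuple[str, ...]
    traits: tuple[str, ...]

    def check_pd(self) -> None:
        for name, M in (("G", self.G), ("P", self.P), ("R", self.R)):
            if M.size:
                try:
                    np.linalg.cholesky(M)
                except np.linalg.LinAlgError:
                    raise ValueError(f"{name} is not positive definite") from None

    def variance(self, trait: str, kind: str) -> float:
        if kind == "pe":
            return float(self.P[self.pe_traits.index(trait)][self.pe_traits.index(trait)])
        if kind == "residual":
            i = self.traits.index(trait)
            return float(self.R[i, i])
        i = self.g_labels.index((trait, kind))
        return float(self.G[i, i])


@dataclass
class PriorSpec:
    """Inverse-Wishart priors for the covariance blocks; flat for locations.

    ``*_df`` are the prior degrees of freedom (added to the data counts in
    the full conditionals) and ``*_scale`` the prior scale matrices.  The
    ``flat`` preset is the improper constant-density limit,
    ``df = -(dim + 1)`` with zero scale; ``weak`` is a barely informative
    proper prior, ``df = dim + 2`` with a small identity scale.
    """

    g_df: float
    g_scale: np.ndarray
    p_df: float
    p_scale: np.ndarray
    r_df: float
    r_scale: np.ndarray
    name: str = "custom"

    @classmethod
    def flat(cls, dim_g: int, dim_p: int, dim_r: int) -> "PriorSpec":
        return cls(
            g_df=-(dim_g + 1), g_scale=np.zeros((dim_g, dim_g)),
            p_df=-(dim_p + 1), p_scale=np.zeros((dim_p, dim_p)),
            r_df=-(dim_r + 1), r_scale=np.zeros((dim_r, dim_r)),
            name="flat",
        )

    @classmethod
    def weak(cls, dim_g: int, dim_p: int, dim_r: int, scale: float = 0.01) -> "PriorSpec":
        return cls(
            g_df=dim_g + 2, g_scale=scale * np.eye(dim_g),
            p_df=dim_p + 2, p_scale=scale * np.eye(dim_p),
            r_df=dim_r + 2, r_scale=scale * np.eye(dim_r),
            name="weak",
        )


@dataclass
class ChainSettings:
    """MCMC run length controls.

    The ``desk`` preset (default) is sized for interactive work; ``paper``
    mirrors a production protocol of 1.5M iterations with a 500k burn-in and
    a sampling interval of 1000.
    """

    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in > self.iterations:
            raise ValueError("burn_in must not exceed iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "ChainSettings":
        if name == "desk":
            return cls(seed=seed)
        if name == "paper":
            return cls(iterations=1_500_000, burn_in=500_000, thin=1000, seed=seed)
        raise ValueError(f"unknown preset {name!r}")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained covariance-component samples plus run metadata."""

    G: np.ndarray  # (n_samples, dimG, dimG)
    P: np.ndarray
    R: np.ndarray
    g_labels: list[tuple[str, str]]
    pe_traits: tuple[str, ...]
    traits: tuple[str, ...]
    settings: ChainSettings
    prior_name: str = "flat"
    location: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.R.shape[0]

    def component(self, i: int) -> CovarianceComponents:
        return CovarianceComponents(
            G=self.G[i], P=self.P[i], R=self.R[i],
            g_labels=self.g_labels, pe_traits=self.pe_traits, traits=self.traits,
        )

    def mean_components(self) -> CovarianceComponents:
        return CovarianceComponents(
            G=self.G.mean(axis=0), P=self.P.mean(axis=0), R=self.R.mean(axis=0),
            g_labels=self.g_labels, pe_traits=self.pe_traits, traits=self.traits,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per retained iterate, upper-triangle columns."""
        cols: dict[str, np.ndarray] = {}
        suff = {"direct": "a", "maternal": "m"}
        gl = [f"{t}{suff[k]}" for t, k in self.g_labels]
        for i, a in enumerate(gl):
            for j, b in enumerate(gl[i:], start=i):
                cols[f"G_{a}_{b}"] = self.G[:, i, j]
        for i, a in enumerate(self.pe_traits):
            for j, b in enumerate(self.pe_traits[i:], start=i):
                cols[f"P_{a}_{b}"] = self.P[:, i, j]
        for i, a in enumerate(self.traits):
            for j, b in enumerate(self.traits[i:], start=i):
                cols[f"R_{a}_{b}"] = self.R[:, i, j]
        return pd.DataFrame(cols)


def write_samples(samples: PosteriorSamples, path) -> None:
    """Delimited samples file with ``#`` metadata header lines."""
    s = samples.settings
    with open(path, "w") as fh:
        fh.write(f"# iterations={s.iterations} burn_in={s.burn_in} thin={s.thin} seed={s.seed}\n")
        fh.write(f"# traits={','.join(samples.traits)}\n")
        fh.write(f"# maternal={','.join(t for t, k in samples.g_labels if k == 'maternal')}\n")
        fh.write(f"# pe={','.join(samples.pe_traits)}\n")
        fh.write(f"# prior={samples.prior_name}\n")
        samples.to_frame().to_csv(fh, index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class GibbsState:
    """Mutable sampler state: location effects, residuals, covariances."""

    theta: np.ndarray
    e: np.ndarray
    comp: CovarianceComponents
    iteration: int = 0


class _System:
    """Flattened equation structure shared by all sweeps of one chain."""

    def __init__(self, mats: ModelMatrices, ainv: RelationshipInverse):
        spec = mats.spec
        self.mats = mats
        n_rec, n_traits = mats.y.shape
        n_ped = mats.ped.n
        dimG = len(spec.g_labels)
        dimP = len(spec.pe_traits)
        self.dimG, self.dimP = dimG, dimP
        self.n_ped, self.n_dam = n_ped, len(mats.pe_ids)

        trait_of_gdim = [spec.traits.index(t) for t, _ in spec.g_labels]
        trait_of_pdim = [spec.traits.index(t) for t in spec.pe_traits]

        eq_trait: list[int] = []
        rows: list[np.ndarray] = []
        wts: list[np.ndarray] = []

        for ti, X in enumerate(mats.X):
            Xc = X.tocsc()
            for j in range(Xc.shape[1]):
                rows.append(Xc.indices[Xc.indptr[j]:Xc.indptr[j + 1]].astype(np.int64))
                wts.append(Xc.data[Xc.indptr[j]:Xc.indptr[j + 1]].astype(np.float64))
                eq_trait.append(ti)
        self.geq_start = len(eq_trait)

        def grouped(idx: np.ndarray, n_levels: int) -> list[np.ndarray]:
            out: list[list[int]] = [[] for _ in range(n_levels)]
            for r, i in enumerate(idx):
                if i >= 0:
                    out[i].append(r)
            return [np.asarray(v, dtype=np.int64) for v in out]

        by_animal = grouped(mats.animal_idx, n_ped) if dimG else []
        by_dam_ped = grouped(mats.dam_idx, n_ped) if spec.maternal_traits else []
        by_dam_pe = grouped(mats.pe_idx, self.n_dam) if dimP else []

        for u in range(dimG):
            kind = spec.g_labels[u][1]
            groups = by_animal if kind == "direct" else by_dam_ped
            for i in range(n_ped):
                rows.append(groups[i])
                wts.append(np.ones(len(groups[i])))
                eq_trait.append(trait_of_gdim[u])
        self.peq_start = len(eq_trait)

        for w in range(dimP):
            for l in range(self.n_dam):
                rows.append(by_dam_pe[l])
                wts.append(np.ones(len(by_dam_pe[l])))
                eq_trait.append(trait_of_pdim[w])

        self.n_eq = len(eq_trait)
        self.eq_trait = np.asarray(eq_trait, dtype=np.int64)
        lens = np.array([len(r) for r in rows], dtype=np.int64)
        self.indptr = np.zeros(self.n_eq + 1, dtype=np.int64)
        np.cumsum(lens, out=self.indptr[1:])
        self.rec_idx = np.concatenate(rows) if rows else np.zeros(0, np.int64)
        self.wt = np.concatenate(wts) if wts else np.zeros(0, np.float64)

        Ai = ainv.matrix.tocsr()
        self.ai_indptr = Ai.indptr.astype(np.int64)
        self.ai_indices = Ai.indices.astype(np.int64)
        self.ai_data = Ai.data.astype(np.float64)
        self.ainv_sparse = Ai

        self.patterns = missing_patterns(mats.obs_mask)


def _start_components(mats: ModelMatrices) -> CovarianceComponents:
    """Half the phenotypic variance to the residual, the rest split equally
    among the genetic/permanent components present for each trait."""
    spec = mats.spec
    vp = np.nanvar(mats.y, axis=0, ddof=1)
    dimG = len(spec.g_labels)
    G = np.zeros((dimG, dimG))
    for u, (t, kind) in enumerate(spec.g_labels):
        ti = spec.traits.index(t)
        n_parts = 1 + (t in spec.maternal_traits) + (t in spec.pe_traits)
        G[u, u] = 0.5 * vp[ti] / n_parts
    dimP = len(spec.pe_traits)
    P = np.zeros((dimP, dimP))
    for w, t in enumerate(spec.pe_traits):
        ti = spec.traits.index(t)
        P[w, w] = 0.5 * vp[ti] / 3
    R = np.diag(0.5 * vp)
    return CovarianceComponents(
        G=G, P=P, R=R, g_labels=spec.g_labels,
        pe_traits=tuple(spec.pe_traits), traits=tuple(spec.traits),
    )


def augment_missing(state: GibbsState, sys: _System, rng: np.random.Generator) -> None:
    """Redraw residuals of unobserved traits from their conditional normal."""
    R = state.comp.R
    e = state.e
    for pat, idx in sys.patterns:
        obs = np.asarray(pat)
        if obs.all():
            continue
        miss = ~obs
        Roo = R[np.ix_(obs, obs)]
        Rmo = R[np.ix_(miss, obs)]
        Rmm = R[np.ix_(miss, miss)]
        B = linalg.solve(Roo, Rmo.T, assume_a="pos").T
        C = Rmm - B @ Rmo.T
        L = np.linalg.cholesky(C)
        mean = e[np.ix_(idx, np.where(obs)[0])] @ B.T
        zdraw = rng.standard_normal((len(idx), int(miss.sum())))
        e[np.ix_(idx, np.where(miss)[0])] = mean + zdraw @ L.T


def sample_location(state: GibbsState, sys: _System, rng: np.random.Generator) -> None:
    """One single-site Gauss–Seidel sampling sweep over all location effects."""
    comp = state.comp
    Rinv = np.linalg.inv(comp.R)
    Ginv = np.linalg.inv(comp.G) if comp.G.size else np.zeros((0, 0))
    Pinv = np.linalg.inv(comp.P) if comp.P.size else np.zeros((0, 0))
    z = rng.standard_normal(sys.n_eq)
    bad = location_sweep(
        state.theta, state.e, z, Rinv, Ginv, Pinv,
        sys.eq_trait, sys.indptr, sys.rec_idx, sys.wt,
        sys.geq_start, sys.n_ped, sys.ai_indptr, sys.ai_indices, sys.ai_data,
        sys.peq_start, max(sys.n_dam, 1),
    )
    if bad >= 0:
        raise RuntimeError(f"zero conditional precision at equation {bad} (aliasing?)")


def sample_covariances(
    state: GibbsState, sys: _System, prior: PriorSpec, rng: np.random.Generator
) -> None:
    """Draw G, P, R from their inverse-Wishart full conditionals."""
    th = state.theta
    it = state.iteration

    def draw(S: np.ndarray, df: float, what: str) -> np.ndarray:
        dim = S.shape[0]
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise RuntimeError(f"{what} scale not positive definite at iterate {it}") from None
        M = invwishart.rvs(df=df, scale=S, random_state=rng)
        M = np.atleast_2d(M)
        return 0.5 * (M + M.T)

    if sys.dimG:
        U = th[sys.geq_start:sys.peq_start].reshape(sys.dimG, sys.n_ped).T
        S = U.T @ (sys.ainv_sparse @ U)
        S = 0.5 * (S + S.T)
        state.comp.G = draw(S + prior.g_scale, sys.n_ped + prior.g_df, "G")
    if sys.dimP:
        E = th[sys.peq_start:].reshape(sys.dimP, sys.n_dam).T
        S = E.T @ E
        state.comp.P = draw(S + prior.p_scale, sys.n_dam + prior.p_df, "P")
    n_rec = state.e.shape[0]
    S = state.e.T @ state.e
    state.comp.R = draw(S + prior.r_scale, n_rec + prior.r_df, "R")


def _check_proper(sys: _System, prior: PriorSpec) -> None:
    checks = [
        ("G", sys.dimG, sys.n_ped + prior.g_df if sys.dimG else None),
        ("P", sys.dimP, sys.n_dam + prior.p_df if sys.dimP else None),
        ("R", sys.mats.y.shape[1], sys.mats.y.shape[0] + prior.r_df),
    ]
    for name, dim, df in checks:
        if df is not None and df <= dim - 1:
            raise ValueError(
                f"{name} full conditional improper: df {df} <= dim-1 with this prior; "
                "use the 'weak' prior or more data"
            )


def run_chain(
    mats: ModelMatrices,
    ainv: RelationshipInverse,
    prior: PriorSpec | None = None,
    settings: ChainSettings | None = None,
    keep_location: bool = False,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return the retained covariance samples.

    Each iteration performs residual augmentation, a location sweep, then
    the covariance draws; every ``thin``-th post-burn-in state is retained.
    Fully reproducible given ``settings.seed``.
    """
    spec = mats.spec
    settings = settings or ChainSettings()
    dimG, dimP, dimR = len(spec.g_labels), len(spec.pe_traits), len(spec.traits)
    prior = prior or PriorSpec.flat(dimG, dimP, dimR)
    sys = _System(mats, ainv)
    _check_proper(sys, prior)
    rng = np.random.default_rng(settings.seed)

    comp = _start_components(mats)
    e = np.where(mats.obs_mask, mats.y, 0.0).astype(np.float64)
    state = GibbsState(theta=np.zeros(sys.n_eq), e=e, comp=comp)

    n_keep = settings.n_retained
    outG = np.zeros((n_keep, dimG, dimG))
    outP = np.zeros((n_keep, dimP, dimP))
    outR = np.zeros((n_keep, dimR, dimR))
    outL = np.zeros((n_keep, sys.n_eq)) if keep_location else None

    kept = 0
    for it in range(1, settings.iterations + 1):
        state.iteration = it
        augment_missing(state, sys, rng)
        sample_location(state, sys, rng)
        sample_covariances(state, sys, prior, rng)
        past = it - settings.burn_in
        if past > 0 and past % settings.thin == 0 and kept < n_keep:
            outG[kept] = state.comp.G
            outP[kept] = state.comp.P
            outR[kept] = state.comp.R
            if outL is not None:
                outL[kept] = state.theta
            kept += 1
    logger.info("chain finished: %d iterations, %d retained", settings.iterations, kept)
    return PosteriorSamples(
        G=outG, P=outP, R=outR, g_labels=spec.g_labels,
        pe_traits=tuple(spec.pe_traits), traits=tuple(spec.traits),
        settings=settings, prior_name=prior.name, location=outL,
    )
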