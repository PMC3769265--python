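"""Genetic parameters derived from (co)variance components.

Under the maternal-effects model the phenotypic variance of a trait is

    sigma2_p = sigma2_a + sigma2_m + sigma_am + sigma2_pe + sigma2_e

(absent terms zero), and the derived parameters are the direct heritability
``h2 = sigma2_a / sigma2_p``, maternal heritability ``m2``, direct–maternal
genetic correlation ``r_am``, permanent-environment ratio ``c2``, residual
ratio ``e2``, and the total heritability

    h2_T = (sigma2_a + 0.5 sigma2_m + 1.5 sigma_am) / sigma2_p

which measures the response to selection on phenotype when both direct and
maternal effects transmit.  Between traits, direct genetic correlations are
the usual covariance-over-geometric-mean-of-variances ratios.

Chains can be summarised either by deriving the parameters at every retained
iterate and averaging (``mean_of_ratios``, the posterior mean of each
parameter — the default) or by deriving once from the posterior-mean
components (``ratio_of_means`` — the only mode that can be checked directly
against published posterior-mean component tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .gibbs import CovarianceComponents, PosteriorSamples

logger = logging.getLogger("willham.posterior")

__all__ = [
    "GeneticParameters",
    "derive_parameters",
    "genetic_correlations",
    "summarize_chain",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed tables)."""
    if np.isnan(x):
        return x
    f = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * f + 0.5) / f)


@dataclass
class GeneticParameters:
    """Derived parameters keyed by (parameter name, trait or trait pair)."""

    values: dict[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def get(self, param: str, pair: str) -> float:
        return self.values.get((param, pair), np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "trait_pair": tp, "value": v}
            for (p, tp), v in self.values.items()
        ]
        return pd.DataFrame(rows)


def derive_parameters(comp: CovarianceComponents) -> GeneticParameters:
    """Willham-model genetic parameters from one set of components.

    Maternal terms (``sigma2_m``, ``sigma_am``, ``m2``, ``r_am``) contribute
    only for traits fitted with a maternal effect; ``r_am`` is reported
    missing when either genetic variance is zero.  All ratios are exact
    arithmetic on the inputs — no shrinkage or clipping — so out-of-range
    values are possible on degenerate inputs and only trigger a warning.
    """
    vals: dict[tuple[str, str], float] = {}
    gl = comp.g_labels
    maternal = [t for t, k in gl if k == "maternal"]

    for t in comp.traits:
        ia = gl.index((t, "direct")) if (t, "direct") in gl else None
        s_a = comp.G[ia, ia] if ia is not None else 0.0
        if t in maternal:
            im = gl.index((t, "maternal"))
            s_m = comp.G[im, im]
            s_am = comp.G[ia, im]
        else:
            s_m = s_am = 0.0
        s_pe = (
            comp.P[comp.pe_traits.index(t), comp.pe_traits.index(t)]
            if t in comp.pe_traits
            else 0.0
        )
        i_r = comp.traits.index(t)
        s_e = comp.R[i_r, i_r]
        s_p = s_a + s_m + s_am + s_pe + s_e

        vals[("sigma2_p", t)] = s_p
        vals[("h2_direct", t)] = s_a / s_p
        vals[("e2", t)] = s_e / s_p
        vals[("h2_total", t)] = (s_a + 0.5 * s_m + 1.5 * s_am) / s_p
        if t in maternal:
            vals[("m2", t)] = s_m / s_p
            vals[("r_am", t)] = (
                s_am / np.sqrt(s_a * s_m) if s_a * s_m > 0 else np.nan
            )
        if t in comp.pe_traits:
            vals[("c2", t)] = s_pe / s_p

    # direct-genetic correlations between traits
    direct = [t for t, k in gl if k == "direct"]
    for i, t1 in enumerate(direct):
        for t2 in direct[i + 1:]:
            i1, i2 = gl.index((t1, "direct")), gl.index((t2, "direct"))
            denom = comp.G[i1, i1] * comp.G[i2, i2]
            vals[("r_g", f"{t1},{t2}")] = (
                comp.G[i1, i2] / np.sqrt(denom) if denom > 0 else np.nan
            )

    for (p, tp), v in vals.items():
        if p in ("h2_direct", "m2", "c2", "e2") and not (0 <= v <= 1):
            logger.warning("%s(%s) = %.3f outside [0, 1]", p, tp, v)
        if p in ("r_am", "r_g") and not np.isnan(v) and abs(v) > 1:
            logger.warning("%s(%s) = %.3f outside [-1, 1]", p, tp, v)
    return GeneticParameters(vals)


def genetic_correlations(G: np.ndarray) -> np.ndarray:
    """Correlation matrix from a covariance block; zero diagonals give NaN."""
    d = np.sqrt(np.diag(G))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = G / np.outer(d, d)
    C[np.outer(d == 0, np.ones_like(d, bool))] = np.nan
    C[np.outer(np.ones_like(d, bool), d == 0)] = np.nan
    return C


def _hpd(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    if np.ptp(x) == 0:
        return float(x[0]), float(x[0])
    lo, hi = az.hdi(np.asarray(x, float), hdi_prob=prob)
    return float(lo), float(hi)


def summarize_chain(
    samples: PosteriorSamples, mode: str = "mean_of_ratios", hdi_prob: float = 0.95
) -> pd.DataFrame:
    """Posterior summary table of the derived genetic parameters.

    ``mean_of_ratios`` derives the parameters at every retained iterate and
    reports their posterior mean, SD and shortest (HPD) interval;
    ``ratio_of_means`` derives once from the posterior-mean components, so
    only the point value is defined and the spread columns are NaN.
    """
    if samples.n_samples < 2:
        raise ValueError("need at least 2 retained samples to summarise")
    if mode == "ratio_of_means":
        pars = derive_parameters(samples.mean_components())
        df = pars.to_frame().rename(columns={"value": "mean"})
        df["sd"] = np.nan
        df["hpd_lo"] = np.nan
        df["hpd_hi"] = np.nan
    elif mode == "mean_of_ratios":
        per_iter = [derive_parameters(samples.component(i)).values for i in range(samples.n_samples)]
        keys = list(per_iter[0])
        rows = []
        for key in keys:
            x = np.array([d[key] for d in per_iter])
            x = x[~np.isnan(x)]
            lo, hi = _hpd(x, hdi_prob) if len(x) else (np.nan, np.nan)
            rows.append(
                {"parameter": key[0], "trait_pair": key[1],
                 "mean": x.mean() if len(x) else np.nan,
                 "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                 "hpd_lo": lo, "hpd_hi": hi}
            )
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df["mode"] = mode
    return df
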