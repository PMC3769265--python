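"""Design-matrix assembly for the multi-trait maternal-effects animal model.

Each trait's observation model is

    y_t = X_t b_t + Z_a a_t + Z_m m_t + Z_pe p_t + e_t

with contemporary group and sex as fixed factors and dam age as a linear
covariate on the traits where it was screened significant.  Direct additive
effects ``a`` span the full pedigree for every trait; maternal genetic ``m``
and maternal permanent-environment ``p`` effects attach to the dam and are
fitted only for the (typically pre-weaning) traits where maternal influence
matters.  Records missing a trait still carry that trait's design row — the
sampler treats unobserved trait values as latent and augments them, which is
what makes the multivariate residual structure tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .pedigree import Pedigree
from .preprocess import TRAITS

logger = logging.getLogger("willham.model")

__all__ = ["ModelSpec", "ModelMatrices", "build_design", "missing_patterns"]


@dataclass
class ModelSpec:
    """Which traits are analysed and which carry maternal structure.

    The default four-trait specification fits direct genetic effects for all
    weights, with maternal genetic and permanent-environment effects on the
    two pre-weaning weights and the dam-age covariate on the traits where it
    screens significant.  ``direct=False`` drops the genetic effects
    entirely (a fixed-effects-only model, useful for conjugate checks).
    """

    traits: tuple[str, ...] = tuple(TRAITS)
    maternal_traits: tuple[str, ...] = ("w120", "w240")
    pe_traits: tuple[str, ...] = ("w120", "w240")
    covariate_traits: tuple[str, ...] = ("w120", "w240")
    direct: bool = True

    def __post_init__(self) -> None:
        if not set(self.maternal_traits) <= set(self.traits):
            raise ValueError("maternal_traits must be a subset of traits")
        if not set(self.pe_traits) <= set(self.maternal_traits):
            raise ValueError("pe_traits must be a subset of maternal_traits")
        if not self.direct and self.maternal_traits:
            raise ValueError("maternal effects require direct effects")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def g_labels(self) -> list[tuple[str, str]]:
        """Row/column labels of the genetic covariance block."""
        if not self.direct:
            return []
        return [(t, "direct") for t in self.traits] + [
            (t, "maternal") for t in self.maternal_traits
        ]


@dataclass
class ModelMatrices:
    """Assembled response, incidence and index structures for the sampler."""

    spec: ModelSpec
    y: np.ndarray                       # (n_rec, n_traits), NaN where missing
    obs_mask: np.ndarray                # bool, same shape
    X: list[sparse.csc_matrix]          # per trait, n_rec x p_t
    x_names: list[list[str]]            # column labels per trait
    animal_idx: np.ndarray              # record -> pedigree index
    dam_idx: np.ndarray                 # record -> pedigree index of dam, -1 unknown
    pe_idx: np.ndarray                  # record -> dam-level index, -1 unknown
    pe_ids: list[str]                   # dam identifiers backing the pe block
    ped: Pedigree
    record_ids: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_equations(self) -> int:
        n = sum(X.shape[1] for X in self.X)
        if self.spec.direct:
            n += len(self.spec.g_labels) * self.ped.n
        n += len(self.spec.pe_traits) * len(self.pe_ids)
        return n


def _drop_aliased(X: np.ndarray, names: list[str], trait: str) -> tuple[np.ndarray, list[str]]:
    """Remove linearly dependent columns, keeping the pivoted leading set."""
    if X.shape[1] == 0:
        return X, names
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        logger.warning("trait %s: dropping aliased fixed columns %s", trait, dropped)
        keep = np.sort(piv[:rank])
        return X[:, keep], [names[j] for j in keep]
    return X, names


def build_design(records: pd.DataFrame, ped: Pedigree, spec: ModelSpec) -> ModelMatrices:
    """Assemble :class:`ModelMatrices` from adjusted records and a pedigree.

    Every record animal must be in the pedigree.  Records observed for none
    of the spec's traits are dropped.  Unknown dams get no maternal or pe
    equation; their calves' maternal contribution is omitted with a warning.
    """
    df = records.reset_index(drop=True)
    missing_traits = [t for t in spec.traits if t not in df or df[t].notna().sum() == 0]
    if missing_traits:
        raise ValueError(f"traits with zero records: {missing_traits}")

    absent = sorted(set(df["animal"].astype(str)) - set(ped.ids))
    if absent:
        raise ValueError(f"record animals absent from pedigree: {absent[:10]}")

    df = df[df[list(spec.traits)].notna().any(axis=1)].reset_index(drop=True)
    n = len(df)
    y = df[list(spec.traits)].to_numpy(float)
    obs = ~np.isnan(y)

    animal_idx = df["animal"].astype(str).map(ped.index).to_numpy(np.int64)

    dam = df["dam"].astype(str)
    dam_known = dam.notna() & (dam != "0") & (dam != "nan") & dam.isin(ped.index)
    if spec.maternal_traits and (~dam_known).any():
        logger.warning(
            "%d records have unknown dams; their maternal terms are omitted",
            int((~dam_known).sum()),
        )
    dam_idx = np.where(dam_known, dam.map(ped.index).fillna(-1), -1).astype(np.int64)

    pe_ids = sorted(set(dam[dam_known]))
    pe_map = {d: i for i, d in enumerate(pe_ids)}
    pe_idx = np.where(dam_known, dam.map(pe_map).fillna(-1), -1).astype(np.int64)

    cg = df["cg"].astype(str)
    cg_levels = sorted(cg.unique())
    sex = df["sex"].astype(str).str.upper().str[0]
    has_sex_contrast = sex.nunique() > 1
    dam_age = pd.to_numeric(df.get("dam_age"), errors="coerce")

    Xs, names_per_trait = [], []
    for t in spec.traits:
        cols = [(f"cg:{g}", (cg == g).to_numpy(float)) for g in cg_levels]
        if has_sex_contrast:
            cols.append(("sex:M", (sex == "M").to_numpy(float)))
        if t in spec.covariate_traits:
            if dam_age.notna().all():
                x = dam_age.to_numpy(float)
                cols.append(("dam_age", x - x.mean()))
            else:
                logger.warning("trait %s: dam_age has missing values; covariate dropped", t)
        names = [c[0] for c in cols]
        X = np.column_stack([c[1] for c in cols])
        X, names = _drop_aliased(X, names, t)
        Xs.append(sparse.csc_matrix(X))
        names_per_trait.append(names)

    return ModelMatrices(
        spec=spec, y=y, obs_mask=obs, X=Xs, x_names=names_per_trait,
        animal_idx=animal_idx, dam_idx=dam_idx, pe_idx=pe_idx, pe_ids=pe_ids,
        ped=ped, record_ids=df["animal"].astype(str).tolist(),
    )


def missing_patterns(obs_mask: np.ndarray) -> list[tuple[tuple[bool, ...], np.ndarray]]:
    """Group record indices by their observed-trait pattern.

    Residual augmentation draws the unobserved traits of each record from
    their conditional normal given the observed ones; grouping by pattern
    lets those draws be vectorised.
    """
    patterns: dict[tuple[bool, ...], list[int]] = {}
    for i, row in enumerate(obs_mask):
        patterns.setdefault(tuple(bool(v) for v in row), []).append(i)
    return [(p, np.asarray(ix, dtype=np.int64)) for p, ix in sorted(patterns.items(), reverse=True)]
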