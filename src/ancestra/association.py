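"""Trait preprocessing and covariate-adjusted covA association models.

The central model regresses a (preprocessed) trait on one ancestry's
standardized covA plus covariates:

    t_i = b0 + b_covA(p) * covA(i, p) + b_c . c_i + e_i

fit by OLS for continuous traits, logistic regression for binary traits and
proportional-odds (ordinal logistic) regression for ordinal traits; for the
latter two the reported effect is an odds ratio. A within-sibship variant
decomposes covA into the sibship mean and the individual deviation from it;
the deviation coefficient is robust to confounders that are constant within
sibships (shared environment correlated with ancestry structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

import networkx as nx

__all__ = [
    "TraitVector",
    "AssociationResult",
    "SibshipAssignment",
    "preprocess_trait",
    "fit_cova_model",
    "bh_fdr",
    "build_sibships",
    "fit_sibling_model",
]

TRAIT_TYPES = ("continuous", "categorical", "ordinal")

# KING kinship bounds for full siblings
FULL_SIB_KINSHIP = (0.177, 0.354)


@dataclass
class TraitVector:
    """Preprocessed trait values with their provenance.

    ``values`` is indexed by sample id; individuals removed as outliers are
    absent. Continuous traits are standardized (mean 0, SD 1); categorical
    traits are coded {0, 1}; ordinal traits are integer category codes in the
    stated order.
    """

    values: pd.Series
    trait_type: str
    name: str = "trait"
    log: list[str] = field(default_factory=list)
    n_removed: int = 0


@dataclass
class AssociationResult:
    trait: str
    ancestry: str
    estimate: float  # slope for continuous traits, OR otherwise
    se: float
    pvalue: float
    model: str  # "linear" | "logistic" | "ordinal" | "linear-sibling" | ...
    n: int
    qvalue: float | None = None

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "ancestry": self.ancestry,
            "estimate": self.estimate,
            "se": self.se,
            "pvalue": self.pvalue,
            "qvalue": self.qvalue,
            "model": self.model,
            "n": self.n,
        }


@dataclass
class SibshipAssignment:
    """Mapping individual -> sibship id for retained full sibships."""

    membership: pd.Series  # index: individual id, value: sibship id

    @property
    def sizes(self) -> pd.Series:
        return self.membership.value_counts()

    @property
    def n_sibships(self) -> int:
        return self.membership.nunique()


def preprocess_trait(
    raw: pd.Series,
    trait_type: str = "continuous",
    log: bool = False,
    adjust_on: pd.Series | None = None,
) -> TraitVector:
    """Preprocess a raw trait for association testing.

    Continuous traits go through: optional log transform, optional
    residualization on an adjustment covariate (e.g. BMI), removal of values
    more than 4 IQRs outside the quartiles, then standardization. Categorical
    traits must already be {0, 1}; ordinal traits must be integer codes.
    """
    if trait_type not in TRAIT_TYPES:
        raise ValueError(f"unknown trait type {trait_type!r}")
    raw = pd.Series(raw).dropna()
    steps: list[str] = []
    if trait_type != "continuous":
        if log or adjust_on is not None:
            raise ValueError("transforms apply to continuous traits only")
        vals = raw.astype(int)
        if trait_type == "categorical" and not set(vals.unique()) <= {0, 1}:
            raise ValueError("categorical traits must be coded {0, 1}")
        return TraitVector(values=vals, trait_type=trait_type, name=raw.name or "trait")

    x = raw.astype(float)
    if log:
        if (x <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
        steps.append("log")
    if adjust_on is not None:
        cov = pd.Series(adjust_on).reindex(x.index)
        ok = cov.notna()
        x = x[ok]
        design = sm.add_constant(cov[ok].astype(float))
        x = pd.Series(sm.OLS(x, design).fit().resid, index=x.index)
        steps.append("adjusted")
    q1, q3 = x.quantile(0.25), x.quantile(0.75)
    iqr = q3 - q1
    keep = (x >= q1 - 4 * iqr) & (x <= q3 + 4 * iqr)
    n_removed = int((~keep).sum())
    x = x[keep]
    steps.append("4iqr-filter")
    sd = x.std(ddof=0)
    if sd == 0 or len(x) < 2:
        raise ValueError("trait has zero variance after filtering")
    x = (x - x.mean()) / sd
    steps.append("standardize")
    return TraitVector(
        values=x,
        trait_type="continuous",
        name=raw.name or "trait",
        log=steps,
        n_removed=n_removed,
    )


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via pivoted QR: smallest |R| diagonals
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(arr.shape[1]) if i >= rank or diag[i] <= tol]
        raise ValueError(f"perfect collinearity among regressors: {sorted(set(map(str, bad)))}")


def _fit(
    y: np.ndarray,
    X: pd.DataFrame,
    trait_type: str,
    coef_name: str,
    trait_name: str,
    ancestry: str,
    model_suffix: str = "",
) -> AssociationResult:
    _check_collinearity(X)
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    if trait_type == "continuous":
        res = sm.OLS(y, X).fit()
        est, se, p = res.params[coef_name], res.bse[coef_name], res.pvalues[coef_name]
        model = "linear"
    elif trait_type == "categorical":
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
        est = float(np.exp(res.params[coef_name]))
        se, p = res.bse[coef_name], res.pvalues[coef_name]
        model = "logistic"
    else:  # ordinal
        exog = X.drop(columns=[c for c in X.columns if c == "const"])
        res = OrderedModel(y, exog, distr="logit").fit(method="bfgs", disp=0, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"ordinal fit did not converge: {res.mle_retvals}")
        est = float(np.exp(res.params[coef_name]))
        se, p = res.bse[coef_name], res.pvalues[coef_name]
        model = "ordinal"
    return AssociationResult(
        trait=trait_name,
        ancestry=ancestry,
        estimate=float(est),
        se=float(se),
        pvalue=float(p),
        model=model + model_suffix,
        n=n,
    )


def fit_cova_model(
    trait: TraitVector,
    cova: pd.Series,
    covariates: pd.DataFrame | None = None,
    ancestry: str = "",
) -> AssociationResult:
    """Fit the covA association model for one trait and one ancestry.

    ``cova`` is the (standardized) covA column for ancestry ``p``, indexed by
    sample id; ``covariates`` optionally adds named covariate columns
    (including the genome-wide covA pair when ``cova`` is TAGR-scoped).
    Individuals are aligned on the shared index.
    """
    cova = pd.Series(cova)
    idx = trait.values.index.intersection(cova.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    y = trait.values.loc[idx].to_numpy()
    X = pd.DataFrame({"covA": cova.loc[idx].astype(float)})
    if covariates is not None:
        cdf = covariates.loc[idx].astype(float)
        bad = [c for c in cdf.columns if cdf[c].nunique() <= 1]
        if bad:
            raise ValueError(f"constant covariate columns: {bad}")
        X = pd.concat([X, cdf], axis=1)
    X = sm.add_constant(X)
    return _fit(y, X, trait.trait_type, "covA", trait.name, ancestry)


def bh_fdr(pvalues, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up FDR control.

    Returns a DataFrame aligned to the input order with monotone adjusted
    p-values (``qvalue``) and a ``significant`` flag at level ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"pvalue": [], "qvalue": [], "significant": []})
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    qvals = np.empty(m)
    qvals[order] = adj
    # step-up: largest k with p_(k) <= k/m * q; all smaller ranks significant
    passing = np.nonzero(p[order] <= np.arange(1, m + 1) / m * q)[0]
    sig = np.zeros(m, dtype=bool)
    if passing.size:
        sig[order[: passing[-1] + 1]] = True
    return pd.DataFrame({"pvalue": p, "qvalue": qvals, "significant": sig})


def build_sibships(
    kinship: pd.DataFrame,
    kinship_bounds: tuple[float, float] = FULL_SIB_KINSHIP,
) -> SibshipAssignment:
    """Construct full sibships from a pairwise kinship table.

    ``kinship`` needs columns ``id1, id2, kinship, full_sib``. Pairs are
    retained when the kinship coefficient lies in ``kinship_bounds`` and the
    full-sibling flag is set; sibships are connected components of retained
    pairs, and any component whose members are not all pairwise full siblings
    is removed entirely.
    """
    if (kinship["id1"] == kinship["id2"]).any():
        raise ValueError("self-pairs are not allowed in the kinship table")
    lo, hi = kinship_bounds
    ok = (
        (kinship["kinship"] >= lo)
        & (kinship["kinship"] <= hi)
        & kinship["full_sib"].astype(bool)
    )
    g = nx.Graph()
    g.add_edges_from(zip(kinship.loc[ok, "id1"], kinship.loc[ok, "id2"]))
    membership: dict = {}
    sid = 0
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(map(str, c))):
        k = len(comp)
        n_edges = g.subgraph(comp).number_of_edges()
        if n_edges < k * (k - 1) // 2:
            continue  # not all pairwise full siblings: drop the whole sibship
        for ind in comp:
            membership[ind] = sid
        sid += 1
    return SibshipAssignment(membership=pd.Series(membership, dtype=int))


def fit_sibling_model(
    trait: TraitVector,
    cova: pd.Series,
    sibships: SibshipAssignment,
    covariates: pd.DataFrame | None = None,
    ancestry: str = "",
) -> AssociationResult:
    """Within-sibship covA model.

    covA is decomposed into the sibship mean (``covA_sib``) and the
    individual's deviation from it (``covA'``), which sum back to the total
    exactly; both enter the regression and the reported estimate is the
    coefficient on the deviation, which is immune to confounders shared
    within a sibship.
    """
    member = sibships.membership
    sizes = member.value_counts()
    keep_sib = sizes[sizes >= 2].index
    member = member[member.isin(keep_sib)]
    if member.empty:
        raise ValueError("no sibship with at least two members")
    cova = pd.Series(cova)
    idx = trait.values.index.intersection(member.index).intersection(cova.index)
    if covariates is not None:
        idx = idx.intersection(covariates.index)
    member = member.loc[idx]
    c = cova.loc[idx].astype(float)
    c_sib = c.groupby(member).transform("mean")
    c_dev = c - c_sib
    if np.allclose(c_dev, 0):
        raise ValueError("perfect collinearity: within-sibship covA deviation is identically zero")
    y = trait.values.loc[idx].to_numpy()
    X = pd.DataFrame({"covA_dev": c_dev, "covA_sib": c_sib})
    if covariates is not None:
        X = pd.concat([X, covariates.loc[idx].astype(float)], axis=1)
    X = sm.add_constant(X)
    res = _fit(y, X, trait.trait_type, "covA_dev", trait.name, ancestry, model_suffix="-sibling")
    return res
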