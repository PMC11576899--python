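"""Reference-set expansion in principal-component + date space.

Ancient candidate samples are projected onto PCs computed from modern
genotypes; a manually curated core set per ancestral group then grows by an
ellipse rule in the 4-dimensional space (date, PC1, PC2, PC3): a candidate
is included when

    sum_d ((x_d - mu_d) / (1.5 sigma_d))^2 <= 1

with mu and sigma the per-dimension core-set mean and SD — i.e. ellipses
whose diameters span 3 core-set SDs (semi-axes of 1.5 SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["CurationSpace", "pca_project", "expand_core_set"]


@dataclass
class CurationSpace:
    """Core-set statistics in curation space (date + leading PCs)."""

    core: pd.DataFrame  # samples x dimensions
    ellipse_sd: float = 1.5  # semi-axis in core SD units (diameter 3 SD)

    def __post_init__(self) -> None:
        if len(self.core) < 2:
            raise ValueError("core set needs at least 2 samples per dimension")
        self.mean = self.core.mean(axis=0)
        self.sd = self.core.std(axis=0, ddof=1)
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"zero core-set SD in dimension(s) {bad}")

    def distance2(self, candidates: pd.DataFrame) -> pd.Series:
        z = (candidates[self.mean.index] - self.mean) / (self.ellipse_sd * self.sd)
        return (z**2).sum(axis=1)

    def includes(self, candidates: pd.DataFrame) -> pd.Series:
        return self.distance2(candidates) <= 1.0


def pca_project(
    moderns: GenotypeMatrix, ancients: GenotypeMatrix, k: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of modern dosages with least-squares projection of ancients.

    Modern dosages are centered at 2f and scaled by sqrt(2f(1-f)); the
    ancient samples (which may be heavily missing) are projected onto the
    modern loadings using only their non-missing loci, solving a per-sample
    least-squares problem so partial coverage renormalizes rather than
    shrinks the projection. Returns (modern scores, ancient projections).
    """
    if not moderns.variants[["chrom", "pos"]].equals(ancients.variants[["chrom", "pos"]]):
        raise ValueError("moderns and ancients must share a variant index")
    X = moderns.dosage_float()
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    f = X.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * f * (1.0 - f))
    ok = scale > 0
    X = (X[:, ok] - 2.0 * f[ok]) / scale[ok]
    if k > min(X.shape) - 1:
        raise ValueError(f"k={k} exceeds available components")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T  # (L, k), orthonormal columns
    cols = [f"PC{i + 1}" for i in range(k)]
    modern_scores = pd.DataFrame(scores, index=moderns.sample_ids, columns=cols)

    A = ancients.dosage_float()[:, ok]
    A = (A - 2.0 * f[ok]) / scale[ok]
    proj = np.empty((ancients.n_samples, k))
    for i in range(ancients.n_samples):
        obs = ~np.isnan(A[i])
        if obs.sum() < k:
            raise ValueError(
                f"ancient sample {ancients.sample_ids[i]!r} has too few "
                f"observed loci ({int(obs.sum())}) to project onto {k} PCs"
            )
        v = loadings[obs]
        proj[i], *_ = np.linalg.lstsq(v, A[i, obs], rcond=None)
    ancient_scores = pd.DataFrame(proj, index=ancients.sample_ids, columns=cols)
    return modern_scores, ancient_scores


def expand_core_set(
    core: pd.DataFrame,
    candidates: pd.DataFrame,
    ellipse_sd: float = 1.5,
) -> pd.DataFrame:
    """Expand a curated core set by the multi-dimensional ellipse rule.

    ``core`` and ``candidates`` share columns (typically ``date, PC1, PC2,
    PC3``). Returns the candidates with their squared ellipse distance and
    an ``included`` flag.
    """
    space = CurationSpace(core=core[core.columns], ellipse_sd=ellipse_sd)
    out = candidates.copy()
    out["distance2"] = space.distance2(candidates)
    out["included"] = space.includes(candidates)
    return out
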