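"""The covA statistic and its supporting operations.

covA(i, p) measures the relative genetic similarity of contemporary
individual *i* to ancestral population *p*: it is the average, over a locus
set S, of the product of the individual's centered allele dosage and the
ancestry's centered reference allele frequency,

    covA(i, p) = (1/|S|) * sum_{l in S} (x_il - fbar_l) (f_pl - gbar_l)

with x_il = dosage/2, fbar_l the contemporary cohort mean of x at locus l,
f_pl the reference frequency of ancestry p, and gbar_l the unweighted mean
of f_pl across ancestries.  Centering by gbar makes the statistic sum to
zero across ancestries for every individual, so with three ancestries there
are only two degrees of freedom.

The locus set S is either the whole variant index (genome-wide covA) or the
variants inside trait-associated genomic regions (TAGR covA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenomicIntervalSet, GenotypeMatrix

__all__ = [
    "ReferenceFrequencies",
    "CovAVector",
    "panel_frequencies",
    "compute_cova",
    "define_tagrs",
    "ascertain_causal",
    "restrict_variants",
]


@dataclass
class ReferenceFrequencies:
    """Per-ancestry effect-allele frequencies aligned to a variant index.

    ``freq`` has shape (n_ancestries, n_variants) with NaN at masked loci;
    ``n_calls`` counts non-missing diploid calls behind each frequency.
    """

    freq: np.ndarray
    n_calls: np.ndarray
    ancestries: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_calls = np.asarray(self.n_calls, dtype=np.int64)
        if self.freq.shape != (len(self.ancestries), len(self.variants)):
            raise ValueError("freq shape does not match ancestries x variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < 0 or np.nanmax(self.freq, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        """Loci where every ancestry has a defined frequency."""
        return ~np.isnan(self.freq).any(axis=0)


@dataclass
class CovAVector:
    """Per-individual, per-ancestry covA values with provenance."""

    values: np.ndarray  # (n_samples, n_ancestries)
    ancestries: list[str]
    sample_ids: np.ndarray
    scope: str  # "genome-wide" or "TAGR:<label>"
    n_loci: int
    standardized: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.ancestries)
        df.insert(0, "sample_id", self.sample_ids)
        df["scope"] = self.scope
        df["n_loci"] = self.n_loci
        return df

    def column(self, ancestry: str) -> np.ndarray:
        return self.values[:, self.ancestries.index(ancestry)]


def panel_frequencies(
    panel: GenotypeMatrix, min_calls: int = 10
) -> ReferenceFrequencies:
    """Effect-allele frequencies per ancestry from a labeled reference panel.

    Loci where any ancestry has fewer than ``min_calls`` non-missing diploid
    calls are masked for all ancestries.
    """
    if "group" not in panel.samples.columns:
        raise ValueError("panel samples must carry a 'group' ancestry label")
    groups = panel.samples["group"]
    if groups.isna().any():
        raise ValueError("every panel sample must be labeled with one ancestry")
    ancestries = list(pd.unique(groups))
    x = panel.dosage_float()
    freq = np.empty((len(ancestries), panel.n_variants))
    n_calls = np.empty((len(ancestries), panel.n_variants), dtype=np.int64)
    for a, anc in enumerate(ancestries):
        sub = x[(groups == anc).to_numpy()]
        if sub.shape[0] == 0:
            raise ValueError(f"ancestry group {anc!r} is empty")
        n = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[a] = np.nansum(sub, axis=0) / (2 * n)
        freq[a, n == 0] = np.nan
        n_calls[a] = n
    low = (n_calls < min_calls).any(axis=0)
    freq[:, low] = np.nan
    return ReferenceFrequencies(
        freq=freq, n_calls=n_calls, ancestries=ancestries, variants=panel.variants
    )


def compute_cova(
    cohort: GenotypeMatrix,
    freqs: ReferenceFrequencies,
    regions: GenomicIntervalSet | None = None,
    standardize: bool = False,
) -> CovAVector:
    """Compute covA for every cohort individual against every ancestry.

    Missing cohort dosages are skipped per individual with renormalization by
    that individual's non-missing locus count. ``standardize`` rescales each
    ancestry's column to mean 0 / SD 1 across individuals (the form entering
    the regressions).
    """
    if cohort.n_variants != len(freqs.variants):
        raise ValueError("cohort and reference frequencies must share a variant index")
    keep = freqs.defined_mask
    scope = "genome-wide"
    if regions is not None:
        if len(regions) == 0:
            raise ValueError("empty region set")
        inside = regions.contains(
            cohort.variants["chrom"].to_numpy(),
            cohort.variants["pos"].to_numpy() - 1,
        )
        keep &= inside
        scope = f"TAGR:{regions.label}" if regions.label else "TAGR"
    if not keep.any():
        raise ValueError("no usable loci: empty intersection of regions and defined frequencies")

    x = cohort.dosage_float()[:, keep] / 2.0  # (n, L)
    f = freqs.freq[:, keep]  # (P, L)
    fbar = np.nanmean(x, axis=0)
    gbar = f.mean(axis=0)
    a = x - fbar
    b = f - gbar  # (P, L); columns sum to zero across ancestries
    obs = ~np.isnan(a)
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("some individuals have no observed genotypes in the locus set")
    a0 = np.where(obs, a, 0.0)
    values = (a0 @ b.T) / n_obs[:, None]
    if standardize:
        sd = values.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a constant covA column")
        values = (values - values.mean(axis=0)) / sd
    return CovAVector(
        values=values,
        ancestries=list(freqs.ancestries),
        sample_ids=cohort.sample_ids,
        scope=scope,
        n_loci=int(keep.sum()),
        standardized=standardize,
    )


def define_tagrs(
    hits: Sequence[tuple[str, int]] | pd.DataFrame,
    window_bp: int = 20_000,
    label: str | None = None,
) -> GenomicIntervalSet:
    """Build trait-associated genomic regions from hit positions.

    Each 1-based hit position becomes a ``window_bp`` window centered on it
    (0-based half-open, clipped at 0); overlapping or adjacent windows are
    merged. An empty hit list yields an empty set.
    """
    if window_bp % 2 != 0:
        raise ValueError("window_bp must be even")
    if isinstance(hits, pd.DataFrame):
        rows = list(zip(hits["chrom"], hits["pos"]))
    else:
        rows = list(hits)
    if not rows:
        return GenomicIntervalSet(label=label)
    half = window_bp // 2
    recs = []
    for chrom, pos in rows:
        center = int(pos) - 1
        recs.append((chrom, max(0, center - half), center + half))
    return GenomicIntervalSet(
        intervals=pd.DataFrame(recs, columns=["chrom", "start", "end"]), label=label
    )


def ascertain_causal(
    beta: np.ndarray,
    freq: np.ndarray,
    trait_var: float,
    tau: float,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> pd.DataFrame:
    """GWAS-like ascertainment of causal SNPs by explained trait variance.

    A causal SNP is retained iff ``2 f (1-f) beta^2 / Var(trait) >= tau``,
    mimicking the discovery bias of GWAS toward variants explaining a large
    fraction of heritability. Returns a DataFrame with the retained loci and
    their ``varexp``; ``chrom``/``pos`` are echoed when given so the result
    can feed straight into :func:`define_tagrs`.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if trait_var <= 0:
        raise ValueError("trait variance must be positive")
    beta = np.asarray(beta, dtype=float)
    freq = np.asarray(freq, dtype=float)
    if beta.shape != freq.shape:
        raise ValueError("beta and freq must be aligned")
    varexp = 2.0 * freq * (1.0 - freq) * beta**2 / trait_var
    kept = varexp >= tau if tau > 0 else (varexp >= tau) & (beta != 0)
    out = {"locus": np.nonzero(kept)[0], "varexp": varexp[kept]}
    if chrom is not None:
        out["chrom"] = np.asarray(chrom)[kept]
    if pos is not None:
        out["pos"] = np.asarray(pos)[kept]
    return pd.DataFrame(out)


def restrict_variants(
    matrix: GenotypeMatrix, regions: GenomicIntervalSet
) -> np.ndarray:
    """Indices of variants whose 0-based position falls in any interval."""
    mask = regions.contains(
        matrix.variants["chrom"].to_numpy(), matrix.variants["pos"].to_numpy() - 1
    )
    return np.nonzero(mask)[0]
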