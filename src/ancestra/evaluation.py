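"""Simulation-evaluation layer: ranking, differentiation, TPR, thresholds.

For each simulated replicate the three reference populations are ranked by
mean genetic value (p = 1, 2, 3 from highest to lowest); the per-ancestry
covA slopes are obtained by regressing the simulated trait on each
standardized covA with no covariates; and the replicate is summarized by
the GV differentiation Delta-GV = (highest - second highest mean GV) /
present-day trait SD. True-positive rates measure how often the ancestry
with the maximal |slope| is the truly top-GV one, per Delta-GV bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cova import compute_cova, define_tagrs, panel_frequencies
from .demography import ANCESTRIES
from .simulate import (
    SimOutput,
    SimScenario,
    ascertain_from_sim,
    filter_relatives,
    local_ancestry_gv,
    run_scenario,
)

__all__ = [
    "ScenarioEvaluation",
    "rank_ancestries_by_gv",
    "gv_differentiation",
    "top_ancestry_tpr",
    "percentile_threshold",
    "cross_cohort_concordance",
    "evaluate_output",
    "run_grid",
]

DEFAULT_BINS = (0.0, 0.1, 0.25, 0.5, 1.0, np.inf)


@dataclass
class ScenarioEvaluation:
    """Per-replicate evaluation record."""

    scenario_id: str
    seed: int
    betas: dict  # ancestry -> covA slope
    panel_gv_means: dict  # ancestry -> mean reference GV
    local_gv: dict  # ancestry -> local-ancestry GV (NaN if undefined)
    trait_sd: float
    delta_gv: float  # reference differentiation, trait-SD units
    delta_gv_local: float
    ranking: tuple  # ancestries ordered p = 1, 2, 3 by reference GV
    tied: bool = False
    n_tagr: int = 0

    def to_dict(self) -> dict:
        d = {"scenario_id": self.scenario_id, "seed": self.seed,
             "trait_sd": self.trait_sd, "delta_gv": self.delta_gv,
             "delta_gv_local": self.delta_gv_local, "n_tagr": self.n_tagr,
             "tied": self.tied}
        for a in self.betas:
            d[f"beta_{a}"] = self.betas[a]
            d[f"panel_gv_{a}"] = self.panel_gv_means[a]
            d[f"local_gv_{a}"] = self.local_gv[a]
        for i, a in enumerate(self.ranking, start=1):
            d[f"rank{i}"] = a
        return d


def rank_ancestries_by_gv(gv_means: dict[str, float]) -> tuple[tuple, bool]:
    """Order ancestries by descending mean GV; ties broken by label order.

    Returns (ordering, tied) where ``tied`` flags exactly equal means.
    """
    if len(gv_means) != 3:
        raise ValueError("expected three ancestry means")
    labels = [a for a in ANCESTRIES if a in gv_means] + [
        a for a in gv_means if a not in ANCESTRIES
    ]
    order = tuple(sorted(labels, key=lambda a: (-gv_means[a], labels.index(a))))
    vals = [gv_means[a] for a in labels]
    tied = len(set(vals)) < len(vals)
    return order, tied


def gv_differentiation(gv_means: dict[str, float], trait_sd: float) -> float:
    """(highest - second highest mean GV) / present-day trait SD."""
    if trait_sd <= 0:
        raise ValueError("trait SD must be positive")
    vals = sorted(gv_means.values(), reverse=True)
    return (vals[0] - vals[1]) / trait_sd


def percentile_threshold(betas, q: float = 0.975) -> float:
    """Empirical quantile of covA slopes (linear interpolation between
    order statistics, numpy's default convention)."""
    betas = np.asarray(betas, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if betas.size < 20:
        raise ValueError("need at least 20 values for a stable quantile")
    return float(np.quantile(betas, q))


def top_ancestry_tpr(
    evals: list[ScenarioEvaluation],
    bins=DEFAULT_BINS,
    target: str = "reference",
) -> pd.DataFrame:
    """True-positive rate of top-ancestry identification per Delta-GV bin.

    A replicate is a true positive when the ancestry with the maximal
    absolute covA slope is the one with the highest mean GV — of the
    reference panels (``target="reference"``) or of the present-day local
    ancestries (``target="local-ancestry"``). Empty bins report NaN.
    """
    if target not in ("reference", "local-ancestry"):
        raise ValueError(f"unknown target {target!r}")
    rows = []
    for ev in evals:
        pred = max(ev.betas, key=lambda a: abs(ev.betas[a]))
        if target == "reference":
            truth = ev.ranking[0]
            dgv = ev.delta_gv
        else:
            finite = {a: v for a, v in ev.local_gv.items() if np.isfinite(v)}
            truth = max(finite, key=finite.get)
            dgv = ev.delta_gv_local
        rows.append((dgv, pred == truth))
    df = pd.DataFrame(rows, columns=["delta_gv", "hit"])
    edges = np.asarray(bins, dtype=float)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (df["delta_gv"] >= lo) & (df["delta_gv"] < hi)
        n = int(sel.sum())
        tpr = float(df.loc[sel, "hit"].mean()) if n else np.nan
        out.append({"bin_lo": lo, "bin_hi": hi, "n": n, "tpr": tpr})
    return pd.DataFrame(out)


def cross_cohort_concordance(
    a: pd.DataFrame, b: pd.DataFrame
) -> pd.Series:
    """Per-ancestry Pearson correlation of association test statistics.

    Inputs are AssociationResult tables (columns ``trait, ancestry,
    estimate, se`` or a ``z`` column); statistics are matched on
    (trait, ancestry) and pairs with missing values dropped listwise.
    """
    def zscores(df: pd.DataFrame) -> pd.Series:
        df = df.copy()
        if "z" not in df.columns:
            df["z"] = df["estimate"] / df["se"]
        return df.set_index(["trait", "ancestry"])["z"]

    za, zb = zscores(a), zscores(b)
    joined = pd.concat([za.rename("a"), zb.rename("b")], axis=1, join="inner").dropna()
    out = {}
    for anc, sub in joined.groupby(level="ancestry"):
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 shared traits for ancestry {anc!r}")
        out[anc] = float(np.corrcoef(sub["a"], sub["b"])[0, 1])
    if not out:
        raise ValueError("no shared (trait, ancestry) pairs")
    return pd.Series(out, name="pearson_r")


def evaluate_output(
    output: SimOutput,
    tau: float | None = None,
    min_calls: int = 10,
    filter_related: bool = False,
    scenario_id: str = "",
) -> ScenarioEvaluation:
    """Evaluate one simulation replicate with the full covA protocol.

    Ascertains causal SNPs (threshold ``tau``; default: half the mean
    per-causal-locus explained variance), builds TAGRs spanning the
    ascertained intervals, computes standardized covA of the (relative-
    filtered) cohort against the reference panels, and regresses the raw
    simulated trait on each ancestry's covA with no covariates.
    """
    scen = output.scenario
    if tau is None:
        # half the mean per-causal-locus fraction of explained variance
        tau = 0.5 * scen.h2 / scen.n_causal_effective
    hits = ascertain_from_sim(output, tau)
    if len(hits) == 0:
        # degenerate ascertainment: fall back to all causal loci
        causal = np.nonzero(output.causal)[0]
        hits = pd.DataFrame(
            {"chrom": output.focal_chrom[causal], "pos": output.focal_pos[causal]}
        )
    tagrs = define_tagrs(hits[["chrom", "pos"]], window_bp=scen.interval_len)
    freqs = panel_frequencies(output.panels, min_calls=min_calls)
    cohort = output.cohort
    trait = output.trait
    if filter_related:
        keep = filter_relatives(output)
        cohort = cohort.take_samples(keep)
        trait = trait[keep]
    cova = compute_cova(cohort, freqs, regions=tagrs, standardize=True)
    betas = {}
    for anc in cova.ancestries:
        X = sm.add_constant(cova.column(anc))
        betas[anc] = float(sm.OLS(trait, X).fit().params[1])
    gv_means = output.panel_gv_means()
    ranking, tied = rank_ancestries_by_gv(gv_means)
    sd = float(np.std(output.trait))
    local = {}
    for anc in ANCESTRIES:
        try:
            local[anc], _ = local_ancestry_gv(output, anc)
        except ValueError:
            local[anc] = np.nan
    finite = sorted((v for v in local.values() if np.isfinite(v)), reverse=True)
    delta_local = (finite[0] - finite[1]) / sd if len(finite) >= 2 else np.nan
    return ScenarioEvaluation(
        scenario_id=scenario_id,
        seed=output.seed,
        betas=betas,
        panel_gv_means=gv_means,
        local_gv=local,
        trait_sd=sd,
        delta_gv=gv_differentiation(gv_means, sd),
        delta_gv_local=delta_local,
        ranking=ranking,
        tied=tied,
        n_tagr=len(tagrs),
    )


def _derive_seed(master: int, scenario_idx: int, rep: int) -> int:
    """Stable per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([master, scenario_idx, rep])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def run_grid(
    scenarios: list[SimScenario],
    reps: int,
    master_seed: int = 0,
    tau: float | None = None,
    scenario_ids: list[str] | None = None,
) -> list[ScenarioEvaluation]:
    """Run a scenario grid: simulate, ascertain, covA, regress, evaluate."""
    if scenario_ids is None:
        scenario_ids = [f"s{idx:03d}" for idx in range(len(scenarios))]
    evals = []
    for idx, scen in enumerate(scenarios):
        for rep in range(reps):
            seed = _derive_seed(master_seed, idx, rep)
            out = run_scenario(replace(scen, seed=seed))
            evals.append(
                evaluate_output(out, tau=tau, scenario_id=scenario_ids[idx])
            )
    return evals


def evaluations_to_frame(evals: list[ScenarioEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in evals])
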