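"""Hybrid forward simulator of admixture under stabilizing selection.

Three ancestral populations (WHG-, EEF- and SBA-like) diverge under
stabilizing selection on an additive polygenic trait and admix into a
present-day cohort. Founder diversity for each unlinked genomic interval is
generated by a neutral coalescent at mutation-drift equilibrium (msprime);
from the deepest split onwards a forward Wright-Fisher phase takes over,
with fitness-proportional parent sampling, per-interval independent
assortment, within-interval recombination, local-ancestry tracking at the
focal (potentially causal) SNP of every interval, and pedigree recording
for the final generations.

Each interval carries one focal SNP; a configurable number of them are
causal with effects beta_l ~ N(0, 1), rescaled once at the deepest split so
the founder genetic-value variance equals h2 — the initial trait variance
is then 1 and trait optima and the fitness-function SD omega are expressed
directly in initial-trait-SD units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .cova import ascertain_causal
from .demography import ANCESTRIES, DemographyModel

__all__ = [
    "SimScenario",
    "SimOutput",
    "run_scenario",
    "compute_gv",
    "phenotype_from_gv",
    "fitness_weights",
    "filter_relatives",
    "local_ancestry_gv",
    "ascertain_from_sim",
]

_LABEL_CODE = {a: i for i, a in enumerate(ANCESTRIES)}
_NO_LABEL = 255


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation scenario."""

    n_loci: int = 1000
    interval_len: int = 20_000
    mu: float = 1.25e-8
    r: float = 1e-8
    h2: float = 0.5
    n_causal: int | None = None  # default: all loci causal
    omega: float | None = 3.0  # None or inf = neutral
    optima: dict = field(default_factory=dict)  # per-ancestry trait optimum
    shift_ancestry: str | None = None
    shift: float = 0.0
    selection_mode: str = "pre_admixture"  # pre_admixture | post_admixture | none
    demography: DemographyModel = field(default_factory=DemographyModel)
    n_cohort: int = 10_000
    n_panel: int = 100
    pedigree_generations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        nc = self.n_causal if self.n_causal is not None else self.n_loci
        if nc > self.n_loci or nc < 1:
            raise ValueError("n_causal must be in [1, n_loci]")
        if self.omega is not None and not math.isinf(self.omega) and self.omega <= 0:
            raise ValueError("omega must be positive (or None/inf for neutral)")
        if self.selection_mode not in ("pre_admixture", "post_admixture", "none"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if self.n_cohort <= 0 or self.n_panel <= 0:
            raise ValueError("population and panel sizes must be positive")
        for a in self.optima:
            if a not in ANCESTRIES:
                raise ValueError(f"unknown ancestry {a!r} in optima")
        if self.shift_ancestry is not None and self.shift_ancestry not in ANCESTRIES:
            raise ValueError(f"unknown shift ancestry {self.shift_ancestry!r}")

    @property
    def neutral(self) -> bool:
        return (
            self.selection_mode == "none"
            or self.omega is None
            or math.isinf(self.omega)
        )

    @property
    def n_causal_effective(self) -> int:
        return self.n_causal if self.n_causal is not None else self.n_loci

    def optimum_of(self, ancestry: str) -> float:
        opt = float(self.optima.get(ancestry, 0.0))
        if ancestry == self.shift_ancestry:
            opt += self.shift
        return opt

    def scaled(self, factor: int) -> "SimScenario":
        """Population-genetic rescaling by ``factor``.

        Ne, event times and the cohort size shrink by ``factor``; mutation
        and recombination rates grow by it; omega^2 shrinks by it so
        selection relative to drift is preserved per scaled generation.
        Panel sizes are kept (they are sample sizes, not Ne).
        """
        omega = self.omega
        if omega is not None and not math.isinf(omega):
            omega = omega / math.sqrt(factor)
        return replace(
            self,
            mu=self.mu * factor,
            r=self.r * factor,
            omega=omega,
            demography=self.demography.scaled(factor),
            n_cohort=max(20, self.n_cohort // factor),
        )

    @classmethod
    def reduced(cls, **kw) -> "SimScenario":
        """Reduced-scale profile: 100 x 5 kb intervals, Ne and times / 10."""
        kw.setdefault("n_loci", 100)
        kw.setdefault("interval_len", 5000)
        return cls(**kw).scaled(10)

    @classmethod
    def test_scale(cls, **kw) -> "SimScenario":
        """Desk-scale profile for test grids: Ne and times / 20."""
        kw.setdefault("n_loci", 100)
        kw.setdefault("interval_len", 5000)
        return cls(**kw).scaled(20)


@dataclass
class SimOutput:
    """Everything one simulation run produces."""

    cohort: GenotypeMatrix
    panels: GenotypeMatrix
    gv: np.ndarray  # cohort genetic values
    trait: np.ndarray  # cohort trait values
    beta: np.ndarray  # per-interval effect size (0 at non-causal loci)
    causal: np.ndarray  # bool per interval
    focal_chrom: np.ndarray  # per interval
    focal_pos: np.ndarray  # 1-based, per interval (-1 if no focal SNP)
    focal_col: np.ndarray  # column of the focal SNP in the variant index (-1 if absent)
    cohort_focal_haps: np.ndarray  # (2 n_cohort, n_loci) alleles at focal SNPs
    cohort_labels: np.ndarray  # (2 n_cohort, n_loci) local-ancestry codes
    parents: np.ndarray  # (n_cohort, 2) parent indices in previous generation
    grandparents: np.ndarray  # (n_prev, 2) parent indices one generation further back
    ancestries: tuple = ANCESTRIES
    scenario: SimScenario | None = None
    seed: int = 0

    def cohort_causal_dosage(self) -> np.ndarray:
        cols = self.focal_col[self.causal]
        return self.cohort.dosage[:, cols].astype(float)

    def panel_gv(self) -> dict[str, np.ndarray]:
        """Genetic values of the reference-panel individuals, per ancestry."""
        cols = self.focal_col[self.causal]
        d = self.panels.dosage[:, cols].astype(float)
        gvs = d @ self.beta[self.causal]
        groups = self.panels.samples["group"]
        return {a: gvs[(groups == a).to_numpy()] for a in self.ancestries}

    def panel_gv_means(self) -> dict[str, float]:
        return {a: float(v.mean()) for a, v in self.panel_gv().items()}

    def ancestry_fraction(self, ancestry: str) -> float:
        """Fraction of present-day allele copies carrying this local ancestry."""
        return float(np.mean(self.cohort_labels == _LABEL_CODE[ancestry]))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def compute_gv(dosage: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Additive genetic value: GV_i = sum_l beta_l * dosage_il."""
    dosage = np.asarray(dosage, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if dosage.ndim != 2 or dosage.shape[1] != effects.shape[0]:
        raise ValueError("dosage columns must align with effects")
    if not np.isin(dosage, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    return dosage @ effects


def phenotype_from_gv(
    gv: np.ndarray, h2: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add environmental noise so the trait has heritability h2."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    gv = np.asarray(gv, dtype=float)
    if h2 == 1.0:
        return gv.copy()
    var_gv = gv.var()
    if var_gv == 0:
        raise ValueError("environmental variance undefined: Var(GV) = 0 with h2 < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ve = var_gv * (1.0 - h2) / h2
    return gv + rng.normal(0.0, math.sqrt(ve), size=gv.shape)


def fitness_weights(
    trait: np.ndarray, optimum: float, omega: float | None
) -> np.ndarray:
    """Gaussian stabilizing-selection fitness w = exp(-(t-opt)^2 / (2 omega^2))."""
    trait = np.asarray(trait, dtype=float)
    if omega is None or math.isinf(omega):
        return np.ones_like(trait)
    if omega <= 0:
        raise ValueError("omega must be positive")
    return np.exp(-((trait - optimum) ** 2) / (2.0 * omega**2))


def filter_relatives(output: SimOutput) -> np.ndarray:
    """Greedy index of cohort individuals with no shared parent or grandparent.

    Individuals are scanned in sample order; one is retained iff none of its
    parents or grandparents is already an ancestor of a retained individual.
    Deterministic given the cohort ordering.
    """
    if output.parents.size == 0:
        raise ValueError("pedigree not available")
    parents = output.parents
    grandparents = output.grandparents
    used_parents: set[int] = set()
    used_grandparents: set[int] = set()
    keep = []
    for i in range(parents.shape[0]):
        ps = {int(p) for p in parents[i] if p >= 0}
        gs = {
            int(g)
            for p in ps
            for g in grandparents[p]
            if g >= 0
        }
        if ps & used_parents or gs & used_grandparents:
            continue
        keep.append(i)
        used_parents |= ps
        used_grandparents |= gs
    return np.asarray(keep, dtype=np.int64)


def local_ancestry_gv(
    output: SimOutput, ancestry: str
) -> tuple[float, np.ndarray]:
    """Expected GV of an individual with all causal loci of one local ancestry.

    GV_p = 2 * sum_l beta_l * f_pl where f_pl is the effect-allele frequency
    among present-day allele copies labeled with ancestry p at causal locus
    l. Causal loci where the ancestry has zero copies are skipped; their
    interval indices are returned alongside the value.
    """
    if ancestry not in output.ancestries:
        raise ValueError(f"unknown ancestry {ancestry!r}")
    code = _LABEL_CODE[ancestry]
    causal_idx = np.nonzero(output.causal)[0]
    alleles = output.cohort_focal_haps[:, causal_idx]
    labels = output.cohort_labels[:, causal_idx]
    mask = labels == code
    counts = mask.sum(axis=0)
    if (counts == 0).all():
        raise ValueError(f"ancestry {ancestry!r} absent at every causal locus")
    ok = counts > 0
    with np.errstate(invalid="ignore"):
        f_local = (alleles * mask).sum(axis=0)[ok] / counts[ok]
    value = 2.0 * float(np.sum(output.beta[causal_idx[ok]] * f_local))
    skipped = causal_idx[~ok]
    return value, skipped


def ascertain_from_sim(output: SimOutput, tau: float) -> pd.DataFrame:
    """GWAS-like ascertainment of a simulation's causal SNPs (see cova)."""
    causal_idx = np.nonzero(output.causal)[0]
    cols = output.focal_col[causal_idx]
    freq = output.cohort.dosage[:, cols].astype(float).mean(axis=0) / 2.0
    return ascertain_causal(
        beta=output.beta[causal_idx],
        freq=freq,
        trait_var=float(np.var(output.trait)),
        tau=tau,
        chrom=output.focal_chrom[causal_idx],
        pos=output.focal_pos[causal_idx],
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher machinery
# ---------------------------------------------------------------------------


class _Genome:
    """Static site bookkeeping shared by all populations of one run."""

    def __init__(self, scenario: SimScenario, site_interval, site_pos, rng):
        self.L = scenario.interval_len
        self.r = scenario.r
        self.n_loci = scenario.n_loci
        self.site_interval = site_interval  # (S,) interval index per site
        self.site_pos = site_pos  # (S,) 0-based position within interval
        self.n_sites = len(site_interval)
        # contiguous slice per interval (sites sorted by interval, then pos)
        self.slices = []
        bounds = np.searchsorted(site_interval, np.arange(self.n_loci + 1))
        for k in range(self.n_loci):
            self.slices.append(slice(bounds[k], bounds[k + 1]))
        self.rl = self.r * self.L  # expected crossovers per interval per meiosis
        self.focal_site = np.full(self.n_loci, -1, dtype=np.int64)
        self.label_pos = np.full(self.n_loci, self.L // 2, dtype=np.int64)

    def choose_focal(self, founder_haps: np.ndarray, rng: np.random.Generator):
        """Pick each interval's focal SNP: common (MAF >= 0.01) and central."""
        freq = founder_haps.mean(axis=0)
        for k in range(self.n_loci):
            sl = self.slices[k]
            if sl.stop == sl.start:
                continue
            f = freq[sl.start : sl.stop]
            pos = self.site_pos[sl.start : sl.stop]
            common = (f >= 0.01) & (f <= 0.99)
            if common.any():
                cand = np.nonzero(common)[0]
            else:
                cand = np.array([int(np.argmin(np.abs(f - 0.5)))])
            best = cand[np.argmin(np.abs(pos[cand] - self.L / 2))]
            self.focal_site[k] = sl.start + best
            self.label_pos[k] = pos[best]


class _Population:
    __slots__ = ("haps", "labels", "name")

    def __init__(self, haps: np.ndarray, labels: np.ndarray, name: str):
        self.haps = haps  # (2N, S) uint8
        self.labels = labels  # (2N, n_loci) uint8, ancestry at the focal SNP
        self.name = name

    @property
    def n(self) -> int:
        return self.haps.shape[0] // 2


def _gametes(
    pop_haps: np.ndarray,
    pop_labels: np.ndarray,
    parent: np.ndarray,
    genome: _Genome,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per parent: independent assortment across intervals,
    Poisson crossovers within intervals, labels follow the focal SNP."""
    nc = parent.shape[0]
    start = rng.integers(0, 2, size=(nc, genome.n_loci), dtype=np.int8)
    choice = start[:, genome.site_interval]  # (nc, S) which parental haplotype
    focal_choice = start
    if genome.rl > 0:
        nx = rng.poisson(genome.rl, size=(nc, genome.n_loci))
        cc, kk = np.nonzero(nx)
        if cc.size:
            focal_choice = start.copy()
            for c, k in zip(cc, kk):
                bps = np.sort(rng.uniform(0, genome.L, size=nx[c, k]))
                sl = genome.slices[k]
                pos = genome.site_pos[sl.start : sl.stop]
                flips = np.searchsorted(bps, pos)
                choice[c, sl.start : sl.stop] = (start[c, k] + flips) % 2
                lf = int(np.searchsorted(bps, genome.label_pos[k]))
                focal_choice[c, k] = (start[c, k] + lf) % 2
    hap_a = pop_haps[2 * parent]
    hap_b = pop_haps[2 * parent + 1]
    haps = np.where(choice != 0, hap_b, hap_a)
    lab_a = pop_labels[2 * parent]
    lab_b = pop_labels[2 * parent + 1]
    labels = np.where(focal_choice != 0, lab_b, lab_a)
    return haps, labels


def _parental_weights(
    pop: _Population,
    scenario: SimScenario,
    genome: _Genome,
    beta: np.ndarray,
    causal_cols: np.ndarray,
    ve0: float,
    optimum: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Fitness-proportional sampling probabilities, or None for uniform."""
    dos = (
        pop.haps[0::2][:, causal_cols].astype(np.float64)
        + pop.haps[1::2][:, causal_cols]
    )
    gv = dos @ beta
    var_gv = gv.var()
    if scenario.h2 == 1.0:
        trait = gv
    else:
        ve = var_gv * (1 - scenario.h2) / scenario.h2 if var_gv > 0 else ve0
        trait = gv + rng.normal(0.0, math.sqrt(ve), size=gv.shape)
    w = fitness_weights(trait, optimum, scenario.omega)
    s = w.sum()
    if s <= 0:
        return None
    return w / s


def _choose_parents(
    n_children: int, n_parents: int, probs: np.ndarray | None, rng
) -> tuple[np.ndarray, np.ndarray]:
    mother = rng.choice(n_parents, size=n_children, p=probs)
    father = rng.choice(n_parents, size=n_children, p=probs)
    for _ in range(20):  # forbid selfing
        same = mother == father
        if not same.any():
            break
        father[same] = rng.choice(n_parents, size=int(same.sum()), p=probs)
    return mother, father


def _reproduce(
    pop: _Population,
    n_children: int,
    probs: np.ndarray | None,
    genome: _Genome,
    rng,
    name: str | None = None,
) -> tuple[_Population, np.ndarray]:
    mother, father = _choose_parents(n_children, pop.n, probs, rng)
    child_haps = np.empty((2 * n_children, genome.n_sites), dtype=np.uint8)
    child_labels = np.empty((2 * n_children, genome.n_loci), dtype=np.uint8)
    for which, par in ((0, mother), (1, father)):
        h, l = _gametes(pop.haps, pop.labels, par, genome, rng)
        child_haps[which::2] = h
        child_labels[which::2] = l
    new = _Population(child_haps, child_labels, name or pop.name)
    return new, np.column_stack([mother, father])


def run_scenario(scenario: SimScenario) -> SimOutput:
    """Run one full simulation: coalescent founders, forward WF, admixture.

    Fixed seed implies bit-identical output.
    """
    dem = scenario.demography
    rng = np.random.default_rng(scenario.seed)
    n_whg = dem.ne_branch["WHG"]
    n_efs = dem.ne_ancestral  # unsplit EEF/SBA ancestor keeps ancestral Ne

    # --- coalescent founder phase: one ancestral population at equilibrium
    founder_n = n_whg + n_efs
    reps = msprime.sim_ancestry(
        samples=founder_n,
        population_size=dem.ne_ancestral,
        sequence_length=scenario.interval_len,
        recombination_rate=scenario.r,
        num_replicates=scenario.n_loci,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mut_seed = int(rng.integers(1, 2**31 - 1))
    hap_blocks, site_interval, site_pos = [], [], []
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=scenario.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed + k,
        )
        gm = mts.genotype_matrix()  # (S_k, 2 founder_n)
        keep = (gm.sum(axis=1) > 0) & (gm.sum(axis=1) < gm.shape[1])
        gm = gm[keep]
        pos = mts.sites_position[keep].astype(np.int64)
        hap_blocks.append(gm.T.astype(np.uint8))
        site_interval.append(np.full(gm.shape[0], k, dtype=np.int64))
        site_pos.append(pos)
    founder_haps = np.concatenate(hap_blocks, axis=1)
    genome = _Genome(
        scenario,
        np.concatenate(site_interval),
        np.concatenate(site_pos),
        rng,
    )
    genome.choose_focal(founder_haps, rng)

    # --- effect sizes at causal loci, rescaled so founder Var(GV) = h2
    with_focal = np.nonzero(genome.focal_site >= 0)[0]
    if scenario.n_causal is None:
        # default polygenicity: every interval that segregates is causal
        n_causal = len(with_focal)
    else:
        n_causal = scenario.n_causal
    if len(with_focal) < n_causal or n_causal == 0:
        raise RuntimeError(
            f"only {len(with_focal)} intervals segregate; cannot place "
            f"{n_causal} causal loci"
        )
    causal = np.zeros(scenario.n_loci, dtype=bool)
    causal[rng.choice(with_focal, size=n_causal, replace=False)] = True
    beta_full = np.zeros(scenario.n_loci)
    beta_full[causal] = rng.normal(0.0, 1.0, size=n_causal)
    causal_cols = genome.focal_site[causal]
    beta_c = beta_full[causal]
    founder_dos = (
        founder_haps[0::2][:, causal_cols].astype(np.float64)
        + founder_haps[1::2][:, causal_cols]
    )
    var0 = (founder_dos @ beta_c).var()
    if var0 > 0:
        scale = math.sqrt(scenario.h2 / var0)
        beta_full *= scale
        beta_c = beta_full[causal]
    ve0 = (1 - scenario.h2)  # initial trait variance is 1 by construction

    lab = lambda code, n2: np.full((n2, scenario.n_loci), code, dtype=np.uint8)
    pops: dict[str, _Population] = {
        "WHG": _Population(
            founder_haps[: 2 * n_whg], lab(_LABEL_CODE["WHG"], 2 * n_whg), "WHG"
        ),
        "EFS": _Population(
            founder_haps[2 * n_whg :], lab(_NO_LABEL, 2 * n_efs), "EFS"
        ),
    }

    pulses = sorted(dem.pulses, key=lambda p: -p.time)
    first_pulse_t = pulses[0].time
    # time at which each branch's reference panel is frozen: one generation
    # before the first admixture pulse affecting that branch
    panel_time = {}
    for a in ANCESTRIES:
        affecting = [p.time for p in pulses if p.source == a]
        if a == dem.base_ancestry:
            affecting.append(first_pulse_t)
        panel_time[a] = (max(affecting) if affecting else first_pulse_t) + 1
    last_needed = {
        a: max([p.time for p in pulses if p.source == a], default=first_pulse_t)
        for a in ANCESTRIES
    }
    last_needed[dem.base_ancestry] = min(last_needed[dem.base_ancestry], first_pulse_t)

    def branch_probs(pop: _Population) -> np.ndarray | None:
        if scenario.neutral or scenario.selection_mode != "pre_admixture":
            return None
        optimum = 0.0 if pop.name == "EFS" else scenario.optimum_of(pop.name)
        return _parental_weights(
            pop, scenario, genome, beta_c, causal_cols, ve0, optimum, rng
        )

    panels: dict[str, _Population] = {}
    parent_records: list[np.ndarray] = []

    for t_child in range(dem.t_deep_split - 1, -1, -1):
        # freeze reference panels from the current (parental) generation,
        # which lives t_child + 1 generations before present
        for a in ANCESTRIES:
            if a in pops and t_child + 1 == panel_time[a] and a not in panels:
                take = rng.choice(pops[a].n, size=min(scenario.n_panel, pops[a].n),
                                  replace=False)
                rows = np.stack([2 * take, 2 * take + 1], axis=1).ravel()
                panels[a] = _Population(
                    pops[a].haps[rows].copy(), pops[a].labels[rows].copy(), a
                )

        new_pops: dict[str, _Population] = {}
        if t_child == dem.t_farmer_steppe_split and "EFS" in pops:
            probs = branch_probs(pops["EFS"])
            for a in ("EEF", "SBA"):
                child, _ = _reproduce(
                    pops["EFS"], dem.ne_branch[a], probs, genome, rng, name=a
                )
                child.labels[:] = _LABEL_CODE[a]
                new_pops[a] = child
        for name, pop in pops.items():
            if name in ("PRESENT", "EFS") or name in new_pops:
                continue
            if name in panels and t_child < last_needed.get(name, 0):
                continue  # branch no longer feeds anything downstream
            new_pops[name], _ = _reproduce(pop, pop.n, branch_probs(pop), genome, rng)
        if "EFS" in pops and t_child > dem.t_farmer_steppe_split:
            new_pops["EFS"], _ = _reproduce(
                pops["EFS"], pops["EFS"].n, branch_probs(pops["EFS"]), genome, rng
            )

        pulse_today = next((p for p in pulses if p.time == t_child), None)
        if pulse_today is not None and "PRESENT" not in pops:
            # founding pulse: present-day lineage appears, each gamete drawn
            # from the source with the pulse proportion, else from the base
            base, src, m = dem.base_ancestry, pulse_today.source, pulse_today.proportion
            n = scenario.n_cohort
            from_src = rng.random(2 * n) < m
            child_haps = np.empty((2 * n, genome.n_sites), dtype=np.uint8)
            child_labels = np.empty((2 * n, genome.n_loci), dtype=np.uint8)
            for pool_name, sel in ((base, ~from_src), (src, from_src)):
                if not sel.any():
                    continue
                pool = pops[pool_name]
                par = rng.choice(pool.n, size=int(sel.sum()), p=branch_probs(pool))
                h, l = _gametes(pool.haps, pool.labels, par, genome, rng)
                child_haps[sel] = h
                child_labels[sel] = l
            new_pops["PRESENT"] = _Population(child_haps, child_labels, "PRESENT")
            parent_records.append(np.full((n, 2), -1, dtype=np.int64))
        elif "PRESENT" in pops:
            present = pops["PRESENT"]
            if scenario.neutral or scenario.selection_mode != "post_admixture":
                probs = None
            else:
                probs = _parental_weights(
                    present, scenario, genome, beta_c, causal_cols, ve0, 0.0, rng
                )
            new, parents = _reproduce(present, present.n, probs, genome, rng)
            if pulse_today is not None:
                # later pulse: a fraction of gametes is replaced from the source
                src, m = pulse_today.source, pulse_today.proportion
                from_src = rng.random(2 * present.n) < m
                if from_src.any():
                    pool = pops[src]
                    par = rng.choice(pool.n, size=int(from_src.sum()),
                                     p=branch_probs(pool))
                    h, l = _gametes(pool.haps, pool.labels, par, genome, rng)
                    new.haps[from_src] = h
                    new.labels[from_src] = l
                    parents[from_src[0::2] | from_src[1::2]] = -1
            new_pops["PRESENT"] = new
            parent_records.append(parents)
        pops = new_pops

    present = pops["PRESENT"]
    n = present.n
    dos_causal = (
        present.haps[0::2][:, causal_cols].astype(np.float64)
        + present.haps[1::2][:, causal_cols]
    )
    gv = dos_causal @ beta_c
    var_gv = gv.var()
    if scenario.h2 == 1.0:
        trait = gv.copy()
    else:
        ve = var_gv * (1 - scenario.h2) / scenario.h2 if var_gv > 0 else ve0
        trait = gv + rng.normal(0.0, math.sqrt(ve), size=n)

    # --- assemble output genotype matrices on the shared variant index
    panel_rows = np.concatenate([panels[a].haps for a in ANCESTRIES], axis=0)
    counts = present.haps.sum(axis=0, dtype=np.int64) + panel_rows.sum(
        axis=0, dtype=np.int64
    )
    total = present.haps.shape[0] + panel_rows.shape[0]
    seg = (counts > 0) & (counts < total)
    seg[genome.focal_site[genome.focal_site >= 0]] = True  # keep focal SNPs
    keep_sites = np.nonzero(seg)[0]
    col_of_site = np.full(genome.n_sites, -1, dtype=np.int64)
    col_of_site[keep_sites] = np.arange(len(keep_sites))

    chroms = np.array([f"iv{k:04d}" for k in range(scenario.n_loci)])
    variants = pd.DataFrame(
        {
            "chrom": chroms[genome.site_interval[keep_sites]],
            "pos": genome.site_pos[keep_sites] + 1,
            "ref": "A",
            "alt": "T",
        }
    )

    def dosage_of(haps: np.ndarray) -> np.ndarray:
        return (haps[0::2][:, keep_sites] + haps[1::2][:, keep_sites]).astype(np.int8)

    cohort_samples = pd.DataFrame(
        {"group": "present"}, index=[f"ind{i:05d}" for i in range(n)]
    )
    cohort = GenotypeMatrix(dosage_of(present.haps), variants, cohort_samples)
    panel_ids, panel_groups = [], []
    for a in ANCESTRIES:
        for i in range(panels[a].n):
            panel_ids.append(f"{a}{i:03d}")
            panel_groups.append(a)
    panel_gm = GenotypeMatrix(
        dosage_of(panel_rows),
        variants,
        pd.DataFrame({"group": panel_groups}, index=panel_ids),
    )

    focal_pos = np.where(genome.focal_site >= 0, genome.site_pos[genome.focal_site] + 1, -1)
    focal_col = np.where(genome.focal_site >= 0, col_of_site[genome.focal_site], -1)
    n_ped = scenario.pedigree_generations
    recent = parent_records[-n_ped:] if parent_records else []
    parents_out = recent[-1] if recent else np.empty((0, 2), dtype=np.int64)
    grandparents = (
        recent[-2] if len(recent) >= 2 else np.full((n, 2), -1, dtype=np.int64)
    )
    focal_haps = present.haps[:, np.where(genome.focal_site >= 0,
                                          genome.focal_site, 0)].copy()
    focal_haps[:, genome.focal_site < 0] = 0

    return SimOutput(
        cohort=cohort,
        panels=panel_gm,
        gv=gv,
        trait=trait,
        beta=beta_full,
        causal=causal,
        focal_chrom=chroms,
        focal_pos=focal_pos,
        focal_col=focal_col,
        cohort_focal_haps=focal_haps,
        cohort_labels=present.labels.copy(),
        parents=parents_out,
        grandparents=grandparents,
        scenario=scenario,
        seed=scenario.seed,
    )
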