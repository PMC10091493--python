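"""Two-sex Wright-Fisher forward simulator for fixation probabilities.

Independent verification engine for the diffusion results: explicit
genotype-resolved populations of ``N_f`` females and ``N_m`` males are
iterated one generation at a time until a single new mutant copy is
either fixed or lost.  Selection acts on fecundity: each offspring draws
its mother and its father independently, with probability proportional to
the parent's fitness within its sex.  Inheritance follows the locus
class:

* autosomal      -- one allele from each parent, uniformly;
* hemizygous X / diploid X -- daughters receive the father's X allele and
  one maternal X allele uniformly; sons receive one maternal X allele
  uniformly.  Under the diploid-X class sons additionally carry the fixed
  ancestral Y-linked allele, which never mutates or recombines, so a male
  mutant carrier is permanently heterozygous (fitness ``1 + h*s_m``);
  under the hemizygous class a male carrier is fully exposed
  (fitness ``1 + s_m``).

Because parents are drawn independently per offspring, the genotype
counts of each sex are a sufficient statistic for the population, and the
next generation is a (multinomial, binomial) draw from the selection-
weighted transmission probabilities.  Replicates are vectorized in blocks
of :data:`BLOCK_SIZE`; block ``i`` uses the ``i``-th child of the root
``SeedSequence``, so results are independent of block execution order and
reproducible from the root seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .diffusion import fixation_probability
from .model import (
    LocusClass,
    ParameterError,
    PopulationModel,
    SelectionRegime,
    drift_coefficients,
)

__all__ = [
    "BLOCK_SIZE",
    "SimConfig",
    "SimResult",
    "PopulationState",
    "initial_state",
    "step_generation",
    "weighted_frequency",
    "estimate_fixation",
    "ComparisonResult",
    "compare_to_diffusion",
    "default_comparison_grid",
]

#: Replicates are simulated in vectorized blocks of this size, each block
#: on its own spawned RNG stream (documented counter scheme).
BLOCK_SIZE = 8192


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one forward-simulation experiment."""

    regime: SelectionRegime
    locus_class: LocusClass
    N_f: int = 250
    N_m: int = 250
    replicates: int = 10_000
    max_generations: int | None = None  # default 100 * (N_f + N_m)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_f < 1 or self.N_m < 1:
            raise ParameterError("need at least one individual of each sex")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        object.__setattr__(self, "locus_class", LocusClass.parse(self.locus_class))

    @property
    def N(self) -> int:
        return self.N_f + self.N_m

    @property
    def generation_cap(self) -> int:
        return self.max_generations if self.max_generations is not None else 100 * self.N

    @property
    def p0(self) -> float:
        """Frequency of a single new copy among the class's chromosomes."""
        if self.locus_class is LocusClass.AUTOSOMAL:
            return 1.0 / (2.0 * self.N)
        return 1.0 / (2.0 * self.N_f + self.N_m)


@dataclass(frozen=True)
class SimResult:
    """Fixation/loss tallies and the estimated fixation probability."""

    fixed: int
    lost: int
    unresolved: int
    u_hat: float
    ci95: tuple[float, float]
    mean_sojourn: float
    warning: str | None = None

    @property
    def replicates(self) -> int:
        return self.fixed + self.lost + self.unresolved


@dataclass
class PopulationState:
    """Genotype counts of a batch of replicate populations.

    ``females`` has shape (replicates, 3): numbers of females carrying
    0, 1 or 2 mutant copies.  ``males`` has shape (replicates, 3) for an
    autosomal locus and (replicates,) mutant-carrier counts for either X
    class (males carry a single X-borne allele).
    """

    females: np.ndarray
    males: np.ndarray


def _female_weights(regime: SelectionRegime) -> np.ndarray:
    return np.array([1.0, 1.0 + regime.h * regime.s_f, 1.0 + regime.s_f])


def _male_weights(regime: SelectionRegime, locus_class: LocusClass):
    if locus_class is LocusClass.AUTOSOMAL:
        return np.array([1.0, 1.0 + regime.h * regime.s_m, 1.0 + regime.s_m])
    if locus_class is LocusClass.HEMIZYGOUS_X:
        return 1.0 + regime.s_m
    # diploid X: male carriers are heterozygous with the ancestral Y allele
    return 1.0 + regime.h * regime.s_m


def initial_state(
    cfg: SimConfig, rng: np.random.Generator, n_replicates: int
) -> PopulationState:
    """Place one mutant copy uniformly over the chromosome copies of the class.

    For X-linked classes the single copy lands in a female with
    probability 2/3 and in a male with probability 1/3 (females carry two
    of the 1.5N X copies); autosomal copies land in either sex with equal
    probability.  This matches the initial frequencies 2/(3N) and 1/(2N).
    """
    r = n_replicates
    females = np.zeros((r, 3), dtype=np.int64)
    females[:, 0] = cfg.N_f
    if cfg.locus_class is LocusClass.AUTOSOMAL:
        males = np.zeros((r, 3), dtype=np.int64)
        males[:, 0] = cfg.N_m
        in_female = rng.random(r) < cfg.N_f / cfg.N
        females[in_female, 0] -= 1
        females[in_female, 1] += 1
        males[~in_female, 0] -= 1
        males[~in_female, 1] += 1
    else:
        males = np.zeros(r, dtype=np.int64)
        p_female = 2.0 * cfg.N_f / (2.0 * cfg.N_f + cfg.N_m)
        in_female = rng.random(r) < p_female
        females[in_female, 0] -= 1
        females[in_female, 1] += 1
        males[~in_female] = 1
    return PopulationState(females=females, males=males)


def _maternal_allele_prob(females: np.ndarray, wf: np.ndarray) -> np.ndarray:
    total = females @ wf
    return (0.5 * females[:, 1] * wf[1] + females[:, 2] * wf[2]) / total


def _offspring_probs(pm: np.ndarray, pp: np.ndarray) -> np.ndarray:
    """Per-replicate genotype probabilities (0, 1, 2 copies) of an offspring."""
    p2 = pm * pp
    p1 = pm + pp - 2.0 * p2
    p0 = 1.0 - p1 - p2
    return np.clip(np.stack([p0, p1, p2], axis=-1), 0.0, 1.0)


def step_generation(
    state: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> PopulationState:
    """Produce the next generation by fitness-weighted Wright-Fisher sampling."""
    wf = _female_weights(cfg.regime)
    wm = _male_weights(cfg.regime, cfg.locus_class)
    pm = _maternal_allele_prob(state.females, wf)

    if cfg.locus_class is LocusClass.AUTOSOMAL:
        pp = _maternal_allele_prob(state.males, wm)  # same algebra for fathers
        probs = _offspring_probs(pm, pp)
        daughters = rng.multinomial(cfg.N_f, probs)
        sons = rng.multinomial(cfg.N_m, probs)
        return PopulationState(females=daughters, males=sons)

    carriers = state.males
    weighted = carriers * wm
    pp = weighted / (weighted + (cfg.N_m - carriers))
    daughters = rng.multinomial(cfg.N_f, _offspring_probs(pm, pp))
    sons = rng.binomial(cfg.N_m, pm)
    return PopulationState(females=daughters, males=sons)


def weighted_frequency(state: PopulationState, cfg: SimConfig) -> np.ndarray:
    """Transmission-weighted mutant frequency (a martingale under neutrality).

    X-linked: (2*x_f + x_m)/3 with x_f the frequency among female-borne X
    copies and x_m among male-borne copies; autosomal: (x_f + x_m)/2.
    """
    x_f = (state.females[..., 1] + 2 * state.females[..., 2]) / (2.0 * cfg.N_f)
    if cfg.locus_class is LocusClass.AUTOSOMAL:
        x_m = (state.males[..., 1] + 2 * state.males[..., 2]) / (2.0 * cfg.N_m)
        return 0.5 * (x_f + x_m)
    x_m = state.males / cfg.N_m
    return (2.0 * x_f + x_m) / 3.0


def _copies(state: PopulationState, cfg: SimConfig) -> np.ndarray:
    fem = state.females[:, 1] + 2 * state.females[:, 2]
    if cfg.locus_class is LocusClass.AUTOSOMAL:
        return fem + state.males[:, 1] + 2 * state.males[:, 2]
    return fem + state.males


def _total_copies(cfg: SimConfig) -> int:
    if cfg.locus_class is LocusClass.AUTOSOMAL:
        return 2 * cfg.N
    return 2 * cfg.N_f + cfg.N_m


def _run_block(
    cfg: SimConfig, rng: np.random.Generator, n_replicates: int
) -> tuple[int, int, int, int]:
    """Run one vectorized block; returns (fixed, lost, unresolved, sojourn_sum)."""
    state = initial_state(cfg, rng, n_replicates)
    total = _total_copies(cfg)
    fixed = lost = 0
    sojourn_sum = 0
    cap = cfg.generation_cap
    for gen in range(1, cap + 1):
        state = step_generation(state, cfg, rng)
        copies = _copies(state, cfg)
        is_lost = copies == 0
        is_fixed = copies == total
        absorbed = is_lost | is_fixed
        n_abs = int(absorbed.sum())
        if n_abs:
            fixed += int(is_fixed.sum())
            lost += int(is_lost.sum())
            sojourn_sum += gen * n_abs
            keep = ~absorbed
            state = PopulationState(females=state.females[keep], males=state.males[keep])
        if state.females.shape[0] == 0:
            break
    unresolved = state.females.shape[0]
    return fixed, lost, unresolved, sojourn_sum


def estimate_fixation(cfg: SimConfig) -> SimResult:
    """Estimate the fixation probability of a single new mutant copy.

    Runs ``cfg.replicates`` independent trajectories (vectorized in
    blocks, each block on its own spawned RNG stream derived from
    ``cfg.seed``).  Trajectories still segregating at the generation cap
    are excluded from the ``u_hat`` denominator and reported; if they
    exceed 0.1% of replicates a warning is recorded on the result.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_blocks = math.ceil(cfg.replicates / BLOCK_SIZE)
    children = ss.spawn(n_blocks)
    fixed = lost = unresolved = 0
    sojourn_sum = 0
    remaining = cfg.replicates
    for child in children:
        n = min(BLOCK_SIZE, remaining)
        remaining -= n
        rng = np.random.default_rng(child)
        f, l, u, s = _run_block(cfg, rng, n)
        fixed += f
        lost += l
        unresolved += u
        sojourn_sum += s

    resolved = fixed + lost
    u_hat = fixed / resolved if resolved else float("nan")
    lo, hi = proportion_confint(fixed, resolved, alpha=0.05, method="wilson")
    warning = None
    if unresolved / cfg.replicates >= 0.001:
        warning = (
            f"{unresolved} of {cfg.replicates} replicates unresolved at the "
            f"generation cap ({cfg.generation_cap})"
        )
    mean_sojourn = sojourn_sum / resolved if resolved else float("nan")
    return SimResult(
        fixed=fixed,
        lost=lost,
        unresolved=unresolved,
        u_hat=u_hat,
        ci95=(float(lo), float(hi)),
        mean_sojourn=mean_sojourn,
        warning=warning,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Simulation-vs-diffusion comparison table and its summary verdict."""

    table: pd.DataFrame
    passed: bool
    fraction_within: float
    z_threshold: float = 2.0


def _default_ne_map(cfg: SimConfig) -> PopulationModel:
    """Census -> effective sizes under even-sex-ratio WF reproduction."""
    return PopulationModel(N=cfg.N, Ne_A=float(cfg.N), Ne_X=0.75 * cfg.N)


def compare_to_diffusion(
    cfg_grid: list[SimConfig],
    ne_map=None,
    z_threshold: float = 2.0,
) -> ComparisonResult:
    """Run a grid of simulations and score each against the diffusion.

    For each configuration the z-score is
    ``(u_hat - u_diff) / sqrt(u_diff * (1 - u_diff) / n_resolved)``.
    The grid passes when the fraction of |z| <= ``z_threshold`` leaves at
    most ``ceil(0.05 * n)`` exceedances -- the integer version of a 5%
    two-sided Monte-Carlo outlier budget on a finite grid.
    """
    if ne_map is None:
        ne_map = _default_ne_map
    rows = []
    for cfg in cfg_grid:
        res = estimate_fixation(cfg)
        pop = ne_map(cfg)
        coeffs = drift_coefficients(cfg.regime, cfg.locus_class, pop, p0=cfg.p0)
        u_diff = fixation_probability(cfg.p0, coeffs).u
        n_res = res.fixed + res.lost
        se = math.sqrt(u_diff * (1.0 - u_diff) / n_res) if n_res else float("nan")
        z = (res.u_hat - u_diff) / se if se else float("nan")
        rows.append(
            {
                "locus_class": cfg.locus_class.value,
                "h": cfg.regime.h,
                "s_f": cfg.regime.s_f,
                "s_m": cfg.regime.s_m,
                "N": cfg.N,
                "replicates": cfg.replicates,
                "u_hat": res.u_hat,
                "ci95_lo": res.ci95[0],
                "ci95_hi": res.ci95[1],
                "u_diffusion": u_diff,
                "z": z,
            }
        )
    table = pd.DataFrame(rows)
    within = int((table["z"].abs() <= z_threshold).sum())
    n = len(table)
    allowed_out = math.ceil(0.05 * n)
    passed = (n - within) <= allowed_out
    return ComparisonResult(
        table=table,
        passed=passed,
        fraction_within=within / n if n else float("nan"),
        z_threshold=z_threshold,
    )


def default_comparison_grid(
    N: int = 500,
    replicates: int = 50_000,
    nea_s_values: tuple[float, ...] = (1.0, 3.0),
    h_values: tuple[float, ...] = (0.0, 0.5, 1.0),
    seed: int = 0,
) -> list[SimConfig]:
    """The standard 18-point verification grid (equal-effect beneficials).

    h in {0, 1/2, 1} x Ne_A*s in {1, 3} x all three locus classes, at
    N = 500 individuals; each configuration gets a distinct sub-seed
    derived from ``seed``.
    """
    cfgs = []
    half = N // 2
    root = np.random.SeedSequence(seed)
    sub_seeds = root.generate_state(
        len(h_values) * len(nea_s_values) * 3, dtype=np.uint32
    )
    i = 0
    for h in h_values:
        for nes in nea_s_values:
            s = nes / N
            regime = SelectionRegime(s_f=s, s_m=s, h=h)
            for locus_class in (
                LocusClass.AUTOSOMAL,
                LocusClass.HEMIZYGOUS_X,
                LocusClass.DIPLOID_X,
            ):
                cfgs.append(
                    SimConfig(
                        regime=regime,
                        locus_class=locus_class,
                        N_f=half,
                        N_m=half,
                        replicates=replicates,
                        seed=int(sub_seeds[i]),
                    )
                )
                i += 1
    return cfgs
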