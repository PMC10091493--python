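"""Two-sex Wright-Fisher forward simulator."""

import math

import numpy as np
import pytest

import slowerx as sx
from slowerx.model import LocusClass
from slowerx.simulate import (
    PopulationState,
    SimConfig,
    compare_to_diffusion,
    estimate_fixation,
    initial_state,
    step_generation,
    weighted_frequency,
)

NEUTRAL = sx.SelectionRegime(0.0, 0.0, 0.5)


def make_cfg(locus_class, regime=NEUTRAL, N=100, replicates=1000, seed=7, **kw):
    return SimConfig(
        regime=regime, locus_class=locus_class, N_f=N // 2, N_m=N // 2,
        replicates=replicates, seed=seed, **kw,
    )


def test_same_seed_reproduces_result_exactly():
    cfg = make_cfg("diploid_X", N=60, replicates=3000)
    a = estimate_fixation(cfg)
    b = estimate_fixation(cfg)
    assert (a.fixed, a.lost, a.unresolved, a.mean_sojourn) == (
        b.fixed, b.lost, b.unresolved, b.mean_sojourn,
    )


def test_tallies_and_ci_are_consistent():
    cfg = make_cfg("autosomal", N=60, replicates=2000)
    res = estimate_fixation(cfg)
    assert res.fixed + res.lost + res.unresolved == cfg.replicates
    assert res.ci95[0] <= res.u_hat <= res.ci95[1]


def test_generation_cap_flags_unresolved_runs():
    cfg = make_cfg("autosomal", N=200, replicates=2000, max_generations=2)
    res = estimate_fixation(cfg)
    assert res.unresolved > 0
    assert res.warning is not None


@pytest.mark.parametrize("locus_class", ["autosomal", "hemizygous_X", "diploid_X"])
def test_neutral_one_step_martingale(locus_class, rng):
    """E[transmission-weighted frequency] is preserved by one neutral step."""
    cfg = make_cfg(locus_class, N=40, replicates=1)
    r = 40_000
    females = np.tile([7, 9, 4], (r, 1))  # x_f = 0.425
    if cfg.locus_class is LocusClass.AUTOSOMAL:
        males = np.tile([11, 6, 3], (r, 1))
    else:
        males = np.full(r, 13)
    state = PopulationState(females=females.astype(np.int64), males=males.astype(np.int64))
    p_before = weighted_frequency(state, cfg)[0]
    stepped = step_generation(state, cfg, rng)
    p_after = weighted_frequency(stepped, cfg)
    se = p_after.std(ddof=1) / math.sqrt(r)
    assert abs(p_after.mean() - p_before) < 4 * se


def test_realized_x_to_autosome_ne_ratio_is_three_quarters(rng):
    """Drift variance of the X vs autosome matches Ne_X/Ne_A = 0.75."""
    N = 40
    r = 60_000
    # both sexes at frequency 1/2 in both classes
    cfg_a = make_cfg("autosomal", N=N)
    st_a = PopulationState(
        females=np.tile([0, N // 2, 0], (r, 1)).astype(np.int64),
        males=np.tile([0, N // 2, 0], (r, 1)).astype(np.int64),
    )
    cfg_x = make_cfg("hemizygous_X", N=N)
    st_x = PopulationState(
        females=np.tile([0, N // 2, 0], (r, 1)).astype(np.int64),
        males=np.full(r, N // 4, dtype=np.int64),
    )
    var_a = weighted_frequency(step_generation(st_a, cfg_a, rng), cfg_a).var(ddof=1)
    var_x = weighted_frequency(step_generation(st_x, cfg_x, rng), cfg_x).var(ddof=1)
    # realized Ne proportional to 1/var at matched frequency
    assert var_a / var_x == pytest.approx(0.75, rel=0.05)


@pytest.mark.parametrize(
    "locus_class, p0",
    [("autosomal", 1 / 200), ("hemizygous_X", 1 / 150), ("diploid_X", 1 / 150)],
)
def test_neutral_fixation_probability_equals_initial_frequency(locus_class, p0):
    cfg = make_cfg(locus_class, N=100, replicates=30_000, seed=11)
    res = estimate_fixation(cfg)
    assert cfg.p0 == p0
    assert res.ci95[0] <= p0 <= res.ci95[1]


def test_full_sheltering_makes_male_selection_invisible():
    """Diploid X with s_f = 0, h = 0: male carriers are masked by the Y
    allele, so even strong male selection leaves the trajectory neutral."""
    sheltered = make_cfg(
        "diploid_X", regime=sx.SelectionRegime(0.0, 0.5, 0.0),
        N=100, replicates=30_000, seed=13,
    )
    res = estimate_fixation(sheltered)
    assert res.ci95[0] <= sheltered.p0 <= res.ci95[1]


def test_hemizygous_males_are_exposed_regardless_of_dominance():
    """With s_f = 0 and h = 0 a hemizygous X mutation is still selected in
    males, unlike its diploid-X counterpart."""
    exposed = make_cfg(
        "hemizygous_X", regime=sx.SelectionRegime(0.0, 0.5, 0.0),
        N=100, replicates=30_000, seed=13,
    )
    res = estimate_fixation(exposed)
    assert res.ci95[0] > exposed.p0  # clearly above the neutral value


def test_selected_autosomal_case_matches_diffusion():
    s = 0.01
    cfg = make_cfg(
        "autosomal", regime=sx.SelectionRegime(s, s, 0.5),
        N=200, replicates=40_000, seed=17,
    )
    res = estimate_fixation(cfg)
    pop = sx.PopulationModel(N=cfg.N, Ne_A=float(cfg.N))
    coeffs = sx.drift_coefficients(cfg.regime, cfg.locus_class, pop, p0=cfg.p0)
    u = sx.fixation_probability(cfg.p0, coeffs).u
    assert res.ci95[0] <= u <= res.ci95[1]


def test_comparison_harness_detects_mismatched_oracle():
    """Feeding the diffusion a tenfold-too-small Ne must raise the fail flag."""
    s = 0.02
    cfgs = [
        make_cfg(lc, regime=sx.SelectionRegime(s, s, 0.5), N=200,
                 replicates=5000, seed=19)
        for lc in ("autosomal", "diploid_X")
    ]
    good = compare_to_diffusion(cfgs)
    assert good.passed
    bad = compare_to_diffusion(
        cfgs,
        ne_map=lambda cfg: sx.PopulationModel(
            N=cfg.N, Ne_A=cfg.N / 10.0, Ne_X=0.075 * cfg.N
        ),
    )
    assert not bad.passed
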