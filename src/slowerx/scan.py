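"""Parameter-grid scans of substitution rates and X/A rate ratios.

The central comparison is the ratio R of the substitution rate at an
X-linked locus (diploid or hemizygous) to the autosomal rate at identical
selection parameters.  All scans work on the population-scaled axes
``h`` and ``Ne_A * s`` (the scale on which the diffusion results depend)
and report the mutation-relative rate of each class alongside R.

Grids are plain :class:`pandas.DataFrame` tables wrapped with their
parameter metadata; they serialize to tab-separated files with a
``#``-commented ``key = value`` provenance header, so an emitted file can
be re-read and the run reproduced from its own header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diffusion import relative_substitution_rate
from .model import LocusClass, ParameterError, PopulationModel, SelectionRegime

__all__ = [
    "RateGrid",
    "DEFAULT_H_GRID",
    "DEFAULT_NES_GRID",
    "DEFAULT_POP",
    "SEX_EFFECT_PRESETS",
    "scan_dominance",
    "scan_sex_effects",
    "equal_Ne_scenario",
    "normalized_rates",
    "deleterious_strength_curve",
]

#: Default dominance grid, h = 0, 0.05, ..., 1.
DEFAULT_H_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))

#: Default population-scaled selection strengths covering the modelled
#: range of Ne_A*s from -3 to 5.
DEFAULT_NES_GRID: tuple[float, ...] = (-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 3.0, 5.0)

#: Default population: N = 1e6 individuals so the exact rate U(p0)/p0 and
#: its first-order-in-p0 limit agree to ~1e-6.
DEFAULT_POP = PopulationModel(N=1_000_000)

_ALL_CLASSES = (LocusClass.AUTOSOMAL, LocusClass.HEMIZYGOUS_X, LocusClass.DIPLOID_X)

_COLUMNS = [
    "locus_class",
    "h",
    "NeA_sf",
    "NeA_sm",
    "relative_rate",
    "R_vs_autosome",
    "ne_ratio_used",
]


@dataclass
class RateGrid:
    """A table of relative substitution rates with its parameter metadata."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        """Write a TSV file with a '#'-commented ``key = value`` header."""
        buf = io.StringIO()
        buf.write(f"# tool = slowerx {__version__}\n")
        for key, value in self.meta.items():
            buf.write(f"# {key} = {value}\n")
        self.table.to_csv(buf, sep="\t", index=False, float_format="%.12g")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "RateGrid":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                body_start = i + 1
            else:
                break
        table = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
        return cls(table=table, meta=meta)


def _sorted(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(
        ["locus_class", "h", "NeA_sf", "NeA_sm"], kind="mergesort"
    ).reset_index(drop=True)


def _grid_rows(
    nea_sf: float,
    nea_sm: float,
    h_grid: Sequence[float],
    pop: PopulationModel,
    classes: Sequence[LocusClass],
    first_order: bool,
) -> list[dict]:
    """Rates and X/A ratios for one (s_f, s_m) pair over a dominance grid."""
    s_f = nea_sf / pop.Ne_A
    s_m = nea_sm / pop.Ne_A
    ne_ratio = pop.Ne_X / pop.Ne_A
    rows = []
    for h in h_grid:
        regime = SelectionRegime(s_f=s_f, s_m=s_m, h=float(h))
        rate_a = relative_substitution_rate(
            regime, LocusClass.AUTOSOMAL, pop, first_order=first_order
        )
        for locus_class in classes:
            if locus_class is LocusClass.AUTOSOMAL:
                rate = rate_a
            else:
                rate = relative_substitution_rate(
                    regime, locus_class, pop, first_order=first_order
                )
            rows.append(
                {
                    "locus_class": locus_class.value,
                    "h": float(h),
                    "NeA_sf": nea_sf,
                    "NeA_sm": nea_sm,
                    "relative_rate": rate,
                    "R_vs_autosome": rate / rate_a,
                    "ne_ratio_used": ne_ratio,
                }
            )
    return rows


def _base_meta(pop: PopulationModel, h_grid, first_order: bool) -> dict:
    return {
        "N": pop.N,
        "Ne_A": pop.Ne_A,
        "Ne_X": pop.Ne_X,
        "ne_ratio": pop.Ne_X / pop.Ne_A,
        "h_grid": ",".join(f"{h:.12g}" for h in h_grid),
        "rate_form": "first_order" if first_order else "exact",
        "p0_convention": "1/(2N) autosomal; 2/(3N) X-linked",
    }


def scan_dominance(
    nea_sf: float,
    nea_sm: float,
    h_grid: Sequence[float] = DEFAULT_H_GRID,
    pop: PopulationModel = DEFAULT_POP,
    classes: Sequence[LocusClass | str] = _ALL_CLASSES,
    first_order: bool = False,
) -> RateGrid:
    """Rates and X/A ratios over a dominance grid at fixed Ne_A*s_f, Ne_A*s_m.

    One row per (h, locus class); deterministic given its inputs.
    """
    h_grid = list(h_grid)
    classes = [LocusClass.parse(c) for c in classes]
    if not h_grid or not classes:
        raise ParameterError("h_grid and classes must be non-empty")
    rows = _grid_rows(float(nea_sf), float(nea_sm), h_grid, pop, classes, first_order)
    meta = _base_meta(pop, h_grid, first_order)
    meta.update({"scan": "dominance", "NeA_sf": nea_sf, "NeA_sm": nea_sm})
    return RateGrid(table=_sorted(pd.DataFrame(rows, columns=_COLUMNS)), meta=meta)


def _sign_ok(preset: str, nea_sm: float, nea_sf: float) -> bool:
    checks = {
        "male_limited": nea_sm != 0 and nea_sf == 0,
        "female_limited": nea_sf != 0 and nea_sm == 0,
        "equal": nea_sf == nea_sm and nea_sf != 0,
        "male_biased": nea_sm * nea_sf > 0 and abs(nea_sm) > abs(nea_sf),
        "female_biased": nea_sm * nea_sf > 0 and abs(nea_sf) > abs(nea_sm),
        "antagonistic_male_benefit": nea_sm > 0 > nea_sf,
        "antagonistic_female_benefit": nea_sf > 0 > nea_sm,
    }
    if preset not in checks:
        raise ParameterError(
            f"unknown preset {preset!r}; expected one of {sorted(checks)}"
        )
    return checks[preset]


#: Names of the supported sex-effect presets.
SEX_EFFECT_PRESETS = (
    "male_limited",
    "female_limited",
    "equal",
    "male_biased",
    "female_biased",
    "antagonistic_male_benefit",
    "antagonistic_female_benefit",
)


def scan_sex_effects(
    preset: str,
    magnitudes: tuple[float, float],
    h_grid: Sequence[float] = DEFAULT_H_GRID,
    pop: PopulationModel = DEFAULT_POP,
    classes: Sequence[LocusClass | str] = _ALL_CLASSES,
    first_order: bool = False,
) -> RateGrid:
    """Dominance scan for a named sex-effect regime.

    ``magnitudes`` is the pair ``(Ne_A*s_m, Ne_A*s_f)``; its signs must be
    consistent with the named preset (e.g. ``male_limited`` requires
    ``s_f = 0``, ``antagonistic_male_benefit`` requires ``s_m > 0 > s_f``).
    """
    nea_sm, nea_sf = float(magnitudes[0]), float(magnitudes[1])
    if not _sign_ok(preset, nea_sm, nea_sf):
        raise ParameterError(
            f"magnitudes (NeA_sm={nea_sm}, NeA_sf={nea_sf}) inconsistent "
            f"with preset {preset!r}"
        )
    grid = scan_dominance(nea_sf, nea_sm, h_grid, pop, classes, first_order)
    grid.meta.update({"scan": "sex_effects", "preset": preset})
    grid.table.insert(0, "preset", preset)
    return grid


def equal_Ne_scenario(
    nea_sf: float,
    nea_sm: float,
    h_grid: Sequence[float] = DEFAULT_H_GRID,
    pop: PopulationModel = DEFAULT_POP,
    classes: Sequence[LocusClass | str] = _ALL_CLASSES,
    first_order: bool = False,
) -> RateGrid:
    """Dominance scan with Ne_X forced equal to Ne_A.

    Removing the X's copy-number disadvantage isolates the contributions
    of sheltering and female-biased transmission.  The metadata records
    the dominance value at which R(diploid X) crosses 1, interpolated
    linearly on the grid (``None`` if R does not cross 1).
    """
    pop_eq = PopulationModel(N=pop.N, Ne_A=pop.Ne_A, Ne_X=pop.Ne_A, mu=pop.mu)
    grid = scan_dominance(nea_sf, nea_sm, h_grid, pop_eq, classes, first_order)
    grid.meta.update({"scan": "equal_Ne"})
    dip = grid.table[grid.table["locus_class"] == LocusClass.DIPLOID_X.value]
    grid.meta["crossover_h"] = _crossover_h(
        dip["h"].to_numpy(), dip["R_vs_autosome"].to_numpy()
    )
    return grid


def _crossover_h(h: np.ndarray, r: np.ndarray) -> float | None:
    """Linearly interpolated h at which r crosses 1, or None."""
    excess = r - 1.0
    for i in range(len(h) - 1):
        if excess[i] == 0.0:
            return float(h[i])
        if excess[i] * excess[i + 1] < 0.0:
            frac = excess[i] / (excess[i] - excess[i + 1])
            return float(h[i] + frac * (h[i + 1] - h[i]))
    if len(excess) and excess[-1] == 0.0:
        return float(h[-1])
    return None


def normalized_rates(grid: RateGrid) -> RateGrid:
    """Add a column of rates normalized by the neutral substitution rate.

    On the mutation-relative scale the neutral rate is identically 1, so
    the normalized value equals ``relative_rate``; the column is kept for
    parity with dN/dS-style empirical measures, and the X/A ratios are
    unchanged by the normalization.
    """
    table = grid.table.copy()
    table["normalized_rate"] = table["relative_rate"] / 1.0
    meta = dict(grid.meta)
    meta["normalization"] = "neutral substitution rate (= 1 on the mu-relative scale)"
    return RateGrid(table=table, meta=meta)


def deleterious_strength_curve(
    h: float,
    strengths: Iterable[float],
    pop: PopulationModel = DEFAULT_POP,
    first_order: bool = False,
) -> RateGrid:
    """R(diploid X) as a function of the strength of a deleterious mutation.

    ``strengths`` are population-scaled values Ne_A*s <= 0 applied equally
    to both sexes.  R grows steeply (empirically, exponentially) with
    |Ne_A*s|: strongly deleterious mutations fix far more often on a
    young X than on an autosome.
    """
    strengths = [float(s) for s in strengths]
    if any(s > 0 for s in strengths):
        raise ParameterError("deleterious strengths must all be <= 0")
    rows = []
    for nes in strengths:
        rows.extend(
            _grid_rows(nes, nes, [float(h)], pop, [LocusClass.DIPLOID_X], first_order)
        )
    meta = _base_meta(pop, [h], first_order)
    meta.update({"scan": "deleterious_strength", "h": h})
    return RateGrid(table=_sorted(pd.DataFrame(rows, columns=_COLUMNS)), meta=meta)
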