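"""Fitness schemes and drift coefficients for autosomal and X-linked loci.

A young X chromosome that has stopped recombining with its Y partner, but
whose Y-linked gametologs are still functional, carries "diploid X" loci:
males are permanently heterozygous X/Y there, so a new X-linked mutation is
always sheltered by the ancestral Y allele in males.  Once the Y copy is
lost the locus becomes "hemizygous X" and males express their single X
allele directly.  The three locus classes modelled here are therefore

* ``AUTOSOMAL``     -- ordinary diploid inheritance in both sexes,
* ``HEMIZYGOUS_X``  -- X-linked with a degenerated Y (classical faster-X
  setting; a male carrier has fitness ``1 + s_m`` regardless of dominance),
* ``DIPLOID_X``     -- X-linked with a functional, non-recombining Y
  homolog (a male carrier is always heterozygous, fitness ``1 + h*s_m``).

Under weak selection the expected per-generation change of the mutant
frequency at any of these loci takes the form ``x(1-x)(a + b*x)``.  The
diffusion that governs fixation then depends on the locus only through the
two compound coefficients

    s_bar = a + b/2      (selection averaged over sexes and genotypes)
    sigma = b/2          (dominance deviation; zero when h = 1/2)

together with the effective population size of the relevant chromosome and
the initial frequency of a single new copy.  :func:`drift_coefficients`
performs this reduction for each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ParameterError",
    "LocusClass",
    "SelectionRegime",
    "PopulationModel",
    "DriftCoefficients",
    "drift_coefficients",
]


class ParameterError(ValueError):
    """A model parameter lies outside its admissible domain."""


class LocusClass(str, Enum):
    """Inheritance class of the locus under consideration."""

    AUTOSOMAL = "autosomal"
    HEMIZYGOUS_X = "hemizygous_X"
    DIPLOID_X = "diploid_X"

    @classmethod
    def parse(cls, value: "LocusClass | str") -> "LocusClass":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        for member in cls:
            if member.value.lower() == key or member.name.lower() == key:
                return member
        raise ParameterError(
            f"unknown locus class {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class SelectionRegime:
    """Sex-specific selection coefficients and a shared dominance coefficient.

    The homozygous mutant has fitness ``1 + s_f`` in females and
    ``1 + s_m`` in males; heterozygotes have fitness ``1 + h*s`` in the
    respective sex.  ``s_f`` and ``s_m`` may independently be negative,
    zero or positive, so sexually antagonistic regimes (opposite signs)
    are allowed.  Dominance is assumed equal in the two sexes.
    """

    s_f: float
    s_m: float
    h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ParameterError(f"dominance coefficient h={self.h} not in [0, 1]")
        if self.s_f <= -1.0 or self.s_m <= -1.0:
            raise ParameterError(
                f"selection coefficients must exceed -1 to keep fitness positive "
                f"(got s_f={self.s_f}, s_m={self.s_m})"
            )

    @property
    def is_neutral(self) -> bool:
        return self.s_f == 0.0 and self.s_m == 0.0


@dataclass(frozen=True)
class PopulationModel:
    """Census and effective population sizes, plus the mutation rate.

    With an even sex ratio a population of ``N`` diploid individuals
    carries ``2N`` autosome copies but only ``1.5N`` X copies, so by
    default the X effective size is three quarters of the autosomal one.
    ``Ne_X`` can be overridden (e.g. ``Ne_X = Ne_A``, roughly the
    Drosophila melanogaster situation) to separate the effect of the
    reduced copy number from that of sheltering and female-biased
    transmission.
    """

    N: int
    Ne_A: float | None = None
    Ne_X: float | None = None
    mu: float = 1e-8

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"census size N={self.N} must be >= 2")
        if self.Ne_A is None:
            object.__setattr__(self, "Ne_A", float(self.N))
        if self.Ne_X is None:
            object.__setattr__(self, "Ne_X", 0.75 * self.Ne_A)
        if self.Ne_A <= 0 or self.Ne_X <= 0:
            raise ParameterError(
                f"effective sizes must be positive (Ne_A={self.Ne_A}, Ne_X={self.Ne_X})"
            )
        if self.mu < 0:
            raise ParameterError(f"mutation rate mu={self.mu} must be >= 0")

    def ne_for(self, locus_class: LocusClass) -> float:
        return self.Ne_A if locus_class is LocusClass.AUTOSOMAL else self.Ne_X

    def copies_for(self, locus_class: LocusClass) -> float:
        """Number of chromosome copies of the class in the census population."""
        return 2.0 * self.N if locus_class is LocusClass.AUTOSOMAL else 1.5 * self.N


@dataclass(frozen=True)
class DriftCoefficients:
    """The (s_bar, sigma) pair driving the diffusion for one locus class.

    ``p0`` is the frequency of a single new mutant copy: ``1/(2N)`` on an
    autosome, ``2/(3N)`` on either X class (one copy among ``1.5N`` X
    chromosomes).
    """

    s_bar: float
    sigma: float
    Ne: float
    p0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ParameterError(f"initial frequency p0={self.p0} not in (0, 1)")
        if self.Ne <= 0:
            raise ParameterError(f"effective size Ne={self.Ne} must be positive")


def drift_coefficients(
    regime: SelectionRegime,
    locus_class: LocusClass | str,
    pop: PopulationModel,
    p0: float | None = None,
) -> DriftCoefficients:
    """Reduce a selection regime at one locus class to diffusion coefficients.

    Writing the selection term of the expected frequency change as
    ``x(1-x)(a + b*x)``, returns ``s_bar = a + b/2`` and ``sigma = b/2``:

    * diploid X:    ``s_bar = (s_f + h*s_m)/3``, ``sigma = s_f*(1-2h)/3``
    * hemizygous X: ``s_bar = (s_f + s_m)/3``,   ``sigma = s_f*(1-2h)/3``
    * autosomal:    ``s_bar = (s_f + s_m)/4``,   ``sigma = (s_f+s_m)*(1-2h)/4``

    The hemizygous form is the diploid-X form with ``s_m`` replaced by
    ``s_m/h``, evaluated in closed form so that ``h = 0`` is legal.

    Parameters
    ----------
    regime, locus_class, pop
        Model inputs; ``locus_class`` may be given as a string.
    p0
        Optional override of the single-copy initial frequency (useful for
        testing); defaults to the class convention described above.
    """
    locus_class = LocusClass.parse(locus_class)
    s_f, s_m, h = regime.s_f, regime.s_m, regime.h

    if locus_class is LocusClass.DIPLOID_X:
        s_bar = (s_f + h * s_m) / 3.0
        sigma = s_f * (1.0 - 2.0 * h) / 3.0
        default_p0 = 2.0 / (3.0 * pop.N)
    elif locus_class is LocusClass.HEMIZYGOUS_X:
        s_bar = (s_f + s_m) / 3.0
        sigma = s_f * (1.0 - 2.0 * h) / 3.0
        default_p0 = 2.0 / (3.0 * pop.N)
    else:  # AUTOSOMAL
        s_bar = (s_f + s_m) / 4.0
        sigma = (s_f + s_m) * (1.0 - 2.0 * h) / 4.0
        default_p0 = 1.0 / (2.0 * pop.N)

    return DriftCoefficients(
        s_bar=s_bar,
        sigma=sigma,
        Ne=pop.ne_for(locus_class),
        p0=default_p0 if p0 is None else p0,
    )
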