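"""Branching-process (Haldane) fixation probabilities for strong selection.

When ``1/Ne << h*s << 1`` the fate of a new beneficial mutation is decided
while it is rare, and its fixation probability is approximately twice the
selective advantage of a heterozygous carrier, averaged over the sexes in
which the mutant copy can find itself.  An autosomal copy spends half its
time in each sex; an X-linked copy spends two thirds of its time in
females and one third in males.  This yields

* autosomal:    ``P_A  = h*(s_f + s_m)``
* diploid X:    ``P_X  = (2/3)*h*(2*s_f + s_m)``   (male carriers are
  heterozygous with the ancestral Y allele, so the male term carries h)
* hemizygous X: ``P_hX = (2/3)*(2*h*s_f + s_m)``   (male carriers are
  fully exposed; equivalently the diploid-X form with s_m -> s_m/h)

Multiplying by the mutant input per generation (``2N`` autosomal copies,
``1.5N`` X copies, equal mutation rates) gives substitution rates whose
diploid-X : autosomal ratio is independent of dominance:

    R = (2*s_f + s_m) / (2*s_f + 2*s_m)

so R = 1 for female-limited, 1/2 for male-limited and 3/4 for
equal-effect beneficial mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import LocusClass, ParameterError, PopulationModel, SelectionRegime

__all__ = ["BranchingResult", "branching_fixation", "R_branching"]

#: Upper bound on the heterozygous advantage for the "strongly beneficial
#: but still weak" regime in which the branching approximation is trusted.
STRONG_SELECTION_CEILING = 0.1


@dataclass(frozen=True)
class BranchingResult:
    """Approximate fixation probability and mutation-relative substitution rate.

    ``valid`` records whether ``1/Ne << (heterozygous advantage) << 0.1``
    held; it is a flag rather than an exception so that grid scans can
    sweep through boundary regions.
    """

    p_fix: float
    K_rel: float
    valid: bool


def branching_fixation(
    regime: SelectionRegime,
    locus_class: LocusClass | str,
    pop: PopulationModel,
) -> BranchingResult:
    """Haldane branching-process fixation probability for one locus class.

    ``K_rel`` is the substitution rate with the mutation rate factored
    out: copy number (2N autosomal, 1.5N X) times ``p_fix``.  Regimes
    that are not supercritical (the sex-averaged heterozygous advantage
    is non-positive) return ``p_fix = 0`` with ``valid = False``.
    """
    locus_class = LocusClass.parse(locus_class)
    s_f, s_m, h = regime.s_f, regime.s_m, regime.h

    if locus_class is LocusClass.AUTOSOMAL:
        p_fix = h * (s_f + s_m)
    elif locus_class is LocusClass.DIPLOID_X:
        p_fix = (2.0 / 3.0) * h * (2.0 * s_f + s_m)
    else:  # HEMIZYGOUS_X, closed form of the s_m -> s_m/h substitution
        p_fix = (2.0 / 3.0) * (2.0 * h * s_f + s_m)

    supercritical = p_fix > 0.0
    p_fix = max(p_fix, 0.0)

    # p_fix/2 is the sex-averaged heterozygous advantage entering the
    # 1/Ne << h*s << 1 validity condition.
    advantage = p_fix / 2.0
    ne = pop.ne_for(locus_class)
    valid = supercritical and (1.0 / ne < advantage < STRONG_SELECTION_CEILING)

    k_rel = pop.copies_for(locus_class) * p_fix
    return BranchingResult(p_fix=p_fix, K_rel=k_rel, valid=valid)


def R_branching(regime: SelectionRegime) -> float:
    """Diploid-X : autosomal ratio of adaptive substitution rates.

    Equals ``(2*s_f + s_m) / (2*s_f + 2*s_m)``; independent of the
    dominance coefficient and of any common rescaling of the selection
    coefficients.
    """
    denom = 2.0 * regime.s_f + 2.0 * regime.s_m
    if denom == 0.0:
        raise ParameterError(
            "branching-process ratio undefined when s_f + s_m = 0 "
            f"(got s_f={regime.s_f}, s_m={regime.s_m})"
        )
    return (2.0 * regime.s_f + regime.s_m) / denom
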