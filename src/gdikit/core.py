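"""Genetic differentiation from the genotypes of two diploid individuals.

The statistic implemented here is an FST-like *genetic
differentiation index* (GDI) computed from just two diploid genomes:

.. math::

    \\mathrm{GDI} = 1 - \\frac{\\pi_1 + \\pi_2}{2\\,\\pi_{tot}}

where :math:`\\pi_i` is the per-bp heterozygosity of individual *i* (its
nucleotide diversity, since a diploid carries two alleles) and
:math:`\\pi_{tot}` is the pooled nucleotide diversity of the four alleles
carried by the pair.  Under panmixia the genotype frequencies follow
Hardy–Weinberg expectations and E[GDI] = 0; population structure depresses
within-individual heterozygosity relative to the pooled diversity and pushes
GDI towards 1.  The index may be negative (an excess of shared
heterozygosity relative to the pooled diversity).

Each biallelic site seen in a pair of diploids falls into one of four
polymorphic categories — fixed difference (AA/TT), shared heterozygote
(AT/AT), heterozygote private to individual 1 (AT/AA) or to individual 2
(AA/AT) — or it is monomorphic.  :math:`\\pi_{tot}` uses the unbiased
average pairwise diversity over the n = 4 alleles of the pair,
:math:`\\frac{n}{n-1}(1-\\sum_a p_a^2)`, i.e. the mean number of differences
over the C(4,2) = 6 unordered allele pairs.  This choice makes E[GDI] = 0
exact under Hardy–Weinberg panmixia.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple


class Genotype(enum.IntEnum):
    """Unphased diploid genotype at a biallelic site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class SiteCategory(enum.Enum):
    """Category of a biallelic site seen in a pair of diploid individuals."""

    MONOMORPHIC = "monomorphic"
    FIXED_DIFF = "fixed_diff"
    SHARED_HET = "shared_het"
    PRIVATE_HET_1 = "private_het_1"
    PRIVATE_HET_2 = "private_het_2"
    UNUSABLE = "unusable"


#: Per-site contribution of each category to the pair's pooled diversity
#: pi_tot: (4/3) * (1 - p^2 - (1-p)^2) with p the alternate-allele frequency
#: among the four alleles of the pair.  Equivalently the mean number of
#: differences over the 6 unordered allele pairs: a fixed difference
#: (p=1/2) gives 4 differing pairs of 6 = 2/3, a shared heterozygote the
#: same, a private heterozygote (p=1/4 or 3/4) gives 3 of 6 = 1/2.
_PI_TOT_CONTRIBUTION = {
    SiteCategory.MONOMORPHIC: 0.0,
    SiteCategory.FIXED_DIFF: 2.0 / 3.0,
    SiteCategory.SHARED_HET: 2.0 / 3.0,
    SiteCategory.PRIVATE_HET_1: 0.5,
    SiteCategory.PRIVATE_HET_2: 0.5,
}

#: Sentinel for a GDI that is undefined because the pair carries no
#: polymorphism at all (pi_tot = 0).  Reported as missing, never as 0.
GDI_UNDEFINED = float("nan")


def classify_site(g1: int, g2: int) -> SiteCategory:
    """Classify one biallelic site from the genotypes of two individuals.

    Parameters
    ----------
    g1, g2
        `Genotype` values (or plain ints with the same encoding) for
        individual 1 and individual 2 at the same biallelic site.

    Returns
    -------
    SiteCategory
        Exactly one category; any missing genotype yields ``UNUSABLE``.
    """
    if g1 == Genotype.MISSING or g2 == Genotype.MISSING:
        return SiteCategory.UNUSABLE
    het1 = g1 == Genotype.HET
    het2 = g2 == Genotype.HET
    if het1 and het2:
        return SiteCategory.SHARED_HET
    if het1:
        return SiteCategory.PRIVATE_HET_1
    if het2:
        return SiteCategory.PRIVATE_HET_2
    if g1 != g2:
        return SiteCategory.FIXED_DIFF
    return SiteCategory.MONOMORPHIC


def individual_pi(het_site_count: int, denominator_bp: int) -> float:
    """Per-bp heterozygosity of one diploid individual.

    For a diploid genome the nucleotide diversity of the individual's two
    haplotypes equals the proportion of heterozygous positions, so
    ``pi = het_site_count / denominator_bp``.  The denominator is the total
    surveyed length in bp (positions absent from the call set are treated
    as homozygous reference).
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    if not 0 <= het_site_count <= denominator_bp:
        raise ValueError(
            f"het_site_count {het_site_count} outside [0, {denominator_bp}]"
        )
    return het_site_count / denominator_bp


def pair_pi_site(category: SiteCategory) -> float:
    """Per-site contribution of one classified site to the pair's pi_tot.

    Uses the unbiased 4-allele pairwise diversity
    (4/3)·(1 − p² − (1−p)²); monomorphic sites contribute 0.
    ``UNUSABLE`` has no defined contribution and raises.
    """
    try:
        return _PI_TOT_CONTRIBUTION[category]
    except KeyError:
        raise ValueError("pair_pi_site is undefined for UNUSABLE sites") from None


def pair_pi_total(
    site_categories: Iterable[SiteCategory], denominator_bp: int
) -> Tuple[float, int]:
    """Pooled per-bp diversity of a pair over a set of classified sites.

    Returns ``(pi_tot, n_unusable)``: the summed per-site contributions
    divided by the surveyed length, and the count of unusable
    (missing-genotype) sites, which contribute 0 and are tallied separately.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    total = 0.0
    n_unusable = 0
    for cat in site_categories:
        if cat is SiteCategory.UNUSABLE:
            n_unusable += 1
        else:
            total += _PI_TOT_CONTRIBUTION[cat]
    return total / denominator_bp, n_unusable


def gdi(pi_1: float, pi_2: float, pi_tot: float) -> float:
    """The genetic differentiation index 1 − (π₁ + π₂)/(2·π_tot).

    Returns NaN (undefined) when the pair carries no polymorphism at all
    (all three diversities zero).  A zero ``pi_tot`` with nonzero
    individual diversity is impossible under the pooled estimator (every
    heterozygous site contributes at least 1/2 to the pi_tot numerator)
    and raises.
    """
    if pi_tot < 0:
        raise ValueError("pi_tot must be non-negative")
    if pi_tot == 0.0:
        if pi_1 == 0.0 and pi_2 == 0.0:
            return GDI_UNDEFINED
        raise ValueError(
            "pi_tot = 0 with nonzero individual pi is inconsistent with the "
            "pooled pairwise-diversity estimator"
        )
    return 1.0 - (pi_1 + pi_2) / (2.0 * pi_tot)


@dataclass(frozen=True)
class PiEstimates:
    """Per-individual and pooled diversity for one pair over one region set.

    All diversities are per-bp; multiply by 1000 for the per-kb convention
    used in reports.
    """

    pi_ind_1: float
    pi_ind_2: float
    pi_tot: float
    n_sites_used: int
    n_sites_missing: int
    denominator_bp: int


@dataclass(frozen=True)
class GDIValue:
    gdi: float  # NaN when undefined (no polymorphism in the pair)
    kind: str  # "intra" or "inter"
    pair: Tuple[str, str]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.gdi)


def gdi_for_pair(
    genotype_pairs: Sequence[Tuple[int, int]],
    denominator_bp: int,
    kind: str = "intra",
    pair: Tuple[str, str] = ("ind1", "ind2"),
) -> Tuple[PiEstimates, GDIValue]:
    """Compute π₁, π₂, π_tot and the GDI for one pair over a region set.

    Parameters
    ----------
    genotype_pairs
        The (g1, g2) genotypes of the two individuals at every variant
        site within the surveyed regions.  Sites with a missing genotype
        are excluded from all numerators; the denominator is unchanged.
    denominator_bp
        Total surveyed length in bp (e.g. n_regions × window_bp).
    kind
        "intra" (same population) or "inter" (one individual per
        population); a label carried through to the result.
    """
    if kind not in ("intra", "inter"):
        raise ValueError(f"kind must be 'intra' or 'inter', got {kind!r}")
    het1 = 0
    het2 = 0
    categories = []
    for g1, g2 in genotype_pairs:
        cat = classify_site(g1, g2)
        categories.append(cat)
        if cat is not SiteCategory.UNUSABLE:
            if g1 == Genotype.HET:
                het1 += 1
            if g2 == Genotype.HET:
                het2 += 1
    pi_tot, n_missing = pair_pi_total(categories, denominator_bp)
    pi_1 = individual_pi(het1, denominator_bp)
    pi_2 = individual_pi(het2, denominator_bp)
    estimates = PiEstimates(
        pi_ind_1=pi_1,
        pi_ind_2=pi_2,
        pi_tot=pi_tot,
        n_sites_used=len(categories) - n_missing,
        n_sites_missing=n_missing,
        denominator_bp=denominator_bp,
    )
    value = GDIValue(gdi=gdi(pi_1, pi_2, pi_tot), kind=kind, pair=pair)
    return estimates, value
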