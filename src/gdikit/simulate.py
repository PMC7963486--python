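"""Coalescent simulation of two-population genotype data with known truth.

Generates biallelic SNP genotypes for a handful of diploid individuals
sampled from two populations that split ``T_split`` generations ago
(constant sizes, no migration by default), under the standard
continuous-time coalescent with infinite-sites mutation at rate ``mu``
per bp per generation.  Each contig is one non-recombining genealogy:
within a deme of diploid size N, k lineages coalesce at rate
k(k−1)/2 · 1/(2N) per generation; at ``T_split`` the demes merge into the
ancestral deme.  Mutations fall on branches as a Poisson process with
rate ``mu × L`` per generation and land at distinct uniform positions
(infinite sites), so every site is biallelic with the ancestral state as
the reference allele.

Because sample sizes are tiny (≤ ~12 haplotypes) the genealogy is built
directly; the whole simulation is exact under the model, seeded, and
deterministic.  Every dataset carries a truth record: for one individual
per population with equal sizes N and no migration, the expected
between-population differentiation index is E[GDI] ≈ T/(T + 3N) (ratio of
expectations), and each individual's expected heterozygosity is
θ = 4Nμ per bp.

A depth-dependent error model perturbs true genotypes the way shallow
sequencing does: per individual per site, depth d ~ Poisson(mean_depth);
d below the calling threshold gives a missing genotype, and a true
heterozygote is miscalled homozygous when all d reads happen to sample
one allele, probability (1/2)^(d−1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core import Genotype
from .genotype_io import ContigRegistry, VariantSite, build_contig_registry

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DemographicModel:
    """Isolation-model parameters for the two-population simulation.

    Sizes are diploid effective sizes (individuals); ``t_split`` is in
    generations; ``mu`` in mutations per bp per generation; genome =
    ``n_contigs`` contigs of ``l_bp`` each.  ``samples`` gives the number
    of diploids drawn from population A and from population B.
    ``migration_rate`` is the per-generation probability that a lineage
    migrates between demes (0 = strict isolation).
    """

    n_a: int = 10_000
    n_b: int = 10_000
    n_anc: int = 10_000
    t_split: int = 30_000
    mu: float = 1e-8
    l_bp: int = 1_000_000
    n_contigs: int = 10
    samples: Tuple[int, int] = (2, 1)
    migration_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_anc) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.t_split < 0:
            raise ValueError("t_split must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.l_bp < 1 or self.n_contigs < 1:
            raise ValueError("l_bp and n_contigs must be >= 1")
        if min(self.samples) < 0 or sum(self.samples) < 1:
            raise ValueError("need at least one sampled diploid")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")

    @property
    def total_bp(self) -> int:
        return self.l_bp * self.n_contigs

    @property
    def roster(self) -> List[str]:
        return [f"A{i + 1}" for i in range(self.samples[0])] + [
            f"B{i + 1}" for i in range(self.samples[1])
        ]

    @property
    def populations(self) -> Dict[str, str]:
        return {name: name[0] for name in self.roster}


@dataclass(frozen=True)
class SimTruth:
    """Analytical expectations accompanying a simulated dataset."""

    expected_gdi_inter: float
    expected_het_per_bp_a: float
    expected_het_per_bp_b: float
    model: DemographicModel

    def to_text(self) -> str:
        m = self.model
        return (
            "# truth record\n"
            f"expected_gdi_inter\t{self.expected_gdi_inter:.6g}\n"
            f"expected_het_per_bp_A\t{self.expected_het_per_bp_a:.6g}\n"
            f"expected_het_per_bp_B\t{self.expected_het_per_bp_b:.6g}\n"
            f"n_a\t{m.n_a}\nn_b\t{m.n_b}\nn_anc\t{m.n_anc}\n"
            f"t_split\t{m.t_split}\nmu\t{m.mu:.6g}\n"
            f"l_bp\t{m.l_bp}\nn_contigs\t{m.n_contigs}\n"
            f"samples\t{m.samples[0]},{m.samples[1]}\n"
            f"migration_rate\t{m.migration_rate:.6g}\nseed\t{m.seed}\n"
        )


def expected_gdi_inter(model: DemographicModel) -> float:
    """Closed-form E[GDI] (ratio of expectations) for one diploid per deme.

    E[π_X] = 4·N_X·μ within each deme; pooled over the four alleles the
    two within-individual pairs have expected coalescence 2·N_X and the
    four cross-deme pairs T + 2·N_anc, so

        E[GDI] = 1 − (4N_A + 4N_B) / (2 · (2N_A + 2N_B + 4T + 8N_anc)/3)

    which reduces to T/(T + 3N) when all sizes equal N.  Valid only
    without migration; with migration the truth is NaN (no closed form
    kept here).
    """
    if model.migration_rate > 0:
        return float("nan")
    m = model
    e_pi_a = 4 * m.n_a * m.mu
    e_pi_b = 4 * m.n_b * m.mu
    # pi_tot is the mean pairwise difference over the 6 allele pairs:
    # 2 within-individual pairs (E[T] = 2N_X) and 4 cross-deme pairs
    # (E[T] = T + 2N_anc), each contributing 2*mu*E[T] differences per bp
    e_pi_tot = 2 * m.mu * (2 * m.n_a + 2 * m.n_b + 4 * (m.t_split + 2 * m.n_anc)) / 6
    return 1.0 - (e_pi_a + e_pi_b) / (2.0 * e_pi_tot)


def sim_truth(model: DemographicModel) -> SimTruth:
    return SimTruth(
        expected_gdi_inter=expected_gdi_inter(model),
        expected_het_per_bp_a=4 * model.n_a * model.mu,
        expected_het_per_bp_b=4 * model.n_b * model.mu,
        model=model,
    )


def _simulate_genealogy(
    rng: np.random.Generator, model: DemographicModel
) -> Tuple[np.ndarray, List[Tuple[float, np.ndarray]]]:
    """One coalescent genealogy for all sampled haplotypes.

    Returns ``(branch_lengths, branches)`` where ``branches`` is a list of
    (length_in_generations, leaf_mask) pairs — a mutation on that branch
    makes exactly the masked haplotypes derived.
    """
    k_a = 2 * model.samples[0]
    k_b = 2 * model.samples[1]
    n_leaves = k_a + k_b
    # active lineages: (leaf_mask, birth_time); demes hold indices
    masks: List[np.ndarray] = [
        np.eye(n_leaves, dtype=bool)[i] for i in range(n_leaves)
    ]
    birth: List[float] = [0.0] * n_leaves
    deme_of: List[int] = [0] * k_a + [1] * k_b
    active = list(range(n_leaves))
    branches: List[Tuple[float, np.ndarray]] = []
    t = 0.0
    merged = model.t_split == 0
    if merged:
        deme_of = [0] * n_leaves
        sizes = {0: model.n_anc, 1: model.n_anc}
    else:
        sizes = {0: model.n_a, 1: model.n_b}

    def _coalesce(i: int, j: int, now: float) -> None:
        nonlocal active
        for idx in (i, j):
            branches.append((now - birth[idx], masks[idx]))
        new_mask = masks[i] | masks[j]
        masks.append(new_mask)
        birth.append(now)
        deme_of.append(deme_of[i])
        new_idx = len(masks) - 1
        active = [a for a in active if a not in (i, j)] + [new_idx]

    while len(active) > 1:
        in_deme = {0: [a for a in active if deme_of[a] == 0],
                   1: [a for a in active if deme_of[a] == 1]}
        rate_c = {
            d: len(in_deme[d]) * (len(in_deme[d]) - 1) / 2.0 / (2.0 * sizes[d])
            for d in (0, 1)
        }
        rate_m = 0.0 if merged else model.migration_rate * len(active)
        total = rate_c[0] + rate_c[1] + rate_m
        if total == 0.0:
            if merged:
                raise RuntimeError("no events possible after merge")  # pragma: no cover
            dt = model.t_split - t
        else:
            dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= model.t_split:
            # deme merge: everything moves to the ancestral deme
            t = model.t_split
            merged = True
            for a in active:
                deme_of[a] = 0
            sizes = {0: model.n_anc, 1: model.n_anc}
            continue
        t += dt
        u = rng.uniform(0.0, total)
        if u < rate_c[0]:
            i, j = rng.choice(len(in_deme[0]), size=2, replace=False)
            _coalesce(in_deme[0][i], in_deme[0][j], t)
        elif u < rate_c[0] + rate_c[1]:
            i, j = rng.choice(len(in_deme[1]), size=2, replace=False)
            _coalesce(in_deme[1][i], in_deme[1][j], t)
        else:
            a = active[int(rng.integers(len(active)))]
            deme_of[a] = 1 - deme_of[a]
    lengths = np.array([l for l, _ in branches])
    return lengths, branches


def simulate_genotypes(
    model: DemographicModel, seed: Optional[int] = None
) -> Tuple[List[VariantSite], SimTruth]:
    """Simulate the full multi-contig genotype dataset for a model.

    Returns sites sorted by (contig, position) and the truth record.
    Deterministic for a given (model, seed); ``seed`` defaults to
    ``model.seed``.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n_ind = sum(model.samples)
    sites: List[VariantSite] = []
    width = len(str(model.n_contigs))
    for c in range(model.n_contigs):
        contig = f"contig{c + 1:0{width}d}"
        lengths, branches = _simulate_genealogy(rng, model)
        total_len = float(lengths.sum())
        n_mut = rng.poisson(model.mu * model.l_bp * total_len)
        n_mut = min(n_mut, model.l_bp)  # infinite sites cannot exceed L
        if n_mut == 0:
            continue
        positions = np.sort(rng.choice(model.l_bp, size=n_mut, replace=False))
        which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
        for pos, b in zip(positions, which):
            mask = branches[b][1]
            # derived-allele count per diploid: haplotypes (2i, 2i+1)
            counts = mask.reshape(n_ind, 2).sum(axis=1)
            gts = tuple(
                int(
                    Genotype.HOM_REF
                    if c0 == 0
                    else Genotype.HET
                    if c0 == 1
                    else Genotype.HOM_ALT
                )
                for c0 in counts
            )
            ref = str(rng.choice(_NUCLEOTIDES))
            alt = str(rng.choice([n for n in "ACGT" if n != ref]))
            sites.append(
                VariantSite(
                    contig_id=contig,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    qual=float(rng.uniform(20.0, 60.0)),
                    genotypes=gts,
                )
            )
    return sites, sim_truth(model)


def contig_registry_for(model: DemographicModel) -> ContigRegistry:
    width = len(str(model.n_contigs))
    return build_contig_registry(
        [(f"contig{c + 1:0{width}d}", model.l_bp) for c in range(model.n_contigs)]
    )


@dataclass(frozen=True)
class DepthErrorModel:
    """Depth-dependent genotyping error for robustness experiments.

    Per individual per site, depth d ~ Poisson(mean_depth).  d below
    ``min_depth_call`` → missing genotype.  A true heterozygote is
    miscalled homozygous with probability (1/2)^(d−1) — the chance that
    all d reads sample the same allele — the miscalled allele chosen
    uniformly.  Homozygotes are never miscalled (no false heterozygotes
    by default); ``false_het_rate`` adds a uniform hom→het error for
    sensitivity runs.
    """

    mean_depth: float = 15.0
    min_depth_call: int = 1
    false_het_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.min_depth_call < 0:
            raise ValueError("min_depth_call must be >= 0")
        if not 0 <= self.false_het_rate <= 1:
            raise ValueError("false_het_rate must be in [0, 1]")

    def het_miscall_probability(self, depth: int) -> float:
        if depth < 1:
            return 1.0
        return 0.5 ** (depth - 1)


def apply_depth_error(
    sites: Sequence[VariantSite], error_model: DepthErrorModel, seed: int
) -> List[VariantSite]:
    """Perturb true genotypes under the depth model; site count conserved."""
    rng = np.random.default_rng(seed)
    out: List[VariantSite] = []
    for site in sites:
        n = len(site.genotypes)
        depths = rng.poisson(error_model.mean_depth, size=n)
        new_gts: List[int] = []
        for g, d in zip(site.genotypes, depths):
            if d < error_model.min_depth_call:
                new_gts.append(int(Genotype.MISSING))
                continue
            if g == Genotype.HET and rng.random() < error_model.het_miscall_probability(int(d)):
                new_gts.append(
                    int(Genotype.HOM_REF) if rng.random() < 0.5 else int(Genotype.HOM_ALT)
                )
            elif (
                error_model.false_het_rate > 0
                and g in (Genotype.HOM_REF, Genotype.HOM_ALT)
                and rng.random() < error_model.false_het_rate
            ):
                new_gts.append(int(Genotype.HET))
            else:
                new_gts.append(int(g))
        out.append(
            replace(site, genotypes=tuple(new_gts), depths=tuple(int(d) for d in depths))
        )
    return out


def write_vcf(
    sites: Sequence[VariantSite],
    roster: Sequence[str],
    registry: ContigRegistry,
    vcf_path: str | Path,
    fai_path: Optional[str | Path] = None,
) -> None:
    """Write sites as plain VCF 4.2 plus a FASTA-index-layout contig file.

    Input must be sorted by (contig order in the registry, position);
    round-trips losslessly through ``genotype_io.load_variants``.
    """
    order = {cid: i for i, (cid, _) in enumerate(registry.entries)}
    keys = [(order[s.contig_id], s.position) for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (contig, position)")
    gt_str = {
        int(Genotype.HOM_REF): "0/0",
        int(Genotype.HET): "0/1",
        int(Genotype.HOM_ALT): "1/1",
        int(Genotype.MISSING): "./.",
    }
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gdikit-synthetic\n")
        for cid, length in registry.entries:
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(roster)
            + "\n"
        )
        for s in sites:
            if s.depths is not None:
                fmt = "GT:DP"
                cols = [f"{gt_str[int(g)]}:{d}" for g, d in zip(s.genotypes, s.depths)]
            else:
                fmt = "GT"
                cols = [gt_str[int(g)] for g in s.genotypes]
            fh.write(
                f"{s.contig_id}\t{s.position + 1}\t.\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{s.qual:.2f}\t.\t.\t{fmt}\t" + "\t".join(cols) + "\n"
            )
    if fai_path is not None:
        with open(fai_path, "w") as fh:
            for cid, length in registry.entries:
                fh.write(f"{cid}\t{length}\t0\t{length}\t{length + 1}\n")


@dataclass
class ReferenceDataset:
    """One grid point of the synthetic reference suite."""

    label: str
    model: DemographicModel
    sites: List[VariantSite]
    truth: SimTruth


def make_reference_suite(
    seed: int,
    t_over_n: Sequence[float] = (0.0, 1.0, 3.0, 9.0),
    n: int = 5_000,
    mu: float = 1e-8,
    l_bp: int = 1_000_000,
    n_contigs: int = 10,
) -> List[ReferenceDataset]:
    """Simulate 3-diploid datasets (2 from A, 1 from B) over a T/N grid.

    Mirrors the reference-species-pair design: two individuals of one
    population (the intraspecific comparison) and one of the other (the
    interspecific comparison), at increasing split ages.  Expected
    between-population GDI at grid ratio r is r/(r + 3).
    """
    out = []
    for i, r in enumerate(t_over_n):
        model = DemographicModel(
            n_a=n,
            n_b=n,
            n_anc=n,
            t_split=int(round(r * n)),
            mu=mu,
            l_bp=l_bp,
            n_contigs=n_contigs,
            samples=(2, 1),
            seed=seed + i,
        )
        sites, truth = simulate_genotypes(model)
        out.append(
            ReferenceDataset(label=f"t_over_n_{r:g}", model=model, sites=sites, truth=truth)
        )
    return out
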