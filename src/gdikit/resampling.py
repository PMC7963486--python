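"""Seeded resampling of genomic windows and replicate-level GDI summaries.

The sampling design mirrors the study protocol: per replicate, 100 windows
of 100 kb are drawn uniformly at random from contigs longer than 100 kb
(10 replicates by default, i.e. 10 × 10 Mb), all sites of a replicate's
windows are pooled into a single GDI computation with denominator
n_regions × window_bp, and the replicate values are summarised as mean and
sample standard deviation.  A "combinatorial" preset with 5 replicates
exists for exhaustive pair-permutation analyses (e.g. 45 intra- and 100
inter-specific pairs from 10 + 10 individuals).

Windows within one replicate never overlap (no site is double-counted in
one estimate); windows of different replicates may overlap, as drawing
10 × 100 Mb from a genome necessarily implies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import GDIValue, PiEstimates, gdi_for_pair
from .genotype_io import Region, VariantTable, region_genotypes

#: Named plan presets: (n_replicates, n_regions, window_bp)
PRESETS: Dict[str, Tuple[int, int, int]] = {
    "default": (10, 100, 100_000),
    "combinatorial": (5, 100, 100_000),
}


@dataclass(frozen=True)
class PlanParams:
    window_bp: int = 100_000
    n_regions: int = 100
    n_replicates: int = 10

    def __post_init__(self) -> None:
        if min(self.window_bp, self.n_regions, self.n_replicates) < 1:
            raise ValueError("plan parameters must be positive")


@dataclass
class ResamplingPlan:
    params: PlanParams
    seed: int
    regions: List[List[Region]]  # one list per replicate

    @property
    def denominator_bp(self) -> int:
        return self.params.n_regions * self.params.window_bp

    def to_bed(self) -> str:
        """Serialize as BED with the replicate id in the name column."""
        lines = [f"# resampling plan seed={self.seed}"]
        for rep, regions in enumerate(self.regions):
            for r in regions:
                lines.append(f"{r.contig_id}\t{r.start}\t{r.end}\trep{rep}")
        return "\n".join(lines) + "\n"


def reduced_replicate_mode(preset: str = "combinatorial") -> PlanParams:
    """Named plan presets ('default': 10×100×100 kb; 'combinatorial': 5×100×100 kb)."""
    n_replicates, n_regions, window_bp = PRESETS[preset]
    return PlanParams(window_bp=window_bp, n_regions=n_regions, n_replicates=n_replicates)


def sample_regions(
    eligible: Sequence[Tuple[str, int]],
    params: PlanParams = PlanParams(),
    seed: int = 0,
) -> ResamplingPlan:
    """Draw the seeded plan of replicates × non-overlapping windows.

    Contigs are chosen with probability proportional to their number of
    available windows (⌊length/window⌋) and start positions uniformly on
    ``[0, length − window]``; within-replicate overlap is resolved by
    rejection.  Deterministic given ``seed``.

    Raises if the eligible contigs cannot host ``n_regions`` disjoint
    windows.
    """
    w = params.window_bp
    capacities = np.array([length // w for _, length in eligible], dtype=np.int64)
    usable = capacities > 0
    total_capacity = int(capacities.sum())
    if total_capacity < params.n_regions:
        raise ValueError(
            f"insufficient eligible sequence: {total_capacity} disjoint windows of "
            f"{w} bp available, {params.n_regions} required"
        )
    rng = np.random.default_rng(seed)
    contig_ids = [c for (c, _), u in zip(eligible, usable) if u]
    lengths = np.array([l for (_, l), u in zip(eligible, usable) if u])
    weights = capacities[usable] / total_capacity

    replicates: List[List[Region]] = []
    max_attempts = 1000 * params.n_regions
    for _ in range(params.n_replicates):
        chosen: Dict[str, List[Tuple[int, int]]] = {}
        regions: List[Region] = []
        attempts = 0
        while len(regions) < params.n_regions:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "window rejection sampling failed to place "
                    f"{params.n_regions} disjoint windows; eligible space too tight"
                )
            ci = int(rng.choice(len(contig_ids), p=weights))
            start = int(rng.integers(0, lengths[ci] - w + 1))
            end = start + w
            taken = chosen.setdefault(contig_ids[ci], [])
            if any(start < e and s < end for s, e in taken):
                continue
            taken.append((start, end))
            regions.append(Region(contig_ids[ci], start, end))
        replicates.append(regions)
    return ResamplingPlan(params=params, seed=seed, regions=replicates)


@dataclass
class ReplicateRecord:
    replicate: int
    estimates: PiEstimates
    value: GDIValue


@dataclass
class ReplicateSummary:
    """Across-replicate summary for one pair of individuals."""

    pair: Tuple[str, str]
    kind: str
    records: List[ReplicateRecord]
    mean_gdi: float
    sd_gdi: float
    mean_het_per_kb: Tuple[float, float]
    sd_het_per_kb: Tuple[float, float]
    n_replicates: int  # replicates with a defined GDI
    n_undefined: int
    seed: int


def _summary_from_records(
    pair: Tuple[str, str], kind: str, records: List[ReplicateRecord], seed: int
) -> ReplicateSummary:
    defined = [r for r in records if r.value.defined]
    gdis = np.array([r.value.gdi for r in defined])
    het1 = np.array([r.estimates.pi_ind_1 * 1000 for r in records])
    het2 = np.array([r.estimates.pi_ind_2 * 1000 for r in records])

    def _mean_sd(x: np.ndarray) -> Tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    mean_gdi, sd_gdi = _mean_sd(gdis)
    m1, s1 = _mean_sd(het1)
    m2, s2 = _mean_sd(het2)
    return ReplicateSummary(
        pair=pair,
        kind=kind,
        records=records,
        mean_gdi=mean_gdi,
        sd_gdi=sd_gdi,
        mean_het_per_kb=(m1, m2),
        sd_het_per_kb=(s1, s2),
        n_replicates=len(defined),
        n_undefined=len(records) - len(defined),
        seed=seed,
    )


def run_replicates(
    plan: ResamplingPlan,
    table: VariantTable,
    pairs: Sequence[Tuple[str, str, str]],
) -> Dict[Tuple[str, str], ReplicateSummary]:
    """Run the GDI over every replicate of the plan for each pair.

    For each (id1, id2, kind) pair and each replicate, all sites in the
    replicate's windows are pooled into one GDI computation with
    denominator ``n_regions × window_bp``.  Replicates with an undefined
    GDI (no polymorphism) are excluded from the mean/sd and counted.
    """
    out: Dict[Tuple[str, str], ReplicateSummary] = {}
    for id1, id2, kind in pairs:
        records = []
        for rep, regions in enumerate(plan.regions):
            genotype_pairs: List[Tuple[int, int]] = []
            for region in regions:
                genotype_pairs.extend(region_genotypes(table, region, (id1, id2)))
            est, val = gdi_for_pair(
                genotype_pairs, plan.denominator_bp, kind=kind, pair=(id1, id2)
            )
            records.append(ReplicateRecord(replicate=rep, estimates=est, value=val))
        out[(id1, id2)] = _summary_from_records((id1, id2), kind, records, plan.seed)
    return out


def enumerate_pairs(
    pop_a_ids: Sequence[str], pop_b_ids: Sequence[str]
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]]]:
    """All within-A pairs and all A×B pairs, lexicographically ordered.

    Returns ``(intra, inter)`` with |intra| = C(|A|, 2) and
    |inter| = |A|·|B| — e.g. 45 and 100 for 10 + 10 individuals.
    """
    intra = list(itertools.combinations(sorted(pop_a_ids), 2))
    inter = [(a, b) for a in sorted(pop_a_ids) for b in sorted(pop_b_ids)]
    return intra, inter


def summaries_to_tsv(summaries: Iterable[ReplicateSummary]) -> str:
    """Tab-separated across-replicate summary table."""
    lines = [
        "# pair\tkind\tmean_GDI\tsd_GDI\tmean_het1_per_kb\tsd_het1\t"
        "mean_het2_per_kb\tsd_het2\tn_replicates\tn_undefined\tseed"
    ]
    for s in summaries:
        lines.append(
            f"{s.pair[0]}/{s.pair[1]}\t{s.kind}\t{s.mean_gdi:.6g}\t{s.sd_gdi:.6g}\t"
            f"{s.mean_het_per_kb[0]:.6g}\t{s.sd_het_per_kb[0]:.6g}\t"
            f"{s.mean_het_per_kb[1]:.6g}\t{s.sd_het_per_kb[1]:.6g}\t"
            f"{s.n_replicates}\t{s.n_undefined}\t{s.seed}"
        )
    return "\n".join(lines) + "\n"


def replicates_to_tsv(summaries: Iterable[ReplicateSummary]) -> str:
    """Tab-separated per-replicate table (π values per kb)."""
    lines = [
        "# replicate\tpair\tkind\tpi_1_per_kb\tpi_2_per_kb\tpi_tot_per_kb\t"
        "n_sites\tn_missing\tGDI"
    ]
    for s in summaries:
        for r in s.records:
            e = r.estimates
            g = f"{r.value.gdi:.6g}" if r.value.defined else "NA"
            lines.append(
                f"{r.replicate}\t{s.pair[0]}/{s.pair[1]}\t{s.kind}\t"
                f"{e.pi_ind_1 * 1000:.6g}\t{e.pi_ind_2 * 1000:.6g}\t"
                f"{e.pi_tot * 1000:.6g}\t{e.n_sites_used}\t{e.n_sites_missing}\t{g}"
            )
    return "\n".join(lines) + "\n"
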