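"""Genotype input: contig registry, site filters and per-region slicing.

Reads diploid genotype calls (VCF) for a small named roster of individuals
mapped to one reference assembly, applies the site and contig filters used
throughout the pipeline — biallelic SNPs only, caller quality strictly
greater than ``min_qual`` (default 10), contigs strictly longer than
``min_contig_bp`` (default 100 kb), user-supplied contig exclusion lists
(e.g. contaminant or X-linked contigs) — and serves per-region genotype
slices to the statistics layer.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted on read, so a window ``[start, end)`` contains a site iff
``start <= pos0 < end``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import Genotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Site and contig filters.

    ``min_qual`` is strict (a site at exactly the threshold is dropped),
    matching the "quality higher than 10" rule; ``min_contig_bp`` is
    likewise strict ("longer than 100,000 bp").  Depth bounds default off;
    they exist only for parity experiments.
    """

    min_qual: float = 10.0
    window_bp: int = 100_000
    min_contig_bp: int = 100_000
    biallelic_snps_only: bool = True
    min_depth: Optional[int] = None
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.window_bp > self.min_contig_bp:
            raise ValueError("window_bp must not exceed min_contig_bp")


@dataclass
class ContigRegistry:
    """Reference contigs (name, length) with merged exclusion lists."""

    entries: List[Tuple[str, int]]
    excluded_ids: Set[str] = field(default_factory=set)
    unknown_excluded_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids in registry")
        if any(length <= 0 for _, length in self.entries):
            raise ValueError("contig lengths must be positive")
        self._lengths: Dict[str, int] = dict(self.entries)

    def length_of(self, contig_id: str) -> int:
        return self._lengths[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._lengths

    def is_excluded(self, contig_id: str) -> bool:
        return contig_id in self.excluded_ids


@dataclass(frozen=True)
class Region:
    """A half-open genomic window [start, end) on one contig."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region {self.contig_id}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-individual diploid genotype calls.

    ``position`` is 0-based.  ``genotypes`` is ordered per the declared
    individual roster.  ``depths`` is optional per-individual read depth.
    """

    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float
    genotypes: Tuple[int, ...]
    depths: Optional[Tuple[int, ...]] = None


def build_contig_registry(
    contig_index: Iterable[Tuple[str, int]],
    exclusions: Sequence[Iterable[str]] = (),
) -> ContigRegistry:
    """Build the contig registry from an index and exclusion id-lists.

    ``contig_index`` holds (name, length) records, e.g. the first two
    columns of a FASTA index (.fai).  ``exclusions`` is zero or more lists
    of contig ids (contaminant contigs, X-linked contigs, ...); they are
    merged.  Excluded ids absent from the index are retained in
    ``unknown_excluded_ids`` and logged, not fatal.
    """
    entries = list(contig_index)
    if not entries:
        raise ValueError("empty contig index")
    known = {c for c, _ in entries}
    excluded: Set[str] = set()
    for lst in exclusions:
        excluded.update(lst)
    unknown = excluded - known
    if unknown:
        logger.warning(
            "%d excluded contig id(s) not present in the index: %s",
            len(unknown),
            ", ".join(sorted(unknown)[:10]),
        )
    return ContigRegistry(
        entries=entries,
        excluded_ids=excluded & known | unknown,
        unknown_excluded_ids=unknown,
    )


def read_fai(path: str | Path) -> List[Tuple[str, int]]:
    """Read (name, length) pairs from a FASTA-index-layout file.

    Only the first two columns are used; further .fai columns (offset,
    linebases, linewidth) are ignored if present.
    """
    out: List[Tuple[str, int]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        out.append((parts[0], int(parts[1])))
    return out


def read_id_list(path: str | Path) -> List[str]:
    """Read one contig id per line; blank lines and '#' comments skipped."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def eligible_contigs(
    registry: ContigRegistry, cfg: FilterConfig
) -> List[Tuple[str, int]]:
    """Non-excluded contigs strictly longer than ``cfg.min_contig_bp``."""
    return [
        (cid, length)
        for cid, length in registry.entries
        if length > cfg.min_contig_bp and not registry.is_excluded(cid)
    ]


class FilterReport(dict):
    """Per-category drop counts from ``load_variants``."""

    CATEGORIES = (
        "input_records",
        "yielded",
        "dropped_qual",
        "dropped_multiallelic",
        "dropped_indel",
        "dropped_excluded_contig",
        "dropped_depth",
        "malformed_skipped",
    )

    def __init__(self) -> None:
        super().__init__({k: 0 for k in self.CATEGORIES})

    def to_tsv(self) -> str:
        lines = ["# filter report"]
        lines += [f"{k}\t{v}" for k, v in self.items()]
        return "\n".join(lines) + "\n"


_CYVCF2_GT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.MISSING, 3: Genotype.HOM_ALT}
_NUCS = frozenset("ACGT")


def load_variants(
    vcf_path: str | Path,
    roster: Sequence[str],
    cfg: FilterConfig = FilterConfig(),
    registry: Optional[ContigRegistry] = None,
    report: Optional[FilterReport] = None,
) -> Iterator[VariantSite]:
    """Stream filtered biallelic SNPs for the rostered individuals.

    Yields only biallelic SNPs with ``qual > cfg.min_qual``; multiallelic
    sites, indels, low-quality sites and sites on excluded contigs are
    dropped and counted in ``report``.  VCF positions are converted to
    0-based.  Raises if a roster id is absent from the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    missing = [s for s in roster if s not in header_samples]
    if missing:
        raise ValueError(f"roster id(s) not in VCF header: {', '.join(missing)}")
    idx = np.array([header_samples.index(s) for s in roster])
    if report is None:
        report = FilterReport()

    for record in vcf:
        report["input_records"] += 1
        try:
            if registry is not None and (
                record.CHROM not in registry or registry.is_excluded(record.CHROM)
            ):
                report["dropped_excluded_contig"] += 1
                continue
            alts = record.ALT
            if cfg.biallelic_snps_only and len(alts) != 1:
                report["dropped_multiallelic"] += 1
                continue
            ref, alt = record.REF, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
                report["dropped_indel"] += 1
                continue
            qual = record.QUAL if record.QUAL is not None else 0.0
            if not qual > cfg.min_qual:
                report["dropped_qual"] += 1
                continue
            gts = record.gt_types[idx]
            depths = None
            if cfg.min_depth is not None or cfg.max_depth is not None:
                try:
                    depths = record.format("DP")[:, 0][idx]
                except (TypeError, ValueError):
                    depths = None
                if depths is not None:
                    lo = cfg.min_depth if cfg.min_depth is not None else 0
                    hi = cfg.max_depth if cfg.max_depth is not None else np.inf
                    if np.any((depths < lo) | (depths > hi)):
                        report["dropped_depth"] += 1
                        continue
            site = VariantSite(
                contig_id=record.CHROM,
                position=record.POS - 1,
                ref_allele=ref,
                alt_allele=alt,
                qual=float(qual),
                genotypes=tuple(int(_CYVCF2_GT[g]) for g in gts),
                depths=tuple(int(d) for d in depths) if depths is not None else None,
            )
        except (KeyError, IndexError, AttributeError) as exc:  # malformed record
            logger.warning("skipping malformed record: %s", exc)
            report["malformed_skipped"] += 1
            continue
        report["yielded"] += 1
        yield site


class VariantTable:
    """Indexed, in-memory variant store supporting fast region queries.

    Sites are grouped per contig with positions sorted, so a half-open
    window is sliced with two binary searches.
    """

    def __init__(self, sites: Iterable[VariantSite], roster: Sequence[str]):
        self.roster = list(roster)
        self._by_contig: Dict[str, Tuple[np.ndarray, List[VariantSite]]] = {}
        grouped: Dict[str, List[VariantSite]] = {}
        for site in sites:
            if len(site.genotypes) != len(self.roster):
                raise ValueError(
                    f"site at {site.contig_id}:{site.position} has "
                    f"{len(site.genotypes)} genotypes for a roster of {len(self.roster)}"
                )
            grouped.setdefault(site.contig_id, []).append(site)
        for contig, lst in grouped.items():
            lst.sort(key=lambda s: s.position)
            self._by_contig[contig] = (
                np.array([s.position for s in lst], dtype=np.int64),
                lst,
            )

    def __len__(self) -> int:
        return sum(len(lst) for _, lst in self._by_contig.values())

    def individual_index(self, individual_id: str) -> int:
        return self.roster.index(individual_id)

    def sites_in_region(self, region: Region) -> List[VariantSite]:
        if region.contig_id not in self._by_contig:
            return []
        positions, lst = self._by_contig[region.contig_id]
        lo = int(np.searchsorted(positions, region.start, side="left"))
        hi = int(np.searchsorted(positions, region.end, side="left"))
        return lst[lo:hi]


def region_genotypes(
    table: VariantTable,
    region: Region,
    pair: Tuple[str, str],
    registry: Optional[ContigRegistry] = None,
) -> List[Tuple[int, int]]:
    """Genotype pairs for two individuals at every site within a region.

    Returns (g1, g2) tuples for all and only sites with
    ``region.start <= position < region.end`` (0-based half-open).  A
    missing genotype is passed through as ``Genotype.MISSING``; the
    statistics layer flags such sites as unusable.  Raises if the region
    lies on an excluded or unknown contig of the supplied registry.
    """
    if registry is not None:
        if region.contig_id not in registry:
            raise ValueError(f"region on unknown contig {region.contig_id!r}")
        if registry.is_excluded(region.contig_id):
            raise ValueError(f"region on excluded contig {region.contig_id!r}")
        if region.end > registry.length_of(region.contig_id):
            raise ValueError(
                f"region {region.contig_id}:{region.start}-{region.end} exceeds contig length"
            )
    i1 = table.individual_index(pair[0])
    i2 = table.individual_index(pair[1])
    return [
        (s.genotypes[i1], s.genotypes[i2]) for s in table.sites_in_region(region)
    ]


def configure_logging(verbose: bool = False) -> None:
    """Structured logs to stderr; -v enables DEBUG."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
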