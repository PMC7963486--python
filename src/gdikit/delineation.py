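"""Comparative species delineation from reference GDI values.

A focal pair's genetic differentiation index is compared against a table
of reference values computed the same way for well-defined species pairs:
intraspecific references (two individuals of one species) span the range
of within-species polymorphism, interspecific references (one individual
of each species of a closely related pair) span between-species
divergence.  A focal GDI at or above the smallest interspecific reference
is species-level differentiation; at or below the largest intraspecific
reference it is undifferentiated; anything between falls in the gray zone
of the speciation continuum.

Boundaries are closed (≥ min-inter counts as species level, ≤ max-intra as
undifferentiated) so the verdict is a total function.  Uncertainty (sds)
is carried through for reporting but does not enter the verdict, which
compares means; an optional conservative flag additionally requires the
focal mean to clear ``min_inter − sd(min-inter reference)``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

logger = logging.getLogger(__name__)


class Verdict(enum.Enum):
    SPECIES_LEVEL = "species_level"
    GRAY_ZONE = "gray_zone"
    UNDIFFERENTIATED = "undifferentiated"


@dataclass(frozen=True)
class ReferencePair:
    label: str
    kind: str  # "intraspecific" | "interspecific"
    gdi_mean: float
    gdi_sd: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("intraspecific", "interspecific"):
            raise ValueError(f"bad reference kind {self.kind!r}")
        if self.gdi_sd < 0:
            raise ValueError("gdi_sd must be >= 0")


@dataclass
class ReferenceTable:
    records: List[ReferencePair]
    max_intra_ref: float
    min_inter_ref: float
    min_inter_sd: float
    overlap: bool


@dataclass(frozen=True)
class DelineationVerdict:
    focal_label: str
    focal_gdi: float
    verdict: Verdict
    max_intra_ref: float
    min_inter_ref: float


def build_reference_table(records: Iterable[ReferencePair]) -> ReferenceTable:
    """Compute the delineation extrema over reference means.

    Requires at least one record of each kind.  If the intraspecific and
    interspecific reference ranges overlap (max intra > min inter) the
    table is still accepted, with a warning — verdicts near the boundary
    are then fragile.
    """
    records = list(records)
    intra = [r for r in records if r.kind == "intraspecific"]
    inter = [r for r in records if r.kind == "interspecific"]
    if not intra or not inter:
        raise ValueError(
            "reference table needs at least one intraspecific and one "
            "interspecific record"
        )
    max_intra = max(r.gdi_mean for r in intra)
    best_inter = min(inter, key=lambda r: r.gdi_mean)
    overlap = max_intra > best_inter.gdi_mean
    if overlap:
        logger.warning(
            "reference ranges overlap: max intraspecific GDI %.3f > min "
            "interspecific GDI %.3f",
            max_intra,
            best_inter.gdi_mean,
        )
    return ReferenceTable(
        records=records,
        max_intra_ref=max_intra,
        min_inter_ref=best_inter.gdi_mean,
        min_inter_sd=best_inter.gdi_sd,
        overlap=overlap,
    )


def classify_focal(
    focal_gdi: float,
    max_intra_ref: float,
    min_inter_ref: float,
    focal_label: str = "focal",
    conservative_sd: Optional[float] = None,
) -> DelineationVerdict:
    """Three-way verdict for a focal pair's GDI against reference extrema.

    ``focal_gdi >= min_inter_ref`` → SPECIES_LEVEL;
    ``focal_gdi <= max_intra_ref`` → UNDIFFERENTIATED; otherwise GRAY_ZONE.
    With ``conservative_sd`` set, the species-level bar is raised to
    ``min_inter_ref`` but a focal value within one reference sd below it is
    demoted to GRAY_ZONE.
    """
    for name, v in (("focal_gdi", focal_gdi), ("max_intra_ref", max_intra_ref),
                    ("min_inter_ref", min_inter_ref)):
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError(f"{name} must be finite")
    threshold_species = min_inter_ref
    if conservative_sd is not None:
        threshold_species = min_inter_ref + conservative_sd
    if focal_gdi >= threshold_species:
        verdict = Verdict.SPECIES_LEVEL
    elif focal_gdi <= max_intra_ref:
        verdict = Verdict.UNDIFFERENTIATED
    else:
        verdict = Verdict.GRAY_ZONE
    return DelineationVerdict(
        focal_label=focal_label,
        focal_gdi=focal_gdi,
        verdict=verdict,
        max_intra_ref=max_intra_ref,
        min_inter_ref=min_inter_ref,
    )


def read_reference_table(path: str | Path) -> List[ReferencePair]:
    """Read references from TSV: label, kind, gdi_mean, gdi_sd[, source]."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"bad reference record: {line!r}")
        records.append(
            ReferencePair(
                label=parts[0],
                kind=parts[1],
                gdi_mean=float(parts[2]),
                gdi_sd=float(parts[3]) if len(parts) > 3 and parts[3] else 0.0,
                source=parts[4] if len(parts) > 4 else "",
            )
        )
    return records


def verdict_to_text(v: DelineationVerdict) -> str:
    phrases = {
        Verdict.SPECIES_LEVEL: (
            "more differentiated than the least-differentiated well-defined "
            "reference species pair: species-level differentiation"
        ),
        Verdict.GRAY_ZONE: (
            "between the intraspecific and interspecific reference ranges: "
            "gray zone of the speciation continuum"
        ),
        Verdict.UNDIFFERENTIATED: (
            "within the intraspecific reference range: undifferentiated"
        ),
    }
    return (
        f"{v.focal_label}: GDI = {v.focal_gdi:.3f} "
        f"(reference max intra = {v.max_intra_ref:.3f}, "
        f"min inter = {v.min_inter_ref:.3f}) -> {v.verdict.value}\n"
        f"  {phrases[v.verdict]}\n"
    )


def verdict_to_record(v: DelineationVerdict) -> str:
    return (
        "# focal_label\tfocal_gdi\tverdict\tmax_intra_ref\tmin_inter_ref\n"
        f"{v.focal_label}\t{v.focal_gdi:.6g}\t{v.verdict.value}\t"
        f"{v.max_intra_ref:.6g}\t{v.min_inter_ref:.6g}\n"
    )
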