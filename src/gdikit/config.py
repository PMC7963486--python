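"""Flat key/value run configuration for the command-line pipeline.

One config file drives a run; command-line flags override file values.
The validated, effective configuration is serialized into the output
directory together with the seed and package version, so any output
directory is self-describing and exactly reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .genotype_io import FilterConfig
from .resampling import PlanParams


@dataclass
class RunConfig:
    """Validated configuration of one GDI run."""

    vcf: Path
    fai: Path
    roster: List[Tuple[str, str]]  # (individual_id, population_label)
    out_dir: Path
    exclude_files: List[Path] = field(default_factory=list)
    reference_table: Optional[Path] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    plan_params: PlanParams = field(default_factory=PlanParams)
    seed: int = 0
    focal_label: str = "focal"

    def __post_init__(self) -> None:
        if len(self.roster) < 2:
            raise ValueError("roster needs at least two individuals")
        ids = [i for i, _ in self.roster]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in roster")
        pops = {p for _, p in self.roster}
        if not 1 <= len(pops) <= 2:
            raise ValueError("roster must span one or two populations")

    def populations(self) -> Dict[str, List[str]]:
        pops: Dict[str, List[str]] = {}
        for ind, pop in self.roster:
            pops.setdefault(pop, []).append(ind)
        return pops

    def to_flat(self) -> Dict[str, str]:
        f, p = self.filter_config, self.plan_params
        flat = {
            "vcf": str(self.vcf),
            "fai": str(self.fai),
            "roster": ",".join(f"{i}:{pop}" for i, pop in self.roster),
            "out_dir": str(self.out_dir),
            "exclude_files": ",".join(str(e) for e in self.exclude_files),
            "reference_table": str(self.reference_table) if self.reference_table else "",
            "min_qual": str(f.min_qual),
            "window_bp": str(p.window_bp),
            "min_contig_bp": str(f.min_contig_bp),
            "n_regions": str(p.n_regions),
            "n_replicates": str(p.n_replicates),
            "seed": str(self.seed),
            "focal_label": self.focal_label,
        }
        return flat

    def serialize(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in sorted(self.to_flat().items()))

    def digest(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:16]


def parse_roster(text: str) -> List[Tuple[str, str]]:
    """Parse 'id1:popA,id2:popA,id3:popB' roster syntax."""
    roster = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ValueError(f"roster entry {item!r} must be id:population")
        ind, pop = item.split(":", 1)
        roster.append((ind.strip(), pop.strip()))
    return roster


def read_flat_config(path: str | Path) -> Dict[str, str]:
    """Read 'key = value' lines; '#' comments and blanks ignored."""
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def build_run_config(flat: Dict[str, str]) -> RunConfig:
    """Assemble and validate a RunConfig from flat key/value pairs."""
    required = ("vcf", "fai", "roster", "out_dir")
    missing = [k for k in required if not flat.get(k)]
    if missing:
        raise ValueError(f"missing config key(s): {', '.join(missing)}")
    window_bp = int(flat.get("window_bp", 100_000))
    min_contig = int(flat.get("min_contig_bp", max(100_000, window_bp)))
    fcfg = FilterConfig(
        min_qual=float(flat.get("min_qual", 10.0)),
        window_bp=window_bp,
        min_contig_bp=min_contig,
    )
    params = PlanParams(
        window_bp=window_bp,
        n_regions=int(flat.get("n_regions", 100)),
        n_replicates=int(flat.get("n_replicates", 10)),
    )
    excludes = [
        Path(p) for p in flat.get("exclude_files", "").split(",") if p.strip()
    ]
    ref = flat.get("reference_table", "")
    return RunConfig(
        vcf=Path(flat["vcf"]),
        fai=Path(flat["fai"]),
        roster=parse_roster(flat["roster"]),
        out_dir=Path(flat["out_dir"]),
        exclude_files=excludes,
        reference_table=Path(ref) if ref else None,
        filter_config=fcfg,
        plan_params=params,
        seed=int(flat.get("seed", 0)),
        focal_label=flat.get("focal_label", "focal"),
    )
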