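"""Barcoding-gap analysis on patristic distances from a phylogram.

Pairwise patristic distances (sums of branch lengths along the tip-to-tip
path, in substitutions per site) are computed from a newick phylogram,
partitioned into intraspecific distances (both tips of the same species:
polymorphism) and interspecific distances (divergence), and a threshold
separating the two distributions is estimated.  The threshold minimises
the number of misclassified records — intraspecific distances above it
plus interspecific distances below it — over an exhaustive scan of
midpoints between consecutive sorted distances, ties broken toward the
smaller threshold.  When the two distributions do not overlap the
threshold lies in the open gap (max intra, min inter) and misclassifies
nothing; the "barcoding gap" is that interval.

Patristic distance is root-invariant, so rooted and unrooted phylograms
are both accepted.  Tree inference itself is upstream; trees arrive as
newick with branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DistanceRecord:
    taxon_1: str
    taxon_2: str
    species_1: str
    species_2: str
    distance: float

    @property
    def relation(self) -> str:
        return "intraspecific" if self.species_1 == self.species_2 else "interspecific"


@dataclass(frozen=True)
class GapSummary:
    max_intra: float
    min_inter: float
    overlap: bool
    threshold: float
    misclassified_at_threshold: int
    n_intra: int
    n_inter: int


def load_tree(path: str | Path) -> dendropy.Tree:
    """Load a newick phylogram; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return tree


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip patristic distance matrix.

    d(i, j) is the sum of branch lengths on the unique path between tips
    i and j; d(i, i) = 0.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def read_species_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (tip_label, species) → mapping."""
    mapping: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"bad species-map line: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def partition_distances(
    matrix: pd.DataFrame,
    species_map: Dict[str, str],
    exclude: Sequence[str] = (),
    min_individuals_for_intra: int = 1,
) -> List[DistanceRecord]:
    """Label every tip pair's distance intra- or interspecific.

    Every retained tip must be mapped to a species; tips named in
    ``exclude`` (e.g. outgroups) are dropped first.  With
    ``min_individuals_for_intra`` > 1, species represented by fewer
    individuals contribute only interspecific records (their lone tips
    cannot inform within-species polymorphism).
    """
    tips = [t for t in matrix.index if t not in set(exclude)]
    unmapped = [t for t in tips if t not in species_map]
    if unmapped:
        raise ValueError(f"unmapped tip(s): {', '.join(unmapped)}")
    counts: Dict[str, int] = {}
    for t in tips:
        counts[species_map[t]] = counts.get(species_map[t], 0) + 1
    records = []
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            sa, sb = species_map[a], species_map[b]
            if sa == sb and counts[sa] < min_individuals_for_intra:
                continue
            records.append(
                DistanceRecord(
                    taxon_1=a,
                    taxon_2=b,
                    species_1=sa,
                    species_2=sb,
                    distance=float(matrix.loc[a, b]),
                )
            )
    return records


def estimate_gap(records: Iterable[DistanceRecord]) -> GapSummary:
    """Estimate the barcoding-gap threshold by misclassification scan.

    Candidate thresholds are the midpoints between consecutive sorted
    unique distances (plus flanking candidates below the minimum and above
    the maximum); the chosen threshold minimises
    ``#{intra > t} + #{inter < t}``, ties broken toward the smaller
    threshold.  Requires at least one record of each relation.
    """
    intra = np.array(sorted(r.distance for r in records if r.relation == "intraspecific"))
    inter = np.array(sorted(r.distance for r in records if r.relation == "interspecific"))
    if intra.size == 0 or inter.size == 0:
        raise ValueError("need at least one intraspecific and one interspecific record")
    values = np.unique(np.concatenate([intra, inter]))
    midpoints = (values[:-1] + values[1:]) / 2.0
    candidates = np.concatenate([[values[0] - 1e-12], midpoints, [values[-1] + 1e-12]])
    # misclassified(t) = intra strictly above t + inter strictly below t
    costs = np.array(
        [
            (intra > t).sum() + (inter < t).sum()
            for t in candidates
        ]
    )
    best = int(np.argmin(costs))  # argmin takes the first minimum: smaller threshold
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    overlap = max_intra > min_inter
    threshold = float(candidates[best])
    return GapSummary(
        max_intra=max_intra,
        min_inter=min_inter,
        overlap=overlap,
        threshold=threshold,
        misclassified_at_threshold=int(costs[best]),
        n_intra=int(intra.size),
        n_inter=int(inter.size),
    )


def records_to_tsv(records: Iterable[DistanceRecord]) -> str:
    lines = ["# taxon_1\ttaxon_2\tspecies_1\tspecies_2\tdistance\trelation"]
    for r in records:
        lines.append(
            f"{r.taxon_1}\t{r.taxon_2}\t{r.species_1}\t{r.species_2}\t"
            f"{r.distance:.6g}\t{r.relation}"
        )
    return "\n".join(lines) + "\n"


def gap_to_tsv(g: GapSummary) -> str:
    return (
        "# max_intra\tmin_inter\toverlap\tthreshold\tmisclassified\tn_intra\tn_inter\n"
        f"{g.max_intra:.6g}\t{g.min_inter:.6g}\t{int(g.overlap)}\t{g.threshold:.6g}\t"
        f"{g.misclassified_at_threshold}\t{g.n_intra}\t{g.n_inter}\n"
    )


def histogram_data(
    records: Iterable[DistanceRecord], n_bins: int = 40
) -> pd.DataFrame:
    """Binned counts per relation, for plotting the gap."""
    recs = list(records)
    dists = np.array([r.distance for r in recs])
    edges = np.histogram_bin_edges(dists, bins=n_bins)
    rows = []
    for relation in ("intraspecific", "interspecific"):
        sub = np.array([r.distance for r in recs if r.relation == relation])
        counts, _ = np.histogram(sub, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"relation": relation, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
    return pd.DataFrame(rows)
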