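#!/usr/bin/env python
"""Classify the simulated focal pairs against the carnivoran references.

Takes the between-population GDI estimates from 02_gdi_recovery.py and
compares each against the published reference extrema for well-defined
carnivoran species pairs — intraspecific GDIs range up to 0.137 (lion),
interspecific GDIs start at 0.437 (wolf/golden jackal) — issuing the
three-way verdict: species-level differentiation, gray zone, or
undifferentiated.

Writes results/verdicts.tsv.
"""

from pathlib import Path

from gdikit.delineation import (
    ReferencePair,
    build_reference_table,
    classify_focal,
    verdict_to_text,
)

ROOT = Path(__file__).resolve().parent.parent / "results"

CARNIVORA_REFERENCES = [
    ReferencePair("polar bear", "intraspecific", 0.029, source="resequencing"),
    ReferencePair("lion", "intraspecific", 0.137, source="resequencing"),
    ReferencePair("wolf/golden jackal", "interspecific", 0.437, source="resequencing"),
    ReferencePair("lion/leopard", "interspecific", 0.760, source="resequencing"),
]


def main() -> None:
    table = build_reference_table(CARNIVORA_REFERENCES)
    rows = ["# dataset\tinter_gdi\tverdict"]
    for line in (ROOT / "gdi_recovery.tsv").read_text().splitlines():
        if line.startswith("#"):
            continue
        name, _, _, inter_gdi, _ = line.split("\t")
        verdict = classify_focal(
            float(inter_gdi), table.max_intra_ref, table.min_inter_ref, name
        )
        rows.append(f"{name}\t{float(inter_gdi):.3f}\t{verdict.verdict.value}")
        print(verdict_to_text(verdict))
    (ROOT / "verdicts.tsv").write_text("\n".join(rows) + "\n")
    print(f"wrote {ROOT / 'verdicts.tsv'}")


if __name__ == "__main__":
    main()
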