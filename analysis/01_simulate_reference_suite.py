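#!/usr/bin/env python
"""Simulate the synthetic reference suite of two-population datasets.

Generates 3-diploid datasets (two individuals from population A, one from
population B) under the isolation model at split ages T/N in {0, 1, 3, 9}
with N = 5,000, mu = 1e-8 and a 10-Mb genome of 40 contigs, mirroring the
sampling design used for the reference species pairs.  Expected
between-population GDI at ratio r is r/(r+3), i.e. {0, 0.25, 0.5, 0.75}.

Writes one dataset directory per grid point under scratch/sim/ (VCF,
contig index, truth record, seed log) — regenerable bulk data, kept out
of results/.
"""

from pathlib import Path

from gdikit.cli import cmd_simulate
from gdikit.simulate import make_reference_suite

OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"
SEED = 20_260_101


def main() -> None:
    for ds in make_reference_suite(seed=SEED, n=5_000, l_bp=250_000, n_contigs=40):
        out = OUT / ds.label
        cmd_simulate(ds.model, out)
        print(
            f"{ds.label}: {len(ds.sites)} SNPs over {ds.model.total_bp/1e6:.0f} Mb, "
            f"expected inter GDI {ds.truth.expected_gdi_inter:.3g} -> {out}"
        )


if __name__ == "__main__":
    main()
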