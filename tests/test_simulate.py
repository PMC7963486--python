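"""The two-population coalescent generator and the depth-error model."""

import collections

import numpy as np
import pytest

from gdikit.core import Genotype, gdi_for_pair
from gdikit.genotype_io import FilterConfig, load_variants
from gdikit.simulate import (
    DemographicModel,
    DepthErrorModel,
    apply_depth_error,
    contig_registry_for,
    expected_gdi_inter,
    make_reference_suite,
    sim_truth,
    simulate_genotypes,
    write_vcf,
)

G = Genotype


def inter_genotype_pairs(model, sites):
    ia = 0
    ib = model.samples[0]  # first B individual
    return [(s.genotypes[ia], s.genotypes[ib]) for s in sites]


class TestModelValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_a": 0},
            {"t_split": -1},
            {"mu": 0.0},
            {"l_bp": 0},
            {"samples": (0, 0)},
            {"migration_rate": -0.1},
        ],
    )
    def test_bad_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            DemographicModel(**kw)

    def test_closed_form_expectation(self):
        m = DemographicModel(n_a=5000, n_b=5000, n_anc=5000, t_split=15_000)
        assert expected_gdi_inter(m) == pytest.approx(15_000 / (15_000 + 3 * 5000))
        truth = sim_truth(m)
        assert truth.expected_het_per_bp_a == pytest.approx(4 * 5000 * 1e-8)
        panmictic = DemographicModel(t_split=0)
        assert expected_gdi_inter(panmictic) == pytest.approx(0.0)

    def test_reference_suite_grid_expectations(self):
        suite = make_reference_suite(seed=1, l_bp=50_000, n_contigs=2)
        expected = [0.0, 0.25, 0.5, 0.75]  # r/(r+3) over the grid
        got = [d.truth.expected_gdi_inter for d in suite]
        assert got == pytest.approx(expected)


class TestGenerator:
    MODEL = DemographicModel(
        n_a=2000, n_b=2000, n_anc=2000, t_split=4000, l_bp=200_000, n_contigs=3, seed=5
    )

    def test_determinism(self):
        a, _ = simulate_genotypes(self.MODEL)
        b, _ = simulate_genotypes(self.MODEL)
        assert a == b
        c, _ = simulate_genotypes(self.MODEL, seed=6)
        assert a != c

    def test_infinite_sites_no_position_collisions(self):
        sites, _ = simulate_genotypes(self.MODEL)
        seen = collections.Counter((s.contig_id, s.position) for s in sites)
        assert max(seen.values()) == 1

    def test_sites_sorted_and_biallelic(self):
        sites, _ = simulate_genotypes(self.MODEL)
        keys = [(s.contig_id, s.position) for s in sites]
        assert keys == sorted(keys)
        for s in sites[:200]:
            assert s.ref_allele != s.alt_allele
            assert len(s.genotypes) == 3
            assert all(g != int(G.MISSING) for g in s.genotypes)
            assert 0 <= s.position < self.MODEL.l_bp

    def test_no_invariant_sites_emitted(self):
        """Every emitted site is polymorphic among the sampled haplotypes."""
        sites, _ = simulate_genotypes(self.MODEL)
        for s in sites:
            assert any(g != int(G.HOM_REF) for g in s.genotypes)
            # a mutation above the sample MRCA would make everyone hom-alt
            assert any(g != int(G.HOM_ALT) for g in s.genotypes)

    def test_migration_reduces_differentiation(self):
        """Strong gene flow pulls the realised inter GDI toward zero."""
        gdis = {}
        for label, m_rate in [("isolated", 0.0), ("mixing", 5e-4)]:
            vals = []
            for seed in range(8):
                m = DemographicModel(
                    n_a=2000, n_b=2000, n_anc=2000, t_split=20_000,
                    l_bp=200_000, n_contigs=10, samples=(1, 1),
                    migration_rate=m_rate, seed=seed,
                )
                sites, _ = simulate_genotypes(m)
                _, val = gdi_for_pair(inter_genotype_pairs(m, sites), m.total_bp, "inter")
                vals.append(val.gdi)
            gdis[label] = np.mean(vals)
        assert gdis["mixing"] < gdis["isolated"]

    def test_cross_check_against_msprime(self):
        """Independent oracle: msprime's isolation model yields statistically
        indistinguishable heterozygosity and inter-individual GDI."""
        import msprime

        n, t, L, reps = 1000, 3000, 1_000_000, 40
        mine, oracle = [], []
        het_mine, het_oracle = [], []
        for seed in range(reps):
            m = DemographicModel(
                n_a=n, n_b=n, n_anc=n, t_split=t, l_bp=L, n_contigs=1,
                samples=(1, 1), seed=seed,
            )
            sites, _ = simulate_genotypes(m)
            est, val = gdi_for_pair(inter_genotype_pairs(m, sites), L, "inter")
            if val.defined:
                mine.append(val.gdi)
            het_mine.append(est.pi_ind_1)

            demography = msprime.Demography()
            demography.add_population(name="A", initial_size=n)
            demography.add_population(name="B", initial_size=n)
            demography.add_population(name="ANC", initial_size=n)
            demography.add_population_split(time=t, derived=["A", "B"], ancestral="ANC")
            ts = msprime.sim_ancestry(
                samples={"A": 1, "B": 1}, demography=demography,
                sequence_length=L, random_seed=seed + 1,
            )
            mts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed + 1,
                                        model=msprime.BinaryMutationModel())
            geno = mts.genotype_matrix()
            pairs = []
            for row in geno:
                g1 = int(row[0] + row[1])
                g2 = int(row[2] + row[3])
                pairs.append((
                    [int(G.HOM_REF), int(G.HET), int(G.HOM_ALT)][g1],
                    [int(G.HOM_REF), int(G.HET), int(G.HOM_ALT)][g2],
                ))
            est_o, val_o = gdi_for_pair(pairs, L, "inter")
            if val_o.defined:
                oracle.append(val_o.gdi)
            het_oracle.append(est_o.pi_ind_1)

        def se(x):
            return np.std(x, ddof=1) / np.sqrt(len(x))

        diff_het = np.mean(het_mine) - np.mean(het_oracle)
        assert abs(diff_het) < 3 * np.hypot(se(het_mine), se(het_oracle))
        diff_gdi = np.mean(mine) - np.mean(oracle)
        assert abs(diff_gdi) < 3 * np.hypot(se(mine), se(oracle))


class TestVcfRoundTrip:
    def test_sites_round_trip_through_loader(self, sim_vcf_dir, isolation_dataset):
        d, model = sim_vcf_dir
        _, sites, _ = isolation_dataset
        cfg = FilterConfig(min_qual=10, window_bp=100_000, min_contig_bp=100_000)
        loaded = list(load_variants(d / "sim.vcf", model.roster, cfg))
        assert len(loaded) == len(sites)
        assert all(
            a.genotypes == b.genotypes and a.position == b.position
            and a.contig_id == b.contig_id
            for a, b in zip(sites, loaded)
        )

    def test_generator_sites_pass_quality_filter(self, sim_vcf_dir, isolation_dataset):
        from gdikit.genotype_io import FilterReport

        d, model = sim_vcf_dir
        report = FilterReport()
        cfg = FilterConfig(min_qual=10, window_bp=100_000, min_contig_bp=100_000)
        list(load_variants(d / "sim.vcf", model.roster, cfg, report=report))
        assert sum(v for k, v in report.items() if k.startswith("dropped")) == 0

    def test_empty_vcf_valid(self, tmp_path):
        model = DemographicModel(l_bp=1000, n_contigs=1)
        write_vcf([], model.roster, contig_registry_for(model), tmp_path / "e.vcf")
        text = (tmp_path / "e.vcf").read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "#CHROM" in text

    def test_unsorted_input_fatal(self, tmp_path, isolation_dataset):
        model, sites, _ = isolation_dataset
        with pytest.raises(ValueError):
            write_vcf(
                list(reversed(sites)), model.roster, contig_registry_for(model),
                tmp_path / "u.vcf",
            )


class TestDepthError:
    SITES, _ = simulate_genotypes(
        DemographicModel(n_a=2000, n_b=2000, n_anc=2000, t_split=4000,
                         l_bp=200_000, n_contigs=2, seed=3)
    )

    def test_site_count_conserved(self):
        out = apply_depth_error(self.SITES, DepthErrorModel(mean_depth=15), seed=1)
        assert len(out) == len(self.SITES)
        for s in out:
            assert s.depths is not None and len(s.depths) == len(s.genotypes)

    def test_high_depth_limit_is_identity(self):
        out = apply_depth_error(self.SITES, DepthErrorModel(mean_depth=1e4), seed=1)
        assert all(a.genotypes == b.genotypes for a, b in zip(self.SITES, out))

    def test_het_miscall_probability(self):
        m = DepthErrorModel(mean_depth=15)
        assert m.het_miscall_probability(1) == 1.0  # one read always looks hom
        assert m.het_miscall_probability(2) == 0.5
        assert m.het_miscall_probability(5) == pytest.approx(0.0625)

    def test_low_depth_creates_missing_and_miscalls(self):
        out = apply_depth_error(
            self.SITES, DepthErrorModel(mean_depth=1.0, min_depth_call=2), seed=1
        )
        flat_in = [g for s in self.SITES for g in s.genotypes]
        flat_out = [g for s in out for g in s.genotypes]
        n_missing = sum(g == int(G.MISSING) for g in flat_out)
        assert n_missing > 0
        # missing + called = total per individual
        assert len(flat_in) == len(flat_out)
        # hets never become more numerous
        assert sum(g == int(G.HET) for g in flat_out) <= sum(
            g == int(G.HET) for g in flat_in
        )

    def test_false_het_rate_adds_hets(self):
        out = apply_depth_error(
            self.SITES,
            DepthErrorModel(mean_depth=50, false_het_rate=0.5),
            seed=2,
        )
        hets_in = sum(g == int(G.HET) for s in self.SITES for g in s.genotypes)
        hets_out = sum(g == int(G.HET) for s in out for g in s.genotypes)
        assert hets_out > hets_in

    def test_determinism(self):
        a = apply_depth_error(self.SITES, DepthErrorModel(mean_depth=15), seed=9)
        b = apply_depth_error(self.SITES, DepthErrorModel(mean_depth=15), seed=9)
        assert a == b


def test_reference_suite_monotone_in_split_age():
    """Realised mean inter GDI increases along the T/N grid."""
    means = collections.defaultdict(list)
    for seed in range(6):
        for ds in make_reference_suite(seed=seed * 10, l_bp=250_000, n_contigs=8):
            pairs = inter_genotype_pairs(ds.model, ds.sites)
            _, val = gdi_for_pair(pairs, ds.model.total_bp, "inter")
            if val.defined:
                means[ds.truth.expected_gdi_inter].append(val.gdi)
    keys = sorted(means)
    realised = [np.mean(means[k]) for k in keys]
    assert realised == sorted(realised)
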