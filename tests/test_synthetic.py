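"""Genome construction, count simulation and fixture round trips."""

import numpy as np
import pytest

import rponseq as r
from rponseq.synthetic import PROMOTER_TYPES, SITE_CLASSES

from conftest import PLANTED_SMALL


def truth_element_groups(promoter):
    """Split a planted promoter's elements into σ54 / σ70 interval sets."""
    groups = {}
    for name, iv in promoter.elements.items():
        if name.startswith("s54_") or promoter.promoter_type.startswith("sigma54"):
            groups.setdefault("sigma54", []).append(iv)
        else:
            groups.setdefault("sigma70", []).append(iv)
    return {k: tuple(sorted(v)) for k, v in groups.items()}


class TestBuildGenome:
    def test_same_seed_is_byte_identical(self, small_genome):
        again = r.build_genome(40, PLANTED_SMALL, seed=1)
        assert again == small_genome

    def test_invariants(self, small_genome):
        g = small_genome
        g.validate()
        assert set("ACGT") >= set(g.sequence)
        for gene in g.genes:
            assert gene.length_bp >= 50
        target_ids = {p.target_gene_id for p in g.promoters}
        assert len(target_ids) == len(g.promoters)  # one promoter per gene

    def test_every_planted_element_recovered_at_truth_coordinates(self, small_genome):
        """Consensus-planted elements are rediscovered at zero weighted
        mismatches; bypass −12 elements (non-consensus C by construction)
        at the default threshold — all at their recorded coordinates."""
        found = {
            "sigma54": {
                tuple(sorted((s, e) for _, s, e in site.elements)): site
                for site in r.scan(small_genome.sequence, r.SIGMA54)
            },
            "sigma70": {
                tuple(sorted((s, e) for _, s, e in site.elements)): site
                for site in r.scan(small_genome.sequence, r.SIGMA70)
            },
        }
        for p in small_genome.promoters:
            for kind, key in truth_element_groups(p).items():
                site = found[kind].get(key)
                assert site is not None, (p.promoter_type, kind, key)
                if kind == "sigma54":
                    assert site.minus12_base == p.minus12_base
                    expected = 0.0 if p.minus12_base == "C" else 2.0
                    assert site.mismatches == expected
                else:
                    assert site.mismatches == 0.0
                exp_strand = (
                    p.sigma54_strand
                    if kind == "sigma54" and p.sigma54_strand
                    else p.strand
                )
                exp_tss = (
                    p.sigma54_tss
                    if kind == "sigma54" and p.sigma54_tss is not None
                    else p.tss
                )
                assert site.strand == exp_strand
                assert site.tss == exp_tss

    def test_no_spurious_perfect_consensus_sites(self, small_genome):
        truth54 = set()
        truth70 = set()
        for p in small_genome.promoters:
            groups = truth_element_groups(p)
            if "sigma54" in groups and p.minus12_base == "C":
                truth54.add(groups["sigma54"])
            if "sigma70" in groups:
                truth70.add(groups["sigma70"])
        for model, truth in ((r.SIGMA54, truth54), (r.SIGMA70, truth70)):
            for site in r.scan(small_genome.sequence, model, threshold=0.0):
                key = tuple(sorted((s, e) for _, s, e in site.elements))
                assert key in truth

    def test_class_iv_geometry(self):
        params = r.SimParams(repressed_classes=("IV",))
        g = r.build_genome(8, {"sigma70_repressed_by_sigma54": 2}, seed=5,
                           params=params)
        for p in g.promoters:
            assert p.site_class == "IV"
            assert p.sigma54_strand != p.strand  # opposite the target gene
            # σ54 site sits > 100 bp downstream of the σ70 tss (gene frame)
            offset = (p.sigma54_tss - p.tss) if p.strand == "+" else (p.tss - p.sigma54_tss)
            assert offset > 100

    def test_all_four_classes_cycle(self, small_genome):
        classes = [p.site_class for p in small_genome.promoters
                   if p.site_class is not None]
        assert sorted(classes) == sorted(SITE_CLASSES)

    def test_rejects_too_few_genes(self):
        with pytest.raises(ValueError):
            r.build_genome(7, {"sigma54_bypass": 2}, seed=0)

    def test_rejects_unknown_type(self):
        with pytest.raises(ValueError):
            r.build_genome(10, {"sigma99": 1}, seed=0)


class TestSimulateCounts:
    def test_same_seed_identical(self, small_genome):
        a = r.simulate_counts(small_genome, 100_000, 2, 5.0, seed=9)
        b = r.simulate_counts(small_genome, 100_000, 2, 5.0, seed=9)
        assert a.counts.equals(b.counts)

    def test_library_size_is_exact_column_sum(self, small_counts):
        for col in small_counts.counts.columns:
            strain, rep = col.rsplit("_", 1)
            assert small_counts.library_size(strain, int(rep)) == \
                small_counts.counts[col].sum()
        assert (small_counts.counts.to_numpy() >= 0).all()

    def test_poisson_limit_mean_matches_formula(self):
        """With very large dispersion the NB degenerates to Poisson and the
        empirical mean over 200 replicates matches μ within 3 SE."""
        g = r.build_genome(4, {}, seed=3)
        mu = r.expected_means(g, depth=50_000)
        counts = r.simulate_counts(g, 50_000, n_replicates=200,
                                   dispersion=1e9, seed=11)
        for gene_id in mu.index:
            row = counts.counts.loc[gene_id, counts.columns_for("WT")]
            m = mu.loc[gene_id, "WT"]
            se = np.sqrt(m / 200)  # Poisson variance ≈ mean
            assert abs(row.mean() - m) < 3 * se

    def test_repressed_none_over_wt_ratio(self):
        """A repressed gene with a_none/a_WT = 8 shows an empirical mean
        ratio within 3 SE of 8 over 200 replicates."""
        g = r.build_genome(8, {"sigma70_repressed_by_sigma54": 1}, seed=4)
        gene_id = next(p.target_gene_id for p in g.promoters)
        counts = r.simulate_counts(g, 200_000, n_replicates=200,
                                   dispersion=10.0, seed=12)
        none_mean = counts.counts.loc[gene_id, counts.columns_for("none")].mean()
        wt_mean = counts.counts.loc[gene_id, counts.columns_for("WT")].mean()
        mu = r.expected_means(g, 200_000)
        expected = mu.loc[gene_id, "none"] / mu.loc[gene_id, "WT"]
        assert expected == pytest.approx(8.0)  # shared normaliser preserves ratios
        cv = np.sqrt(1 / mu.loc[gene_id, "WT"] + 1 / 10.0)
        se_ratio = expected * cv * np.sqrt(2 / 200)
        assert abs(none_mean / wt_mean - expected) < 3 * se_ratio

    def test_nb_moments(self):
        """Sample mean/variance consistent with (μ, μ + μ²/k) at 500 reps."""
        g = r.build_genome(4, {}, seed=6)
        k = 10.0
        counts = r.simulate_counts(g, 100_000, n_replicates=500,
                                   dispersion=k, seed=13)
        mu = r.expected_means(g, 100_000)
        gene_id = mu.index[0]
        x = counts.counts.loc[gene_id, counts.columns_for("WT")].to_numpy()
        m = mu.loc[gene_id, "WT"]
        var = m + m * m / k
        assert abs(x.mean() - m) < 4 * np.sqrt(var / 500)
        # variance of the sample variance for NB ~ 2 var^2/(n-1) (+ kurtosis)
        assert abs(x.var(ddof=1) - var) < 5 * var * np.sqrt(2 / 499)

    def test_expected_library_size_near_depth(self):
        # when differentially-expressed genes are a small minority (the
        # realistic genome-wide regime) per-strain expected totals stay
        # within 10% of the target depth; the strain average is exact
        g = r.build_genome(
            200,
            {t: 1 for t in PROMOTER_TYPES},
            seed=8,
        )
        mu = r.expected_means(g, depth=123_456)
        assert np.allclose(mu.sum(axis=0), 123_456, rtol=0.10)
        assert mu.sum(axis=0).mean() == pytest.approx(123_456)

    def test_rejects_bad_parameters(self, small_genome):
        with pytest.raises(ValueError):
            r.simulate_counts(small_genome, 0, 3, 10.0, seed=1)
        with pytest.raises(ValueError):
            r.simulate_counts(small_genome, 1000, 3, -1.0, seed=1)


class TestFixtureRoundTrip:
    def test_write_then_read_is_identity(self, small_genome, small_counts, tmp_path):
        manifest = r.write_fixture(small_genome, small_counts, tmp_path)
        genome2, counts2 = r.read_fixture(tmp_path)
        assert genome2 == small_genome
        assert counts2.counts.equals(small_counts.counts)
        assert counts2.n_replicates == small_counts.n_replicates
        assert manifest["seed"] == small_genome.seed

    def test_truth_bed_is_zero_based_half_open(self, small_genome, small_counts, tmp_path):
        from rponseq import io
        r.write_fixture(small_genome, small_counts, tmp_path)
        bed = io.read_bed(tmp_path / "truth.bed")
        sigma70_rows = bed[bed["name"] == "sigma70_constitutive"]
        p = next(p for p in small_genome.promoters
                 if p.promoter_type == "sigma70_constitutive")
        spans = {(row.start, row.end) for row in sigma70_rows.itertuples()}
        expected = (min(s for s, _ in p.elements.values()),
                    max(e for _, e in p.elements.values()))
        assert expected in spans
        assert expected[1] - expected[0] == 29  # -35 start .. -10 end (half-open)

    def test_gff_round_trip_preserves_coordinates(self, small_genome, small_counts, tmp_path):
        from rponseq import io
        r.write_fixture(small_genome, small_counts, tmp_path)
        genes = [r.Gene(*rec) for rec in io.read_gff3(tmp_path / "genes.gff3")]
        assert sorted(genes, key=lambda g: g.start) == \
            sorted(small_genome.genes, key=lambda g: g.start)
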