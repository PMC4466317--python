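"""fGn generator, DNA coarsening and synthetic-genome construction."""

import numpy as np
import pytest
from scipy import stats as sps

from genehurst.codec import digitize, extract_gene_sequence, GenomeSequence
from genehurst.exceptions import DomainError, InputError
from genehurst.hurst import estimate
from genehurst.normality import ks_test_family
from genehurst.simulate import (
    FGnSpec,
    LogNormalLength,
    NormalMixture,
    SyntheticGenomeSpec,
    TruncatedNormal,
    fgn_autocovariance,
    fgn_to_dna,
    generate_genome,
    simulate_fgn,
)
from conftest import as_records


class TestAutocovariance:
    def test_white_noise_limit(self):
        assert fgn_autocovariance(0.5, 1.0, 1) == pytest.approx(0.0)

    def test_marginal_variance(self):
        for h in (0.3, 0.5, 0.9):
            assert fgn_autocovariance(h, 1.0, 0) == pytest.approx(1.0)

    def test_perfect_persistence_limit(self):
        assert fgn_autocovariance(1.0, 1.0, 1) == pytest.approx(1.0)

    def test_domain(self):
        with pytest.raises(DomainError):
            fgn_autocovariance(1.5, 1.0, 1)
        with pytest.raises(DomainError):
            fgn_autocovariance(0.5, -1.0, 1)

    def test_power_law_decay(self):
        """gamma(k) ~ H(2H-1) k^(2H-2) for large k."""
        h = 0.8
        k = np.array([64.0, 128.0, 256.0])
        ratio = fgn_autocovariance(h, 1.0, k) / (h * (2 * h - 1) * k ** (2 * h - 2))
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-3)


class TestSimulateFGn:
    def test_determinism(self):
        spec = FGnSpec(H=0.7, length=1024, seed=9)
        np.testing.assert_array_equal(simulate_fgn(spec), simulate_fgn(spec))

    def test_length_and_finiteness(self):
        x = simulate_fgn(FGnSpec(H=0.9, length=1000, seed=1))
        assert x.shape == (1000,) and np.all(np.isfinite(x))

    def test_white_noise_lag1_autocorrelation(self):
        """At H=0.5 the lag-1 autocorrelation is 0 in expectation."""
        acs = []
        for r in range(100):
            x = simulate_fgn(FGnSpec(H=0.5, length=4096, seed=700 + r))
            acs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert abs(np.mean(acs)) < 0.02

    def test_empirical_covariance_matches_theory(self):
        """Lags 1..5 at H=0.8: replicate means within 3 SE of closed form."""
        reps, n, h = 200, 1024, 0.8
        lags = np.arange(1, 6)
        est = np.empty((reps, lags.size))
        for r in range(reps):
            x = simulate_fgn(FGnSpec(H=h, length=n, seed=880 + r))
            for i, k in enumerate(lags):
                est[r, i] = np.dot(x[:-k], x[k:]) / (n - k)
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        theory = fgn_autocovariance(h, 1.0, lags)
        assert np.all(np.abs(mean - theory) < 3 * se + 1e-12)

    def test_marginal_sd_scales_with_sigma(self):
        a = simulate_fgn(FGnSpec(H=0.6, length=4096, seed=3, sigma=1.0))
        b = simulate_fgn(FGnSpec(H=0.6, length=4096, seed=3, sigma=2.5))
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(DomainError):
            FGnSpec(H=1.2, length=100, seed=0)


class TestFGnToDNA:
    def test_quartile_counts_balanced(self):
        x = simulate_fgn(FGnSpec(H=0.7, length=4000, seed=5))
        counts = np.bincount(fgn_to_dna(x).values, minlength=4)
        assert np.all(np.abs(counts - 1000) <= 2)

    def test_monotone_input_order_statistics(self):
        d = fgn_to_dna(np.arange(8.0))
        assert d.values.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_constant_input_degenerate(self):
        with pytest.raises(DomainError):
            fgn_to_dna(np.ones(16))

    def test_coarsening_preserves_scaling(self):
        """DFA on the digitized series recovers the continuous H to ~0.1
        (20-replicate spot check of the full acceptance property)."""
        errs = []
        for r in range(20):
            x = simulate_fgn(FGnSpec(H=0.8, length=8192, seed=9200 + r))
            errs.append(estimate(fgn_to_dna(x).values, "dfa").H - 0.8)
        assert abs(np.mean(errs)) < 0.1


class TestDistributions:
    def test_truncated_normal_respects_bounds(self, rng):
        d = TruncatedNormal(mean=0.9, sd=0.2, low=0.05, high=0.95)
        draws = d.sample(2000, rng)
        assert np.all((draws > 0.05) & (draws < 0.95))

    def test_mixture_weights_validated(self):
        with pytest.raises(DomainError):
            NormalMixture(components=((0.6, TruncatedNormal(0.5, 0.1)),))

    def test_gene_lengths_clipped(self, rng):
        lens = LogNormalLength().sample(5000, rng)
        assert lens.min() >= 150 and lens.max() <= 6000
        assert 600 < np.median(lens) < 1300


class TestGenerateGenome:
    def test_counts_and_total_length(self, small_synthetic):
        g = small_synthetic
        labels = [r["essentiality"] for r in g.gene_rows]
        assert labels.count("essential") == 10
        assert labels.count("nonessential") == 30
        gene_span = sum(r["end"] - r["start"] + 1 for r in g.gene_rows)
        assert gene_span < len(g.residues)  # spacers account for the rest

    def test_round_trip_extract_digitize(self, small_synthetic):
        """FASTA coordinates + strand recover the generated coding series
        bit-exactly for every gene."""
        g = small_synthetic
        genomes, genes = as_records(g)
        truth = {t["gene_id"]: t for t in g.truth}
        for gene in genes:
            seq = extract_gene_sequence(genomes[0], gene)
            assert seq == truth[gene.gene_id]["coding"]
            d = digitize(seq)
            assert np.all((d.values >= 0) & (d.values <= 3))

    def test_determinism(self):
        spec = SyntheticGenomeSpec(n_essential=5, n_nonessential=5, seed=77)
        assert generate_genome(spec).residues == generate_genome(spec).residues

    def test_zero_genes_rejected(self):
        with pytest.raises(InputError):
            SyntheticGenomeSpec(n_essential=0, n_nonessential=0)

    def test_truth_sidecar_and_files(self, small_synthetic_files):
        fasta, genes, truth = small_synthetic_files
        lines = truth.read_text().splitlines()
        assert lines[0] == "gene_id\ttrue_H\tgroup"
        assert len(lines) == 41
        assert fasta.read_text().startswith(">SYN_REPLICON_1")

    def test_essential_truth_h_normal(self):
        """Truth H of the essential group (a truncated normal draw) passes
        the normality K-S in nearly all seeded runs at n >= 100."""
        passes = 0
        reps = 20
        for seed in range(reps):
            g = generate_genome(
                SyntheticGenomeSpec(n_essential=100, n_nonessential=1, seed=4000 + seed)
            )
            h = [t["true_H"] for t in g.truth if t["group"] == "essential"]
            passes += ks_test_family(h, "normal").p >= 0.05
        assert passes >= int(0.9 * reps)

    def test_per_gene_estimates_track_truth(self):
        """Estimated H correlates with the generating H across genes."""
        g = generate_genome(SyntheticGenomeSpec(n_essential=40, n_nonessential=85, seed=3))
        truth_h, est_h = [], []
        genome = GenomeSequence(g.replicon_id, g.residues)
        truth = {t["gene_id"]: t["true_H"] for t in g.truth}
        _, genes = as_records(g)
        for gene in genes:
            seq = extract_gene_sequence(genome, gene)
            est_h.append(estimate(digitize(seq).values, "dfa").H)
            truth_h.append(truth[gene.gene_id])
        rho = sps.spearmanr(truth_h, est_h).statistic
        assert rho >= 0.6
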