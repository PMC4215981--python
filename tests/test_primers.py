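"""Genome-/allele-specific primer design and in-silico PCR."""

import numpy as np
import pytest

from pedqtl import primers
from pedqtl.core import ConfigError, DesignError
from pedqtl.sim import simulate_contig_triplet


@pytest.fixture(scope="module")
def triplet():
    return simulate_contig_triplet(1000, 0.03, 500, seed=4)


@pytest.fixture(scope="module")
def primer_set(triplet):
    return primers.design_primer_set(triplet, marker_id="snp1")


class TestFindHomoeologs:
    def _db(self, triplet):
        return [(f"contig_{g}", s) for g, s in triplet.sequences.items()]

    def test_perfect_match_contig_is_target(self, triplet):
        genome, offset, ref, alt = triplet.target_snp
        probe = triplet.sequences[genome][offset - 50 : offset + 50]
        found = primers.find_homoeologs(probe, self._db(triplet), 50, alt)
        assert found.target_genome == genome
        assert found.target_snp == triplet.target_snp

    def test_incomplete_genome_set_rejected(self, triplet):
        genome, offset, _, alt = triplet.target_snp
        probe = triplet.sequences[genome][offset - 50 : offset + 50]
        db = [r for r in self._db(triplet) if not r[0].endswith("_D")]
        with pytest.raises(DesignError, match="incomplete"):
            primers.find_homoeologs(probe, db, 50, alt)

    def test_scores_match_smith_waterman_oracle(self, triplet):
        """Alignment scores agree with an exhaustive quadratic-DP local aligner."""

        def sw(a, b, match=1, mismatch=-2, open_=-5, extend=-1):
            # affine-gap Smith-Waterman (Gotoh), O(len(a)*len(b))
            n, m = len(a), len(b)
            H = np.zeros((n + 1, m + 1))
            E = np.full((n + 1, m + 1), -np.inf)
            F = np.full((n + 1, m + 1), -np.inf)
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    E[i, j] = max(E[i, j - 1] + extend, H[i, j - 1] + open_ + extend)
                    F[i, j] = max(F[i - 1, j] + extend, H[i - 1, j] + open_ + extend)
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
                    best = max(best, H[i, j])
            return best

        genome, offset, _, _ = triplet.target_snp
        probe = triplet.sequences[genome][offset - 20 : offset + 20]
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        for g in ("A", "B", "D"):
            contig = triplet.sequences[g][offset - 150 : offset + 150]
            assert aligner.score(contig, probe) == pytest.approx(sw(contig, probe))


class TestDesignGsp:
    def test_zero_divergence_has_no_genome_specific_site(self):
        flat = simulate_contig_triplet(600, 0.0, 300, seed=0)
        with pytest.raises(DesignError, match="no genome-specific site"):
            primers.design_gsp(flat)

    def test_constraints_verified_post_hoc(self, triplet, primer_set):
        """Returned primers sit on discriminating sites with the SNP at the
        one-third position and Tm inside the window."""
        gsp = primer_set.gsp
        c = primers.DesignConstraints()
        seq = triplet.sequences[triplet.target_genome]
        others = [triplet.sequences[g] for g in triplet.off_genomes]
        for site in (gsp.forward_site, gsp.reverse_site):
            assert seq[site] != others[0][site] and seq[site] != others[1][site]
        frac = gsp.snp_fraction
        assert 0.233 <= min(frac, 1 - frac) <= 0.433
        assert c.amplicon_range[0] <= gsp.product_size <= c.amplicon_range[1]
        for tm in (gsp.tm_forward, gsp.tm_reverse):
            assert c.tm_range[0] <= tm <= c.tm_range[1]
        # primer sequences really are the amplicon termini
        assert seq[gsp.amplicon_start : gsp.amplicon_start + len(gsp.forward)] == gsp.forward
        assert primers.revcomp(seq[gsp.amplicon_end - len(gsp.reverse) : gsp.amplicon_end]) == gsp.reverse


class TestDesignAsp:
    def test_three_prime_base_is_the_allele(self, triplet, primer_set):
        _, s, ref, alt = triplet.target_snp
        asp1, asp2 = primer_set.asp_allele1, primer_set.asp_allele2
        if primer_set.asp_orientation == "reverse":
            from pedqtl.primers import _COMPLEMENT

            assert asp1.sequence[-1] == ref.translate(_COMPLEMENT)
            assert asp2.sequence[-1] == alt.translate(_COMPLEMENT)
        else:
            assert asp1.sequence[-1] == ref
            assert asp2.sequence[-1] == alt

    def test_asps_differ_only_at_three_prime_base(self, primer_set):
        a, b = primer_set.asp_allele1.sequence, primer_set.asp_allele2.sequence
        assert len(a) == len(b)
        assert a[:-1] == b[:-1] and a[-1] != b[-1]

    def test_engineered_mismatch_is_transversion_at_third_base(self, primer_set):
        for asp in (primer_set.asp_allele1, primer_set.asp_allele2):
            assert asp.mismatch_pos_from_3 == 3
            assert primers.TRANSVERSION[asp.original_base] == asp.substituted_base
            assert asp.sequence[-3] == asp.substituted_base

    def test_mismatch_counts_against_both_allele_templates(self):
        """Across simulated triplets every ASP carries exactly one engineered
        mismatch against its own allele's template and two against the other."""
        n_checked = 0
        for seed in range(30):
            triplet = simulate_contig_triplet(1000, 0.03, 500, seed=100 + seed)
            try:
                ps = primers.design_primer_set(triplet)
            except DesignError:
                continue
            n_checked += 1
            _, s, ref, alt = triplet.target_snp
            for asp, own, other in (
                (ps.asp_allele1, ref, alt),
                (ps.asp_allele2, alt, ref),
            ):
                L = len(asp.sequence)
                for allele, expected in ((own, 1), (other, 2)):
                    template = triplet.allele_sequence(allele)
                    if ps.asp_orientation == "reverse":
                        window = primers.revcomp(template[s : s + L])
                    else:
                        window = template[s - L + 1 : s + 1]
                    mism = sum(x != y for x, y in zip(asp.sequence, window))
                    assert mism == expected
        assert n_checked >= 20

    def test_identical_alleles_rejected_at_construction(self, triplet):
        from dataclasses import replace

        with pytest.raises(ConfigError, match="identical"):
            replace(
                triplet,
                target_snp=(triplet.target_snp[0], triplet.target_snp[1],
                            triplet.target_snp[2], triplet.target_snp[2]),
            )


class TestInsilicoPcr:
    def test_band_contract_on_both_alleles(self, triplet, primer_set):
        _, _, ref, alt = triplet.target_snp
        gsps = [primer_set.gsp_forward, primer_set.gsp_reverse]
        rx1 = gsps + [primer_set.asp_allele1.sequence]
        match = primers.insilico_pcr(rx1, triplet.allele_sequence(ref))
        mismatch = primers.insilico_pcr(rx1, triplet.allele_sequence(alt))
        assert match.n_bands == 2 and mismatch.n_bands == 1
        assert set(match.band_sizes) >= set(mismatch.band_sizes)  # GSP band shared
        assert max(match.band_sizes) == primer_set.expected_sizes[0]
        assert min(match.band_sizes) == primer_set.expected_sizes[1]

    def test_off_target_genome_gives_no_bands(self, triplet, primer_set):
        gsps = [primer_set.gsp_forward, primer_set.gsp_reverse]
        for genome in triplet.off_genomes:
            for asp in (primer_set.asp_allele1, primer_set.asp_allele2):
                bp = primers.insilico_pcr(gsps + [asp.sequence], triplet.sequences[genome])
                assert bp.n_bands == 0

    def test_agrees_with_brute_force_binding_scan(self, primer_set, triplet):
        """Amplicons match an independent per-offset scan of the binding rule."""
        template = triplet.allele_sequence(triplet.target_snp[2])[:600]
        plist = [primer_set.gsp_forward, primer_set.asp_allele1.sequence]

        def binds(primer, window):
            if len(window) != len(primer):
                return False
            mm = [a != b for a, b in zip(primer, window)]
            return (not mm[-1]) and sum(mm[-5:]) <= 1 and sum(mm) <= 3

        fwd, rev = [], []
        rc = primers.revcomp
        for p in plist:
            L = len(p)
            for start in range(len(template) - L + 1):
                window = template[start : start + L]
                if binds(p, window):
                    fwd.append((start, start + L - 1))
                if binds(p, rc(window)):
                    rev.append((start + L - 1, start))
        sizes = set()
        for f5, f3 in fwd:
            for r5, r3 in rev:
                if f3 <= r3 and 0 < r5 - f5 + 1 <= 2000:
                    sizes.add(r5 - f5 + 1)
        bp = primers.insilico_pcr(plist, template)
        assert set(bp.band_sizes) == sizes


class TestValidatePrimerSet:
    def test_well_formed_set_passes(self, triplet, primer_set):
        report = primers.validate_primer_set(primer_set, triplet)
        assert report.passed, report.failures

    def test_wrong_genome_gsps_fail_validation(self, triplet):
        """GSPs copied from an off-target subgenome amplify the wrong genome."""
        from dataclasses import replace

        good = primers.design_primer_set(triplet)
        off = triplet.off_genomes[0]
        seq = triplet.sequences[off]
        gsp = good.gsp
        bad_f = seq[gsp.amplicon_start : gsp.amplicon_start + len(gsp.forward)]
        bad_r = primers.revcomp(seq[gsp.amplicon_end - len(gsp.reverse) : gsp.amplicon_end])
        bad = replace(good, gsp_forward=bad_f, gsp_reverse=bad_r)
        report = primers.validate_primer_set(bad, triplet)
        assert not report.passed
        assert any("off-target" in f or "band" in f for f in report.failures)
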