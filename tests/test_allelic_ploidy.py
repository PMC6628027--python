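import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaclone import allelic_ploidy as ap
from metaclone import pipeline as pl
from metaclone import synthetic_cohort as sc
from metaclone._genome import AUTOSOMES, CHROM_LENGTHS


class TestExpectedLog2:
    def test_neutral_diploid_is_zero(self):
        assert ap.expected_log2(2, 1.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_normalised_to_sample_ploidy(self):
        assert ap.expected_log2(4, 1.0, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic_oracle(self):
        # (cT=1, rho=0.8, psi=2) -> log2(1.2/2.0)
        assert ap.expected_log2(1, 0.8, 2.0) == pytest.approx(np.log2(1.2 / 2.0), abs=1e-9)

    def test_zero_copies_full_purity_floored(self):
        assert ap.expected_log2(0, 1.0, 2.0) == ap.LOG2_FLOOR

    @given(rho=st.floats(0.05, 1.0), psi=st.floats(1.0, 5.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_total_copies(self, rho, psi):
        vals = ap.expected_log2(np.arange(1, 9), rho, psi)
        assert np.all(np.diff(vals) > 0)

    def test_no_tumour_signal_limit(self):
        # rho -> 0: ratio tends to 1 for every copy number
        for c in range(9):
            assert abs(ap.expected_log2(c, 1e-6, 2.0)) < 1e-5


class TestExpectedBaf:
    def test_balanced(self):
        assert ap.expected_baf(1, 1, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_full_loh(self):
        assert ap.expected_baf(2, 0, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_direct_arithmetic_oracle(self):
        # (2,1) at rho=0.6: mirrored((0.6+0.4)/(1.8+0.8))
        b = (0.6 * 1 + 0.4) / (0.6 * 3 + 0.8)
        assert ap.expected_baf(2, 1, 0.6) == pytest.approx(max(b, 1 - b), abs=1e-9)
        assert ap.expected_baf(2, 1, 0.6) == pytest.approx(0.6154, abs=1e-4)

    def test_empty_state_full_purity_sentinel(self):
        assert np.isnan(ap.expected_baf(0, 0, 1.0))

    @given(nB=st.integers(0, 4), extra=st.integers(0, 4),
           rho=st.floats(0.05, 1.0))
    @settings(deadline=None, max_examples=100)
    def test_unmirrored_symmetry_and_range(self, nB, extra, rho):
        """b(nA,nB) + b(nB,nA) = 1 on the unmirrored scale; mirrored value
        lies in [0.5, 1] and equals 0.5 iff the state is balanced."""
        nA = nB + extra
        den = rho * (nA + nB) + 2 * (1 - rho)
        if den == 0:
            return
        b_fwd = (rho * nB + (1 - rho)) / den
        b_rev = (rho * nA + (1 - rho)) / den
        assert b_fwd + b_rev == pytest.approx(1.0, abs=1e-12)
        mirrored = ap.expected_baf(nA, nB, rho)
        assert 0.5 - 1e-12 <= mirrored <= 1.0 + 1e-12
        if nA == nB:
            assert mirrored == pytest.approx(0.5, abs=1e-12)


class TestBafBands:
    def test_balanced_sites_even_parity(self):
        rng = np.random.default_rng(0)
        bafs = 0.5 + rng.normal(0, 0.02, 60)
        out = ap.baf_bands(bafs, depths=np.full(60, 600))
        assert out.parity == "even"
        assert out.band == pytest.approx(0.5, abs=0.03)

    def test_one_third_two_thirds_band(self):
        bafs = np.array([0.33, 0.67] * 20)
        out = ap.baf_bands(bafs)
        assert out.band == pytest.approx(0.667, abs=0.01)
        assert out.parity == "odd"

    def test_too_few_sites_indeterminate(self):
        out = ap.baf_bands([0.5, 0.5, 0.5])
        assert out.parity == "indeterminate"
        assert not out.determinate

    def test_loh_band_flagged(self):
        bafs = np.array([0.05, 0.95] * 20)
        out = ap.baf_bands(bafs)
        assert out.loh_flag
        assert out.band > 0.85

    def test_depth_debiasing_recovers_balanced_band_at_low_depth(self):
        """Mirror-free variance decomposition: binomial spread at depth 60
        must not masquerade as allelic imbalance."""
        rng = np.random.default_rng(1)
        depth = np.full(200, 60)
        bafs = rng.binomial(60, 0.5, 200) / 60
        out = ap.baf_bands(bafs, depths=depth)
        assert out.parity == "even"


def _diploid_case(rho=0.85, max_cn=4):
    """Six noise-free segments of a diploid-like genome."""
    states = [(1, 1), (2, 1), (2, 0), (1, 0), (2, 2), (2, 1)]
    lengths = [200, 100, 150, 120, 60, 90]
    psi = sum((a + b) * w for (a, b), w in zip(states, lengths)) / sum(lengths)
    rows, bands = [], []
    for i, ((nA, nB), w) in enumerate(zip(states, lengths)):
        rows.append({"chrom": AUTOSOMES[i], "start": 0, "end": w * 1_000_000,
                     "n_probes": w, "mean_log2": ap.expected_log2(nA + nB, rho, psi)})
        band = ap.expected_baf(nA, nB, rho)
        parity = "even" if nA == nB else "odd"
        bands.append(ap.BafBandSummary(i, [band], 50, parity, band >= 0.75))
    return pd.DataFrame(rows), bands, psi


def oracle_grid_score(segments, bands, rho, psi, max_cn=4, w=4.0, cap=0.1):
    """Independent plain-loop scorer for one (rho, psi) grid point.

    Returns (score, homdel_fraction) or None where a parity constraint
    leaves no admissible state.
    """
    total = 0.0
    zero_len = 0.0
    all_len = 0.0
    for (_, seg), band in zip(segments.iterrows(), bands):
        best, best_ct = np.inf, None
        for ct in range(max_cn + 1):
            for nb in range(ct // 2 + 1):
                na = ct - nb
                if band.determinate:
                    if band.parity == "even" and na != nb:
                        continue
                    if band.parity == "odd" and na == nb:
                        continue
                r = min((seg["mean_log2"] - ap.expected_log2(ct, rho, psi)) ** 2, cap)
                if band.determinate:
                    eb = ap.expected_baf(na, nb, rho)
                    eb = 0.5 if np.isnan(eb) else eb
                    r += w * (band.band - eb) ** 2
                if r < best:
                    best, best_ct = r, ct
        total += best
        length = seg["end"] - seg["start"]
        all_len += length
        if best_ct == 0:
            zero_len += length
    return total, zero_len / all_len


class TestFitPurityPloidy:
    def test_noise_free_diploid_self_consistency(self):
        seg, bands, psi = _diploid_case(rho=1.0)
        fit = ap.fit_purity_ploidy(seg, bands, max_cn=4)
        assert fit.purity == pytest.approx(1.0, abs=0.011)
        assert fit.ploidy == pytest.approx(psi, abs=0.05)
        allelic = ap.assign_allele_specific_cn(seg, bands, fit)
        assert allelic["assigned"].all()

    def test_matches_brute_force_enumeration(self):
        """The grid optimum equals an exhaustive plain-loop enumeration
        over (rho grid, psi grid, integer states) on a small instance."""
        seg, bands, _ = _diploid_case(rho=0.85)
        fit = ap.fit_purity_ploidy(seg, bands, max_cn=4)
        rho_grid, psi_grid = ap._grid()
        best = np.inf
        for rho in rho_grid:
            for psi in psi_grid:
                score, homdel = oracle_grid_score(seg, bands, rho, psi)
                if homdel <= 0.01 and score < best:
                    best = score
        at_fit, _ = oracle_grid_score(seg, bands, fit.purity, fit.grid_psi)
        assert at_fit == pytest.approx(fit.score, abs=1e-9)
        # noise-free instance: halving costs nothing, fit sits at the optimum
        assert fit.score == pytest.approx(best, abs=1e-9)

    def test_tetraploid_parameter_recovery(self, noise_free_patient):
        het = noise_free_patient.germline
        prof = pl.analyze_sample(
            noise_free_patient.probes["Pr4"], het[het["sample"] == "Pr4"],
            name="Pr4")
        truth = noise_free_patient.truth["samples"].set_index("sample")
        assert prof.fit.purity == pytest.approx(0.85, abs=0.05)
        assert prof.fit.ploidy == pytest.approx(truth.loc["Pr4", "ploidy"], abs=0.2)

    def test_all_indeterminate_raises(self):
        seg, bands, _ = _diploid_case()
        empty = [ap.BafBandSummary(i, [], 0, "indeterminate", False)
                 for i in range(len(seg))]
        with pytest.raises(ap.FitError):
            ap.fit_purity_ploidy(seg, empty)


class TestAssignment:
    def test_lowest_level_balanced_band_in_tetraploid_is_one_one(self):
        fit = ap.PurityPloidyFit(0.8, 3.6, 3.6, 0.0, ap.NEAR_TETRAPLOID)
        seg = pd.DataFrame({"chrom": ["chr13"], "start": [0], "end": [10],
                            "n_probes": [100],
                            "mean_log2": [ap.expected_log2(2, 0.8, 3.6)]})
        bands = [ap.BafBandSummary(0, [0.5], 100, "even", False)]
        out = ap.assign_allele_specific_cn(seg, bands, fit)
        assert (out.loc[0, "major_cn"], out.loc[0, "minor_cn"]) == (1, 1)
        assert out.loc[0, "total_cn"] == 2

    def test_copy_neutral_loh(self):
        fit = ap.PurityPloidyFit(1.0, 2.0, 2.0, 0.0, ap.NEAR_DIPLOID)
        seg = pd.DataFrame({"chrom": ["chr3"], "start": [0], "end": [10],
                            "n_probes": [100], "mean_log2": [0.0]})
        bands = [ap.BafBandSummary(0, [1.0], 100, "odd", True)]
        out = ap.assign_allele_specific_cn(seg, bands, fit)
        assert (out.loc[0, "major_cn"], out.loc[0, "minor_cn"]) == (2, 0)

    def test_exact_inversion_two_one(self):
        fit = ap.PurityPloidyFit(1.0, 2.0, 2.0, 0.0, ap.NEAR_DIPLOID)
        seg = pd.DataFrame({"chrom": ["chr5"], "start": [0], "end": [10],
                            "n_probes": [100],
                            "mean_log2": [ap.expected_log2(3, 1.0, 2.0)]})
        bands = [ap.BafBandSummary(0, [ap.expected_baf(2, 1, 1.0)], 100, "odd", False)]
        out = ap.assign_allele_specific_cn(seg, bands, fit)
        assert (out.loc[0, "major_cn"], out.loc[0, "minor_cn"]) == (2, 1)

    def test_off_ladder_segment_unassigned(self):
        fit = ap.PurityPloidyFit(1.0, 2.0, 2.0, 0.0, ap.NEAR_DIPLOID)
        seg = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [10],
                            "n_probes": [100], "mean_log2": [np.log2(2.5 / 2)]})
        bands = [ap.BafBandSummary(0, [], 0, "indeterminate", False)]
        out = ap.assign_allele_specific_cn(seg, bands, fit)
        assert not out.loc[0, "assigned"]


class TestClassifyPloidy:
    def _segments(self, cts, assigned=None):
        n = len(cts)
        assigned = [True] * n if assigned is None else assigned
        return pd.DataFrame({
            "chrom": [AUTOSOMES[i % len(AUTOSOMES)] for i in range(n)],
            "start": [0] * n, "end": [100] * n,
            "total_cn": cts, "major_cn": cts, "minor_cn": [0] * n,
            "assigned": assigned,
        })

    def test_all_two_copies_near_diploid(self):
        assert ap.classify_ploidy(self._segments([2, 2, 2])) == ap.NEAR_DIPLOID

    def test_boundary_three_is_other(self):
        assert ap.classify_ploidy(self._segments([3, 3, 3])) == ap.OTHER

    def test_insufficient_assignment_errors(self):
        seg = self._segments([2, 2, 2, 2], assigned=[True, False, False, False])
        with pytest.raises(ap.FitError):
            ap.classify_ploidy(seg)

    def test_simulated_metastasis_near_tetraploid(self, noise_free_patient):
        het = noise_free_patient.germline
        prof = pl.analyze_sample(noise_free_patient.probes["M2"],
                                 het[het["sample"] == "M2"], name="M2")
        assert prof.ploidy_class == ap.NEAR_TETRAPLOID


class TestDetectLoh:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn",
                                           "major_cn", "minor_cn", "assigned"])

    def test_hemizygous_loss_reported(self):
        out = ap.detect_loh(self._seg([("chr3", 0, 100, 1, 1, 0, True)]))
        assert len(out) == 1
        assert out.loc[0, "note"] == "single parental allele"

    def test_copy_neutral_loh_same_interval(self):
        out = ap.detect_loh(self._seg([("chr3", 0, 100, 2, 2, 0, True)]))
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 100

    def test_adjacent_segments_merged(self):
        out = ap.detect_loh(self._seg([("chr3", 0, 100, 1, 1, 0, True),
                                       ("chr3", 100, 250, 2, 2, 0, True)]))
        assert len(out) == 1
        assert out.loc[0, "end"] == 250

    def test_balanced_genome_empty(self):
        out = ap.detect_loh(self._seg([("chr1", 0, 100, 2, 1, 1, True)]))
        assert out.empty


class TestWgdConsistency:
    def test_clean_doubling_assigns_even_copies_genome_wide(self):
        """A whole-genome-doubled clone gets an even total copy number
        over >= 90% of the assigned genome.

        The doubling carries a handful of focal odd-copy losses (2% of the
        genome): a doubling with no odd-copy segment at all is
        mathematically indistinguishable from a diploid genome, and the
        fitter then prefers the parsimonious diploid reading — odd-copy
        segments are exactly the evidence that identifies tetraploidy.
        """
        ev = sc.CNAEvent
        focal = [ev(c, 40_000_000, 50_000_000, "B", -1)
                 for c in ("chr6", "chr8", "chr14", "chr15", "chr17",
                           "chr18", "chr21", "chr22")]
        clones = {
            "normal": sc.CloneNode("normal", None, []),
            "trunk": sc.CloneNode("trunk", "normal", [
                ev("chr3", 0, CHROM_LENGTHS["chr3"], "B", -1),
                ev("chr5", 50_000_000, CHROM_LENGTHS["chr5"], "A", +1),
            ]),
            "wgd": sc.CloneNode("wgd", "trunk", [sc.WGD] + focal),
        }
        g = sc.CloneGenotypes(clones)
        spec = sc.index_cohort_spec(seed=7, log2_sigma=0.0)
        sample = sc.SampleSpec("T", "primary", {"wgd": 1.0}, 0.8)
        probes, het = sc.realize_sample_signals(g, sample, spec, seed=7)
        prof = pl.analyze_sample(probes, het, name="T")
        seg = prof.segments
        seg = seg[seg["assigned"] & seg["chrom"].isin(AUTOSOMES)]
        lengths = (seg["end"] - seg["start"]).to_numpy(float)
        even = (seg["total_cn"] % 2 == 0).to_numpy()
        assert lengths[even].sum() / lengths.sum() >= 0.9
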