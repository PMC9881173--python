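import gzip

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from rmdkit.repeat_model import default_repeat_pair, detect_divergent_sites
from rmdkit.retention_pipeline import (
    AlignmentConfig,
    ReadCalls,
    RetentionProfile,
    SiteCallMatrix,
    aggregate_replicates,
    align_and_call,
    collapse_and_filter,
    compare_sites,
    fit_resolution_model,
    holm_sidak,
    polarity_index,
    retention_profile,
    run_pipeline,
)
from rmdkit.synthetic_data import (
    ResolutionParams,
    expected_retention,
    generate_reads,
    simulate_heteroduplex,
)


def make_profile(percentages, sample_id="s"):
    """Profile with the given per-site percentages out of 100 reads."""
    pct = np.asarray(percentages, dtype=float)
    k = pct.size
    return RetentionProfile(
        sample_id=sample_id,
        ranks=np.arange(1, k + 1),
        offsets=np.arange(k) * 10,
        n_top=np.round(pct).astype(int),
        n_bottom=100 - np.round(pct).astype(int),
        n_excluded=np.zeros(k, dtype=int),
    )


class TestCollapseAndFilter:
    def test_inclusive_threshold_edge(self):
        """At 10,000 reads, a 10-copy sequence (exactly 0.100%) is retained
        and a 9-copy sequence (0.09%) is dropped."""
        reads = ["AAAA"] * 9981 + ["CCCC"] * 10 + ["GGGG"] * 9
        table = collapse_and_filter(reads, min_fraction=0.001)
        assert table.total_reads == 10000
        assert "CCCC" in table.entries
        assert "GGGG" not in table.entries
        assert table.entries["CCCC"] == 10

    def test_zero_threshold_keeps_everything(self):
        reads = ["AA", "CC", "CC", "GG"]
        table = collapse_and_filter(reads, min_fraction=0.0)
        assert table.entries == {"AA": 1, "CC": 2, "GG": 1}

    def test_matches_brute_force_filter(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(500)]
        table = collapse_and_filter(seqs, min_fraction=0.004)
        counts = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        brute = {s: c for s, c in counts.items() if c / len(seqs) >= 0.004}
        assert table.entries == brute

    def test_raising_threshold_never_adds_sequences(self, rng):
        seqs = list(rng.choice(["AA", "CC", "GG", "TT", "AC", "AG"], 200, p=[0.4, 0.3, 0.15, 0.1, 0.04, 0.01]))
        retained = [
            set(collapse_and_filter(seqs, min_fraction=f).entries)
            for f in (0.0, 0.005, 0.02, 0.05, 0.2, 0.5)
        ]
        for bigger, smaller in zip(retained, retained[1:]):
            assert smaller <= bigger

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            collapse_and_filter([])

    def test_fastq_path_and_gzip_equivalent(self, tmp_path, pair3, wt_params):
        mols = simulate_heteroduplex(pair3, wt_params, 100, seed=1)
        reads = generate_reads(mols, seed=2)
        plain = tmp_path / "reads.fastq"
        SeqIO.write(reads, str(plain), "fastq")
        gz = tmp_path / "reads.fastq.gz"
        with gzip.open(gz, "wt") as fh:
            SeqIO.write(reads, fh, "fastq")
        a = collapse_and_filter(plain, min_fraction=0.0)
        b = collapse_and_filter(gz, min_fraction=0.0)
        assert a.entries == b.entries


class TestAlignAndCall:
    def test_top_sequence_calls_all_top(self, pair3):
        table = collapse_and_filter([pair3.top_seq])
        matrix = align_and_call(table, pair3)
        assert matrix.reads[0].calls == tuple(["TOP"] * 8)

    def test_bottom_sequence_calls_all_bottom(self, pair3):
        table = collapse_and_filter([pair3.bottom_seq])
        matrix = align_and_call(table, pair3)
        assert matrix.reads[0].calls == tuple(["BOTTOM"] * 8)

    def test_reverse_complement_detected(self, pair3):
        table = collapse_and_filter([reverse_complement(pair3.top_seq)])
        matrix = align_and_call(table, pair3)
        assert matrix.reads[0].calls == tuple(["TOP"] * 8)
        assert matrix.reads[0].orientation == "reverse"

    def test_third_base_called_other(self, pair3, sites3):
        site = sites3[3]
        third = ({"A", "C", "G", "T"} - {site.top_base, site.bottom_base}).pop()
        read = (
            pair3.top_seq[: site.offset] + third + pair3.top_seq[site.offset + 1 :]
        )
        matrix = align_and_call(collapse_and_filter([read]), pair3)
        assert matrix.reads[0].calls[3] == "OTHER"
        assert matrix.reads[0].calls[0] == "TOP"

    def test_deleted_site_called_gap(self, pair3, sites3):
        site = sites3[5]
        read = pair3.top_seq[: site.offset] + pair3.top_seq[site.offset + 1 :]
        matrix = align_and_call(collapse_and_filter([read]), pair3)
        assert matrix.reads[0].calls[5] == "GAP"

    def test_unrelated_read_fails_identity_gate(self, pair3):
        junk = ("ACGT" * 80)[: len(pair3)]
        matrix = align_and_call(collapse_and_filter([junk]), pair3)
        assert set(matrix.reads[0].calls) == {"GAP"}

    def test_site_offset_outside_reference_rejected(self, pair3, sites3):
        bad = [s for s in sites3]
        bad[0] = type(sites3[0])(rank=1, offset=999, top_base="A", bottom_base="G")
        with pytest.raises(ValueError, match="outside reference"):
            align_and_call(collapse_and_filter([pair3.top_seq]), pair3, sites=bad)

    def test_flanked_reads_align_with_free_end_gaps(self, pair3):
        read = "TTTTTTTT" + pair3.bottom_seq + "AAAAAAAA"
        matrix = align_and_call(collapse_and_filter([read]), pair3)
        assert matrix.reads[0].calls == tuple(["BOTTOM"] * 8)


class TestRetentionProfile:
    def test_all_top_is_hundred_percent(self, sites3):
        matrix = SiteCallMatrix(
            reads=[ReadCalls("x", 7, tuple(["TOP"] * 8), "forward", 0.0, 1.0)],
            sites=sites3,
        )
        profile = retention_profile(matrix)
        assert np.all(profile.retained_top_percent == 100.0)

    def test_weighted_counts_and_exclusions(self, sites3):
        rows = [
            ReadCalls("a", 3, tuple(["TOP"] * 8), "forward", 0.0, 1.0),
            ReadCalls("b", 1, tuple(["BOTTOM"] * 8), "forward", 0.0, 1.0),
            ReadCalls("c", 1, tuple(["OTHER"] * 8), "forward", 0.0, 1.0),
        ]
        profile = retention_profile(SiteCallMatrix(reads=rows, sites=sites3))
        assert np.all(profile.retained_top_percent == 75.0)
        assert np.all(profile.n_excluded == 1)

    def test_uninformative_site_reported_missing_not_zero(self, sites3):
        calls = ["TOP"] * 8
        calls[2] = "GAP"
        rows = [ReadCalls("a", 5, tuple(calls), "forward", 0.0, 1.0)]
        profile = retention_profile(SiteCallMatrix(reads=rows, sites=sites3))
        assert np.isnan(profile.retained_top_percent[2])
        assert profile.retained_top_percent[0] == 100.0

    def test_duplicating_reads_leaves_percentages_unchanged(self, pair3, wt_params):
        mols = simulate_heteroduplex(pair3, wt_params, 400, seed=3)
        reads = [m.sequence for m in mols]
        p1 = run_pipeline(reads, pair3, min_fraction=0.0)
        p2 = run_pipeline(reads * 2, pair3, min_fraction=0.0)
        np.testing.assert_allclose(
            p1.retained_top_percent, p2.retained_top_percent
        )

    def test_orientation_invariance(self, pair3, wt_params):
        mols = simulate_heteroduplex(pair3, wt_params, 400, seed=4)
        fwd = [m.sequence for m in mols]
        rev = [reverse_complement(s) for s in fwd]
        p1 = run_pipeline(fwd, pair3, min_fraction=0.0)
        p2 = run_pipeline(rev, pair3, min_fraction=0.0)
        np.testing.assert_allclose(
            p1.retained_top_percent, p2.retained_top_percent
        )

    def test_end_to_end_matches_closed_form(self, pair3, wt_params):
        """Simulate -> reads -> pipeline reproduces the closed-form retention
        curve within 3 binomial SE per site."""
        n = 20000
        mols = simulate_heteroduplex(pair3, wt_params, n, seed=5)
        reads = generate_reads(mols, error_rate=0.0, seed=6)
        profile = run_pipeline(reads, pair3, min_fraction=0.0)
        p = expected_retention(pair3, wt_params)
        se = np.sqrt(p * (1 - p) / n)
        np.testing.assert_array_less(
            np.abs(profile.retained_top_percent / 100.0 - p), 3 * se
        )


class TestAggregateAndCompare:
    def test_identical_replicates_have_zero_sd(self):
        profiles = [make_profile([60, 50, 40])] * 3
        summary = aggregate_replicates(profiles)
        assert np.all(summary.sd == 0.0)

    def test_mean_and_sd_forced_arithmetic(self):
        profiles = [make_profile([60] * 2), make_profile([70] * 2), make_profile([80] * 2)]
        summary = aggregate_replicates(profiles)
        assert summary.mean[0] == pytest.approx(70.0)
        assert summary.sd[0] == pytest.approx(10.0)

    def test_mismatched_site_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_replicates([make_profile([50, 50]), make_profile([50, 50, 50])])

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([make_profile([50])])

    def test_identical_sites_compare_at_p_one(self):
        profiles = [make_profile([60, 60, 30]) for _ in range(3)]
        table = compare_sites(profiles)
        row = table[(table.site_a == 1) & (table.site_b == 2)].iloc[0]
        assert row.p_raw == 1.0 and row.p_adjusted == 1.0

    def test_adjusted_never_below_raw_and_monotone(self, pair3, wt_params, rng):
        profiles = [
            make_profile(50 + rng.normal(0, 5, size=8), sample_id=f"r{i}")
            for i in range(3)
        ]
        table = compare_sites(profiles)
        assert np.all(table.p_adjusted >= table.p_raw - 1e-12)
        ordered = table.sort_values("p_raw")
        assert np.all(np.diff(ordered.p_adjusted) >= -1e-12)


class TestHolmSidak:
    def test_two_pvalue_worked_example(self):
        adjusted = holm_sidak([0.01, 0.04])
        assert adjusted[0] == pytest.approx(1 - 0.99**2)
        assert adjusted[1] == pytest.approx(max(1 - 0.99**2, 1 - 0.96))

    def test_single_comparison_unchanged(self):
        assert holm_sidak([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 1, size=12)
        ours = holm_sidak(p)
        theirs = statsmodels.multipletests(p, method="holm-sidak")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bounds_and_dominance(self, pvals):
        adjusted = holm_sidak(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-12)
        assert np.all((adjusted >= 0) & (adjusted <= 1))


class TestPolarityAndFit:
    def test_flat_profile_has_zero_polarity(self):
        summary = aggregate_replicates([make_profile([50] * 8)] * 3)
        assert polarity_index(summary) == 0.0

    def test_wild_type_polarity_positive_and_shrinks_with_pi(self, pair3, wt_params):
        exp_wt = expected_retention(pair3, wt_params) * 100
        exp_lo = expected_retention(pair3, wt_params.scaled(0.25)) * 100
        s_wt = aggregate_replicates([make_profile(exp_wt)] * 2)
        s_lo = aggregate_replicates([make_profile(exp_lo)] * 2)
        assert polarity_index(s_wt) > 0
        assert 0 < polarity_index(s_lo) < polarity_index(s_wt)

    def test_exact_closed_form_recovered(self, pair3):
        truth = ResolutionParams(pi_b=0.45, pi_t=0.3, theta_b=0.985, theta_t=0.995)
        exp = expected_retention(pair3, truth) * 100
        sites = detect_divergent_sites(pair3)
        profile = RetentionProfile(
            sample_id="exact",
            ranks=np.array([s.rank for s in sites]),
            offsets=np.array([s.offset for s in sites]),
            n_top=np.round(exp * 10).astype(int),
            n_bottom=np.round((100 - exp) * 10).astype(int),
            n_excluded=np.zeros(8, dtype=int),
        )
        # use exact percentages, not the integer-count approximation
        fit = fit_resolution_model(
            aggregate_replicates(
                [
                    RetentionProfile(
                        "a", profile.ranks, profile.offsets,
                        exp, 100 - exp, np.zeros(8),
                    ),
                    RetentionProfile(
                        "b", profile.ranks, profile.offsets,
                        exp, 100 - exp, np.zeros(8),
                    ),
                ]
            ),
            pair3,
        )
        assert fit.params.pi_b == pytest.approx(truth.pi_b, abs=1e-3)
        assert fit.params.pi_t == pytest.approx(truth.pi_t, abs=1e-3)
        assert fit.params.theta_b == pytest.approx(truth.theta_b, abs=1e-3)
        assert fit.params.theta_t == pytest.approx(truth.theta_t, abs=1e-3)

    def test_flat_profile_fits_null_excision(self, pair3):
        summary = aggregate_replicates([make_profile([50.0] * 8)] * 3)
        fit = fit_resolution_model(summary, pair3)
        assert fit.params.pi_b <= 0.02
        assert fit.params.pi_t <= 0.02

    def test_too_few_sites_rejected(self, pair3):
        summary = aggregate_replicates([make_profile([60, 40])] * 2)
        with pytest.raises(ValueError):
            fit_resolution_model(summary, pair3)
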