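"""Per-site strand-retention calling from amplicon reads.

This mirrors the product-analysis procedure for divergent-repeat
deletion products: collapse reads to unique sequences, keep those that
represent at least 0.1% of all reads for the sample, align each retained
unique read globally to the top-strand reference (free end gaps, both
orientations tried), call the base at every divergent site as TOP /
BOTTOM / OTHER / GAP, and report the percentage of reads retaining the
top-strand base per site.  Replicates are aggregated as mean and sample
SD, site pairs are compared with two-sample t-tests under Holm-Sidak
step-down correction, and the resolution-model parameters can be
recovered from a profile by constrained least squares.
"""

from __future__ import annotations

import gzip
import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .repeat_model import DivergentSite, RepeatPair, detect_divergent_sites
from .synthetic_data import ResolutionParams

CALL_TOP, CALL_BOTTOM, CALL_OTHER, CALL_GAP = "TOP", "BOTTOM", "OTHER", "GAP"


@dataclass
class AbundanceTable:
    """Unique read sequences with counts, after the abundance filter.

    ``total_reads`` is the pre-filter total over which fractions are
    computed; the retained entries are exactly those whose fraction of
    that total is >= the filter threshold (inclusive).
    """

    entries: dict[str, int]
    total_reads: int
    sample_id: str = "sample"

    @property
    def retained_reads(self) -> int:
        return sum(self.entries.values())


@dataclass(frozen=True)
class ReadCalls:
    """Site calls for one unique read sequence."""

    sequence: str
    count: int
    calls: tuple[str, ...]
    orientation: str  # "forward" or "reverse"
    score: float
    identity: float


@dataclass
class SiteCallMatrix:
    """Per-unique-read, per-site calls with alignment metadata."""

    reads: list[ReadCalls]
    sites: list[DivergentSite]
    sample_id: str = "sample"


@dataclass
class RetentionProfile:
    """Per-site counts and percent top-strand retention for one sample.

    ``retained_top_percent[i] = 100 * n_top[i] / (n_top[i] + n_bottom[i])``;
    sites where no read gives a TOP or BOTTOM call are reported as NaN
    (missing), never as 0.  OTHER and GAP calls count toward
    ``n_excluded`` only.
    """

    sample_id: str
    ranks: np.ndarray
    offsets: np.ndarray
    n_top: np.ndarray
    n_bottom: np.ndarray
    n_excluded: np.ndarray

    @property
    def retained_top_percent(self) -> np.ndarray:
        informative = self.n_top + self.n_bottom
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.n_top / informative
        return np.where(informative > 0, pct, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "offset": self.offsets,
                "n_top": self.n_top,
                "n_bottom": self.n_bottom,
                "n_excluded": self.n_excluded,
                "retained_top_percent": self.retained_top_percent,
            }
        )


@dataclass
class ProfileSummary:
    """Mean and sample SD of percent retention across replicates."""

    ranks: np.ndarray
    offsets: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "offset": self.offsets,
                "mean_retained_top_percent": self.mean,
                "sd": self.sd,
                "n_replicates": self.n_replicates,
            }
        )


# --------------------------------------------------------------------------
# read collapsing and filtering


def _iter_sequences(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
        return
    for item in reads:
        yield (str(item.seq) if hasattr(item, "seq") else str(item)).upper()


def collapse_and_filter(
    reads, min_fraction: float = 0.001, sample_id: str = "sample"
) -> AbundanceTable:
    """Collapse reads to unique sequences; keep those at >= ``min_fraction``.

    ``reads`` may be a FASTQ path (``.gz`` accepted) or an iterable of
    records/strings.  Counts are computed over *all* reads and the
    threshold is inclusive (a sequence at exactly 0.1% of 10,000 reads,
    i.e. 10 copies, is retained).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    counts = Counter(_iter_sequences(reads))
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads in input")
    entries = {
        seq: n for seq, n in counts.items() if n / total >= min_fraction
    }
    return AbundanceTable(entries=entries, total_reads=total, sample_id=sample_id)


# --------------------------------------------------------------------------
# alignment and site calling


@dataclass(frozen=True)
class AlignmentConfig:
    """Global-alignment scoring for site genotyping.

    Match/mismatch/gap default to +1/-2/-3 with free end gaps; reads
    whose identity to the top-strand reference over the repeat window
    falls below ``min_identity`` are called GAP at every site.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -3.0
    min_identity: float = 0.8
    flank_left: str = ""
    flank_right: str = ""


def _make_aligner(config: AlignmentConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap
    aligner.extend_gap_score = config.gap
    # free end gaps, spelled differently across Biopython versions
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # pragma: no cover
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _aligned_bases(alignment, read: str, positions: Sequence[int]) -> list[str | None]:
    """Base of ``read`` aligned to each reference position (None = gap)."""
    blocks = alignment.aligned
    out: list[str | None] = []
    for pos in positions:
        base = None
        for (t0, t1), (q0, q1) in zip(blocks[0], blocks[1]):
            if t0 <= pos < t1:
                base = read[q0 + (pos - t0)]
                break
        out.append(base)
    return out


def align_and_call(
    table: AbundanceTable,
    pair: RepeatPair,
    sites: Sequence[DivergentSite] | None = None,
    config: AlignmentConfig | None = None,
) -> SiteCallMatrix:
    """Align each unique read to the top-strand reference and call sites.

    Each read is aligned in both orientations and the better-scoring one
    kept (ties go to forward).  At each divergent site the aligned base
    is classified TOP (equals the top-strand base), BOTTOM (equals the
    bottom-strand base), OTHER (a third base) or GAP (deleted or not
    covered); reads failing the minimum-identity gate get GAP at all
    sites.
    """
    config = config or AlignmentConfig()
    if sites is None:
        sites = detect_divergent_sites(pair)
    sites = list(sites)
    if not sites:
        raise ValueError("no divergent sites to call")
    for s in sites:
        if not 0 <= s.offset < len(pair):
            raise ValueError(f"site offset {s.offset} outside reference of length {len(pair)}")

    reference = config.flank_left + pair.top_seq + config.flank_right
    window_start = len(config.flank_left)
    window = range(window_start, window_start + len(pair))
    site_positions = [window_start + s.offset for s in sites]
    aligner = _make_aligner(config)

    rows: list[ReadCalls] = []
    for seq, count in table.entries.items():
        rc = reverse_complement(seq)
        score_f = aligner.score(reference, seq)
        score_r = aligner.score(reference, rc)
        if score_f >= score_r:
            read, orientation, score = seq, "forward", score_f
        else:
            read, orientation, score = rc, "reverse", score_r
        alignment = aligner.align(reference, read)[0]

        window_bases = _aligned_bases(alignment, read, window)
        matches = sum(
            1 for pos, base in zip(window, window_bases) if base == reference[pos]
        )
        identity = matches / len(pair)
        if identity < config.min_identity:
            calls = tuple(CALL_GAP for _ in sites)
        else:
            calls = []
            for site, pos in zip(sites, site_positions):
                base = window_bases[pos - window_start]
                if base is None:
                    calls.append(CALL_GAP)
                elif base == site.top_base:
                    calls.append(CALL_TOP)
                elif base == site.bottom_base:
                    calls.append(CALL_BOTTOM)
                else:
                    calls.append(CALL_OTHER)
            calls = tuple(calls)
        rows.append(
            ReadCalls(
                sequence=seq,
                count=count,
                calls=calls,
                orientation=orientation,
                score=score,
                identity=identity,
            )
        )
    return SiteCallMatrix(reads=rows, sites=sites, sample_id=table.sample_id)


def retention_profile(matrix: SiteCallMatrix, sample_id: str | None = None) -> RetentionProfile:
    """Abundance-weighted percent top-strand retention per site."""
    if not matrix.reads:
        raise ValueError("empty site-call matrix")
    k = len(matrix.sites)
    n_top = np.zeros(k, dtype=np.int64)
    n_bottom = np.zeros(k, dtype=np.int64)
    n_excluded = np.zeros(k, dtype=np.int64)
    for row in matrix.reads:
        for i, call in enumerate(row.calls):
            if call == CALL_TOP:
                n_top[i] += row.count
            elif call == CALL_BOTTOM:
                n_bottom[i] += row.count
            else:
                n_excluded[i] += row.count
    return RetentionProfile(
        sample_id=sample_id or matrix.sample_id,
        ranks=np.array([s.rank for s in matrix.sites]),
        offsets=np.array([s.offset for s in matrix.sites]),
        n_top=n_top,
        n_bottom=n_bottom,
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# replicate aggregation and statistics


def _check_same_sites(profiles: Sequence[RetentionProfile]) -> None:
    first = profiles[0]
    for p in profiles[1:]:
        if not (
            np.array_equal(p.ranks, first.ranks)
            and np.array_equal(p.offsets, first.offsets)
        ):
            raise ValueError("replicate profiles have mismatched site sets")


def aggregate_replicates(profiles: Sequence[RetentionProfile]) -> ProfileSummary:
    """Per-site mean and sample SD (ddof=1) of percent retention."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicate profiles")
    _check_same_sites(profiles)
    values = np.vstack([p.retained_top_percent for p in profiles])
    return ProfileSummary(
        ranks=profiles[0].ranks.copy(),
        offsets=profiles[0].offsets.copy(),
        mean=values.mean(axis=0),
        sd=values.std(axis=0, ddof=1),
        n_replicates=len(profiles),
    )


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Raw p-values are ordered ascending and ``adj_k`` is the running
    maximum of ``1 - (1 - p_j)**(m - j + 1)`` for ``j <= k`` (1-based),
    clipped to [0, 1]; the adjusted sequence is monotone and each
    adjusted value is >= its raw value.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for step, idx in enumerate(order):  # step is 0-based: m - step = m - j + 1
        running = max(running, 1.0 - (1.0 - p[idx]) ** (m - step))
        adjusted[idx] = min(1.0, running)
    return adjusted


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance
        return 1.0 if a[0] == b[0] else 0.0
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t.pvalue)


def compare_sites(
    profiles: Sequence[RetentionProfile],
    correction: str = "holm-sidak",
    equal_var: bool = True,
) -> pd.DataFrame:
    """All-pairs two-sided t-tests between sites, on replicate percentages.

    Student's equal-variance t by default (``equal_var=False`` for
    Welch); raw p-values are Holm-Sidak adjusted across the m = K(K-1)/2
    comparisons.  Two sites with identical constant replicate values
    compare at p = 1 by convention.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicate profiles")
    if correction not in ("holm-sidak", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    _check_same_sites(profiles)
    values = np.vstack([p.retained_top_percent for p in profiles])
    ranks = profiles[0].ranks
    pairs = list(itertools.combinations(range(len(ranks)), 2))
    raw = np.array(
        [_two_sample_t(values[:, i], values[:, j], equal_var) for i, j in pairs]
    )
    adjusted = holm_sidak(raw) if correction == "holm-sidak" else raw.copy()
    return pd.DataFrame(
        {
            "site_a": [int(ranks[i]) for i, _ in pairs],
            "site_b": [int(ranks[j]) for _, j in pairs],
            "mean_a": [values[:, i].mean() for i, _ in pairs],
            "mean_b": [values[:, j].mean() for _, j in pairs],
            "p_raw": raw,
            "p_adjusted": adjusted,
        }
    )


def polarity_index(summary: ProfileSummary) -> float:
    """Mean retention at rank 1 minus mean retention at the last rank.

    Positive under the wild-type-like polarity (top base retained near
    the Cdkn1A end, lost near the GFP end); shrinks toward 0 as the
    excision probabilities shrink.
    """
    if summary.ranks.size < 2:
        raise ValueError("polarity index needs >= 2 sites")
    return float(summary.mean[0] - summary.mean[-1])


# --------------------------------------------------------------------------
# model fitting


@dataclass
class FitResult:
    params: ResolutionParams
    residual_ss: float
    n_starts: int
    success: bool
    observed_percent: np.ndarray
    fitted_percent: np.ndarray


def _percentages(source) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(source, ProfileSummary):
        return source.mean, source.offsets
    if isinstance(source, RetentionProfile):
        return source.retained_top_percent, source.offsets
    raise TypeError("expected ProfileSummary or RetentionProfile")


def fit_resolution_model(
    summary: ProfileSummary | RetentionProfile,
    pair: RepeatPair,
    n_starts: int = 12,
    seed: int = 0,
) -> FitResult:
    """Recover ``ResolutionParams`` from an observed retention profile.

    Box-constrained least squares of the exclusive-policy closed form
    against observed mean percentages, over (pi_b, pi_t, theta_b,
    theta_t); multi-start (a fixed grid plus seeded random draws) guards
    against local minima.  Raises if every start fails.
    """
    observed_pct, offsets = _percentages(summary)
    mask = np.isfinite(observed_pct)
    if mask.sum() < 3:
        raise ValueError("need >= 3 informative sites to fit 4 parameters")
    y = observed_pct[mask] / 100.0
    off = offsets[mask].astype(float)
    length = float(len(pair))

    def residuals(x: np.ndarray) -> np.ndarray:
        pi_b, pi_t, th_b, th_t = x
        pred = 0.5 + (pi_b * th_b**off - pi_t * th_t ** (length - off - 1)) / 2.0
        return pred - y

    lo = np.array([0.0, 0.0, 1e-4, 1e-4])
    hi = np.array([1.0, 1.0, 1.0 - 1e-6, 1.0 - 1e-6])
    starts = [
        np.array([0.0, 0.0, 0.5, 0.5]),
        np.array([0.5, 0.5, 0.99, 0.99]),
        np.array([0.6, 0.6, 0.995, 0.995]),
        np.array([0.2, 0.2, 0.9, 0.9]),
        np.array([0.9, 0.9, 0.999, 0.999]),
    ]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    rng.uniform(0, 1),
                    rng.uniform(0, 1),
                    rng.uniform(0.8, 0.9999),
                    rng.uniform(0.8, 0.9999),
                ]
            )
        )

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[0]:
            best = (ss, sol)
    if best is None:
        raise RuntimeError("model fit failed to converge from any start")
    ss, sol = best
    pi_b, pi_t, th_b, th_t = sol.x
    params = ResolutionParams(
        pi_b=float(pi_b),
        pi_t=float(pi_t),
        theta_b=float(np.clip(th_b, 1e-9, 1 - 1e-9)),
        theta_t=float(np.clip(th_t, 1e-9, 1 - 1e-9)),
    )
    fitted = np.full_like(observed_pct, np.nan, dtype=float)
    fitted[mask] = (residuals(sol.x) + y) * 100.0
    return FitResult(
        params=params,
        residual_ss=ss,
        n_starts=len(starts),
        success=bool(sol.success),
        observed_percent=np.asarray(observed_pct, dtype=float),
        fitted_percent=fitted,
    )


def run_pipeline(
    reads,
    pair: RepeatPair,
    min_fraction: float = 0.001,
    config: AlignmentConfig | None = None,
    sample_id: str = "sample",
) -> RetentionProfile:
    """Convenience chain: collapse/filter -> align/call -> profile."""
    table = collapse_and_filter(reads, min_fraction=min_fraction, sample_id=sample_id)
    matrix = align_and_call(table, pair, config=config)
    return retention_profile(matrix)
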