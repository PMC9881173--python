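"""Generators for every input the analysis consumes, with known ground truth.

The centrepiece is a quantitative form of the nick-directed
heteroduplex-resolution model for single-strand annealing (SSA) between
divergent repeats.  After annealing, the two strands of the repeat
duplex derive from different repeats and are mismatched at each
divergent site; each DSB end is represented as a nick.  Mismatch repair
(MLH1-PMS2) incises the strand proximal to a DSB end, and the incised
strand is excised and resynthesized on the intact template, converting
every divergent site the excision tract reaches:

* with probability ``pi_b`` an excision tract starts on the *bottom*
  strand at the Cdkn1A-proximal nick; sites within its reach resolve to
  the TOP base;
* with probability ``pi_t`` a tract starts on the *top* strand at the
  GFP-proximal nick; sites within reach resolve to the BOTTOM base;
* tract lengths are geometric with per-nucleotide continuation
  probabilities ``theta_b`` / ``theta_t`` (memoryless, minimal
  one-parameter choice; the underlying biology constrains no particular
  distribution);
* sites reached by neither tract stay heteroduplex and segregate at
  replication: all of a molecule's unresolved sites jointly inherit TOP
  or BOTTOM with probability 1/2 (one daughter strand is sampled).

Under the default ``exclusive`` policy the two excision events are drawn
independently and a site covered by both tracts resolves by a fair
per-site coin, so at most one mechanism decides any given site.  This
admits any ``(pi_b, pi_t)`` in the unit square and gives the exact
closed form implemented by :func:`expected_retention`:

    p_top(i) = 1/2 + [pi_b * theta_b**offset_i
                      - pi_t * theta_t**(L - offset_i - 1)] / 2

The ``first-wins`` policy (Cdkn1A-side incision acts first and its
conversions are final) is provided for sensitivity analysis and is
Monte-Carlo only.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeat_model import DivergentSite, RepeatPair, detect_divergent_sites

_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i
_I2B = np.frombuffer(b"ACGT", dtype=np.uint8).copy()
_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP[_x] = _y

TOP, BOTTOM = "TOP", "BOTTOM"

POLICIES = ("exclusive", "first-wins")


@dataclass(frozen=True)
class ResolutionParams:
    """Parameters of the nick-directed resolution model.

    pi_b, pi_t
        Probabilities that the bottom-strand (Cdkn1A-proximal nick) and
        top-strand (GFP-proximal nick) excision events occur.
    theta_b, theta_t
        Per-nucleotide tract continuation probabilities; tract length is
        Geometric, ``P(L >= d) = theta**(d-1)``.
    policy
        ``exclusive`` (default; per-site exclusivity, closed form
        available) or ``first-wins`` (Cdkn1A-side tract applied first;
        Monte-Carlo only).
    """

    pi_b: float = 0.6
    pi_t: float = 0.6
    theta_b: float = 0.99
    theta_t: float = 0.99
    policy: str = "exclusive"

    def __post_init__(self) -> None:
        for name in ("pi_b", "pi_t"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("theta_b", "theta_t"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; expected one of {POLICIES}")

    def scaled(self, factor: float) -> "ResolutionParams":
        """Both excision probabilities scaled by ``factor`` (loss-of-function-like)."""
        return ResolutionParams(
            pi_b=self.pi_b * factor,
            pi_t=self.pi_t * factor,
            theta_b=self.theta_b,
            theta_t=self.theta_t,
            policy=self.policy,
        )


@dataclass
class ResolvedMolecule:
    """One RMD product molecule after heteroduplex resolution.

    ``sequence`` is the repeat window in top-strand orientation and
    agrees with ``truth_calls`` at every divergent site; sequencing
    errors are *not* present here (they belong to reads).
    """

    sequence: str
    truth_calls: tuple[str, ...]
    mechanism: str  # bottom_tract | top_tract | both_tracts | unresolved_segregation


@dataclass(frozen=True)
class ScreenMeasurement:
    """One reporter-assay well: raw GFP+ frequency with its parallel
    GFP-expression-vector transfection frequency."""

    gene: str
    assay: str
    replicate: int
    raw_gfp_freq: float
    transfection_gfp_freq: float
    is_control: bool = False


@dataclass(frozen=True)
class QPCRRecord:
    """Ct values for one qRT-PCR reaction (target gene vs ACTIN reference)."""

    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name}={v} must be positive and finite")


# --------------------------------------------------------------------------
# heteroduplex resolution


def _site_call_matrix(
    offsets: np.ndarray,
    length: int,
    params: ResolutionParams,
    n_molecules: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-site calls.

    Returns ``(top_mask, mechanism_code)`` where ``top_mask`` has shape
    (n_molecules, K) and is True where the site resolves TOP, and
    ``mechanism_code`` is 0=none, 1=bottom_tract, 2=top_tract, 3=both.
    """
    n, k = n_molecules, offsets.size
    has_b = rng.random(n) < params.pi_b
    tract_b = rng.geometric(1.0 - params.theta_b, size=n)
    has_t = rng.random(n) < params.pi_t
    tract_t = rng.geometric(1.0 - params.theta_t, size=n)
    seg_top = rng.random(n) < 0.5  # joint segregation coin per molecule
    coin = rng.random((n, k)) < 0.5  # per-site coin for doubly covered sites

    d_b = offsets + 1  # distance of each site from the Cdkn1A-proximal nick
    d_t = length - offsets  # distance from the GFP-proximal nick
    cov_b = has_b[:, None] & (tract_b[:, None] >= d_b[None, :])
    cov_t = has_t[:, None] & (tract_t[:, None] >= d_t[None, :])

    if params.policy == "first-wins":
        # Cdkn1A-side incision acts first; its conversions are final.
        cov_t &= ~cov_b
        top = np.where(cov_b, True, np.where(cov_t, False, seg_top[:, None]))
    else:
        both = cov_b & cov_t
        top = np.where(
            both, coin, np.where(cov_b, True, np.where(cov_t, False, seg_top[:, None]))
        )
    mech = has_b.astype(np.int8) + 2 * has_t.astype(np.int8)
    return top, mech


_MECH_NAMES = {0: "unresolved_segregation", 1: "bottom_tract", 2: "top_tract", 3: "both_tracts"}


def simulate_heteroduplex(
    pair: RepeatPair,
    params: ResolutionParams,
    n_molecules: int,
    seed: int = 0,
) -> list[ResolvedMolecule]:
    """Draw resolved RMD product molecules under the tract model.

    Deterministic under ``seed``.  Raises if the pair has no divergent
    sites (there is nothing to resolve).
    """
    sites = detect_divergent_sites(pair)
    if not sites:
        raise ValueError("no divergent sites to resolve")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    offsets = np.array([s.offset for s in sites])
    rng = np.random.default_rng(seed)
    top, mech = _site_call_matrix(offsets, len(pair), params, n_molecules, rng)

    top_u8 = np.frombuffer(pair.top_seq.encode(), dtype=np.uint8)
    bottom_bases = np.frombuffer(
        "".join(s.bottom_base for s in sites).encode(), dtype=np.uint8
    )
    seqs = np.tile(top_u8, (n_molecules, 1))
    rows, cols = np.nonzero(~top)
    seqs[rows, offsets[cols]] = bottom_bases[cols]
    flat = seqs.reshape(-1).view(f"S{len(pair)}")

    molecules = []
    for m in range(n_molecules):
        calls = tuple(TOP if t else BOTTOM for t in top[m])
        molecules.append(
            ResolvedMolecule(
                sequence=flat[m].decode(),
                truth_calls=calls,
                mechanism=_MECH_NAMES[int(mech[m])],
            )
        )
    return molecules


def expected_retention(pair: RepeatPair, params: ResolutionParams) -> np.ndarray:
    """Closed-form per-site probability of retaining the top-strand base.

    Valid under the ``exclusive`` policy only:
    ``p_top(i) = 1/2 + [pi_b c_b(i) - pi_t c_t(i)] / 2`` with
    ``c_b(i) = theta_b**offset_i`` (tract from the Cdkn1A-proximal nick
    reaches the site) and ``c_t(i) = theta_t**(L - offset_i - 1)``.
    """
    if params.policy != "exclusive":
        raise ValueError(
            f"no closed form for policy {params.policy!r}; use simulate_heteroduplex"
        )
    sites = detect_divergent_sites(pair)
    if not sites:
        raise ValueError("no divergent sites to resolve")
    offsets = np.array([s.offset for s in sites], dtype=float)
    c_b = params.theta_b ** offsets
    c_t = params.theta_t ** (len(pair) - offsets - 1)
    return 0.5 + (params.pi_b * c_b - params.pi_t * c_t) / 2.0


# --------------------------------------------------------------------------
# amplicon reads


def _phred_for(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, max(2, round(-10.0 * math.log10(error_rate))))


def generate_reads(
    molecules: Sequence[ResolvedMolecule],
    reads_per_molecule: int = 1,
    n_reads: int | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    rc_fraction: float = 0.0,
    flank_left: str = "",
    flank_right: str = "",
    indel_rate: float = 0.0,
) -> list[SeqRecord]:
    """Emulate amplicon deep sequencing of resolved molecules.

    Each read spans the full repeat window plus the given flanks, with
    i.i.d. substitution errors at ``error_rate`` and a ``rc_fraction``
    of reads emitted reverse-complemented.  Phred+33 qualities are
    constant and consistent with ``error_rate``.  ``n_reads`` samples
    molecules with replacement; otherwise each molecule yields
    ``reads_per_molecule`` reads.  ``indel_rate`` adds per-base
    deletions (exercises the gap-call path).
    """
    if not molecules:
        raise ValueError("empty molecule list")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    n_mol = len(molecules)
    width = len(flank_left) + len(molecules[0].sequence) + len(flank_right)

    mol_matrix = np.frombuffer(
        "".join(flank_left + m.sequence + flank_right for m in molecules).encode(),
        dtype=np.uint8,
    ).reshape(n_mol, width)

    if n_reads is not None:
        src = rng.integers(0, n_mol, size=n_reads)
    else:
        src = np.repeat(np.arange(n_mol), reads_per_molecule)
    reads = mol_matrix[src].copy()

    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        reads[err] = _I2B[(_B2I[reads[err]] + shift) % 4]

    rc = rng.random(reads.shape[0]) < rc_fraction
    if rc.any():
        reads[rc] = _COMP[reads[rc]][:, ::-1]

    seqs = [row.decode() for row in reads.reshape(-1).view(f"S{width}")]
    if indel_rate > 0:
        seqs = [
            "".join(c for c in s if rng.random() >= indel_rate) for s in seqs
        ]

    q = _phred_for(error_rate)
    records = []
    for i, (s, mol_idx, is_rc) in enumerate(zip(seqs, src, rc)):
        rec = SeqRecord(
            Seq(s),
            id=f"read{i}",
            description=f"mol={mol_idx} rc={int(is_rc)}",
        )
        rec.letter_annotations["phred_quality"] = [q] * len(s)
        records.append(rec)
    return records


def write_truth_table(
    molecules: Sequence[ResolvedMolecule], path: str | Path
) -> None:
    """Ground-truth sidecar CSV: molecule id, mechanism, per-site truth calls."""
    k = len(molecules[0].truth_calls) if molecules else 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule_id", "mechanism"] + [f"site_{i+1}" for i in range(k)])
        for i, m in enumerate(molecules):
            writer.writerow([i, m.mechanism, *m.truth_calls])


# --------------------------------------------------------------------------
# reporter screen and qPCR tables

DEFAULT_ASSAYS = ("identical:16bp", "identical:9.1kb", "1%:16bp", "1%:9.1kb")
CONTROL_GENE = "siCTRL"


def simulate_screen(
    effect_table: Mapping[str, float | Mapping[str, float]],
    n_replicates: int = 2,
    noise_cv: float = 0.1,
    seed: int = 0,
    assays: Sequence[str] = DEFAULT_ASSAYS,
    base_freq: float = 0.05,
    control_gene: str = CONTROL_GENE,
) -> list[ScreenMeasurement]:
    """Emulate the siRNA reporter screen (genes x assays x replicates).

    ``effect_table`` maps gene -> fold effect (scalar, or per-assay
    mapping).  The non-targeting control is added automatically with
    fold 1 and its expected normalized value is 1 by construction.
    Replicate noise is lognormal with coefficient of variation
    ``noise_cv`` (mean-corrected so the expectation equals the planted
    fold); each well carries its own parallel transfection frequency.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    genes = dict(effect_table)
    genes.setdefault(control_gene, 1.0)
    for gene, fold in genes.items():
        folds = fold.values() if isinstance(fold, Mapping) else [fold]
        if any(f <= 0 for f in folds):
            raise ValueError(f"fold effects must be > 0 (gene {gene})")

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    out: list[ScreenMeasurement] = []
    for gene in genes:
        for assay in assays:
            fold = genes[gene]
            if isinstance(fold, Mapping):
                fold = fold.get(assay, 1.0)
            for rep in range(1, n_replicates + 1):
                noise = (
                    math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                    if sigma > 0
                    else 1.0
                )
                value = base_freq * fold * noise
                transfection = rng.uniform(0.3, 0.6)
                out.append(
                    ScreenMeasurement(
                        gene=gene,
                        assay=assay,
                        replicate=rep,
                        raw_gfp_freq=min(value * transfection, transfection),
                        transfection_gfp_freq=transfection,
                        is_control=(gene == control_gene),
                    )
                )
    return out


def simulate_qpcr(
    expression_table: Mapping[str, float],
    control_condition: str = "siCTRL",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[QPCRRecord]:
    """Emulate a Ct table.  ``expression_table`` maps condition -> relative
    mRNA level (control = 1); knockdown to level x shifts the target Ct
    by ``-log2(x)`` cycles relative to the ACTIN reference."""
    if control_condition not in expression_table:
        expression_table = {control_condition: 1.0, **expression_table}
    rng = np.random.default_rng(seed)
    records = []
    for condition, level in expression_table.items():
        if level <= 0:
            raise ValueError(f"expression level must be > 0 (condition {condition})")
        for _ in range(n_replicates):
            ct_ref = 17.0 + rng.normal(0.0, noise_sd)
            ct_tgt = ct_ref + 6.0 - math.log2(level) + rng.normal(0.0, noise_sd)
            records.append(
                QPCRRecord(condition=condition, ct_target=ct_tgt, ct_reference=ct_ref)
            )
    return records
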