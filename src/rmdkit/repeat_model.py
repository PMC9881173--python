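"""Repeat pairs and their divergent sites.

The reporter construct carries two tandem 287-bp repeats; the 5' repeat
(adjacent to the *Cdkn1A* promoter) is sequenced as the top-strand
reference, and the 3' repeat (fused to GFP) may carry a small number of
equally spaced substitutions.  A position at which the two repeats differ
is a *divergent site*; sites are ranked 1..K starting from the
Cdkn1A-proximal end of the repeat.  The divergence classes used by the
assay are: identical (0 substitutions), 1% (3 substitutions in 287 bp)
and 3% (8 substitutions in 287 bp).

The actual reporter repeat sequence is not bundled; any user-supplied
FASTA pair is treated as authoritative, and :func:`random_repeat`
provides a deterministic seeded synthetic stand-in so the whole pipeline
is exercisable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

#: purine<->purine / pyrimidine<->pyrimidine substitution map
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: DSB/repeat distances used by the reporter panel
DSB_REPEAT_DISTANCES = ("16 bp", "1 kb", "3.3 kb", "9.1 kb", "19 kb", "28.4 kb")

#: divergence class -> number of substitutions in the 287-bp repeat
DIVERGENCE_CLASSES = {"identical": 0, "1%": 3, "3%": 8}


class RepeatValidationError(ValueError):
    """A repeat pair violates its structural invariants."""


@dataclass(frozen=True)
class DivergentSite:
    """A single mismatched position between the two repeats.

    rank
        1-based index ordered from the Cdkn1A-proximal end (rank 1 is the
        site closest to offset 0).
    offset
        0-based position within the repeat.
    top_base / bottom_base
        The base contributed by the Cdkn1A-side repeat (top strand, the
        sequencing reference) and by the GFP-side repeat respectively,
        both written in the reference orientation.
    """

    rank: int
    offset: int
    top_base: str
    bottom_base: str

    def __post_init__(self) -> None:
        if self.top_base == self.bottom_base:
            raise RepeatValidationError(
                f"site at offset {self.offset}: top and bottom base are both "
                f"{self.top_base!r}"
            )


def _validate_seq(seq: str, name: str) -> None:
    for i, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            raise RepeatValidationError(
                f"{name} contains non-ACGT character {base!r} at position {i}"
            )


@dataclass
class RepeatPair:
    """The two repeats, both written in the top-strand orientation.

    ``top_seq`` is the sequencing reference (Cdkn1A-side repeat);
    ``bottom_seq`` is the GFP-side repeat.  Positions at which the two
    differ define the divergent sites.
    """

    top_seq: str
    bottom_seq: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.top_seq) != len(self.bottom_seq):
            raise RepeatValidationError(
                f"repeat lengths differ: top {len(self.top_seq)} vs "
                f"bottom {len(self.bottom_seq)}"
            )
        _validate_seq(self.top_seq, "top_seq")
        _validate_seq(self.bottom_seq, "bottom_seq")

    def __len__(self) -> int:
        return len(self.top_seq)


@dataclass(frozen=True)
class ReporterConfig:
    """Geometry of one reporter assay variant.

    ``divergence_label`` is one of ``identical``, ``1%`` or ``3%`` and
    fixes the number of divergent sites (0, 3 or 8 in a 287-bp repeat);
    ``dsb_repeat_distance`` is the label of the Cas9 cut position
    upstream of the 3' repeat.
    """

    divergence_label: str = "identical"
    dsb_repeat_distance: str = "16 bp"
    repeat_length: int = 287

    def __post_init__(self) -> None:
        if self.divergence_label not in DIVERGENCE_CLASSES:
            raise RepeatValidationError(
                f"unknown divergence class {self.divergence_label!r}; "
                f"expected one of {sorted(DIVERGENCE_CLASSES)}"
            )
        if self.dsb_repeat_distance not in DSB_REPEAT_DISTANCES:
            raise RepeatValidationError(
                f"unknown DSB/repeat distance {self.dsb_repeat_distance!r}; "
                f"expected one of {DSB_REPEAT_DISTANCES}"
            )

    @property
    def n_mismatches(self) -> int:
        return DIVERGENCE_CLASSES[self.divergence_label]


def detect_divergent_sites(pair: RepeatPair) -> list[DivergentSite]:
    """Locate all mismatched positions between the two repeats.

    Returns one :class:`DivergentSite` per differing position, ranked
    1..K by increasing offset (rank 1 = Cdkn1A-proximal).  Identical
    sequences yield an empty list.
    """
    sites: list[DivergentSite] = []
    for offset, (t, b) in enumerate(zip(pair.top_seq, pair.bottom_seq)):
        if t != b:
            sites.append(
                DivergentSite(rank=len(sites) + 1, offset=offset, top_base=t, bottom_base=b)
            )
    return sites


def divergence_percent(n_sites: int, repeat_length: int) -> int:
    """Percent sequence divergence, rounded to the nearest integer.

    Eight substitutions in a 287-bp repeat give 3%; three give 1%.
    """
    if repeat_length <= 0:
        raise ValueError("repeat_length must be positive")
    if not 0 <= n_sites <= repeat_length:
        raise ValueError("n_sites must lie in [0, repeat_length]")
    # round half away from zero, rather than banker's rounding
    return int(np.floor(100.0 * n_sites / repeat_length + 0.5))


def equally_spaced_offsets(length: int, n: int) -> list[int]:
    """Centered equal partition: offsets floor((i - 0.5) * L / n), i = 1..n."""
    return [int(np.floor((i - 0.5) * length / n)) for i in range(1, n + 1)]


def construct_divergent_repeat(
    seq: str,
    n_mismatches: int,
    seed: int = 0,
    mode: str = "transition",
) -> RepeatPair:
    """Build a repeat pair by planting equally spaced substitutions in ``seq``.

    The returned pair has ``top_seq == seq`` and a ``bottom_seq`` that
    differs at exactly ``n_mismatches`` offsets placed by centered equal
    partitioning of the repeat.  Substitutions are transitions by default
    (``mode="transition"``); ``mode="transversion"`` picks one of the two
    transversions deterministically from ``seed``.
    """
    _validate_seq(seq, "seq")
    if n_mismatches > len(seq):
        raise ValueError(
            f"cannot place {n_mismatches} mismatches in a {len(seq)}-bp repeat"
        )
    if mode not in ("transition", "transversion"):
        raise ValueError(f"unknown substitution mode {mode!r}")
    bottom = list(seq)
    if n_mismatches > 0:
        rng = np.random.default_rng(seed)
        for offset in equally_spaced_offsets(len(seq), n_mismatches):
            base = seq[offset]
            if mode == "transition":
                bottom[offset] = TRANSITIONS[base]
            else:
                bottom[offset] = TRANSVERSIONS[base][rng.integers(0, 2)]
    label = f"synthetic pair: {n_mismatches} planted substitutions"
    return RepeatPair(top_seq=seq, bottom_seq="".join(bottom), label=label)


def random_repeat(length: int = 287, seed: int = 17) -> str:
    """Deterministic synthetic repeat sequence (uniform base composition)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def default_repeat_pair(
    divergence_label: str = "3%", length: int = 287, seed: int = 17
) -> RepeatPair:
    """The package's self-contained stand-in for the reporter repeat pair."""
    n = DIVERGENCE_CLASSES[divergence_label]
    pair = construct_divergent_repeat(random_repeat(length, seed), n, seed=seed)
    pair.label = f"synthetic {length}-bp repeat pair, {divergence_label} divergence"
    return pair


# --------------------------------------------------------------------------
# serialization

def write_repeat_pair(pair: RepeatPair, path: str | Path) -> None:
    """Write the pair as a two-record FASTA (ids ``top`` and ``bottom``)."""
    records = [
        SeqRecord(Seq(pair.top_seq), id="top", description=pair.label),
        SeqRecord(Seq(pair.bottom_seq), id="bottom", description=pair.label),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_repeat_pair(path: str | Path) -> RepeatPair:
    """Read a two-record FASTA pair; the first record is the top strand."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise RepeatValidationError(
            f"{path}: expected exactly 2 FASTA records (top, bottom), "
            f"found {len(records)}"
        )
    by_id = {r.id.lower(): str(r.seq).upper() for r in records}
    if {"top", "bottom"} <= set(by_id):
        top, bottom = by_id["top"], by_id["bottom"]
    else:
        top, bottom = (str(r.seq).upper() for r in records)
    return RepeatPair(top_seq=top, bottom_seq=bottom, label=records[0].description)


def sites_to_json(sites: Sequence[DivergentSite], path: str | Path | None = None) -> str:
    payload = json.dumps(
        [
            {
                "rank": s.rank,
                "offset": s.offset,
                "top_base": s.top_base,
                "bottom_base": s.bottom_base,
            }
            for s in sites
        ],
        indent=2,
    )
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def sites_from_json(source: str | Path) -> list[DivergentSite]:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return [DivergentSite(**entry) for entry in json.loads(text)]
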