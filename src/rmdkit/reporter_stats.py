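"""Reporter-assay arithmetic and screen statistics.

Every GFP+ repair frequency is divided by the GFP+ frequency of the
parallel GFP-expression-vector transfection for the same condition
(transfection-efficiency normalization), and siRNA experiments are
further scaled so the mean of the non-targeting control (siCTRL) is
exactly 1.  On top of that sit the screen triage rule (flag a gene if
any assay shows a >= 1.5-fold effect in either direction), the
divergent/identical frequency ratio, relative mRNA quantification by
2^-ddCt against an ACTIN reference, and the group-comparison tests used
throughout (one-way ANOVA with Tukey HSD, or pairwise t-tests with
Holm-Sidak correction).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .retention_pipeline import holm_sidak
from .synthetic_data import QPCRRecord, ScreenMeasurement

TRIAGE_THRESHOLD = 1.5


@dataclass(frozen=True)
class NormalizedFrequency:
    """One measurement after transfection-efficiency and control scaling."""

    gene: str
    assay: str
    replicate: int
    value: float  # raw GFP+ / parallel transfection GFP+
    control_scaled_value: float  # value / mean(control values); NaN if no controls
    is_control: bool


@dataclass(frozen=True)
class FoldEffect:
    """Mean control-scaled value for one gene x assay, with the gene-level
    triage flag (>= 1.5-fold effect in either direction, in any assay)."""

    gene: str
    assay: str
    fold: float
    direction: str  # "up" or "down"
    flagged: bool


def normalize_batch(measurements: Sequence[ScreenMeasurement]) -> list[NormalizedFrequency]:
    """Transfection-efficiency normalization plus siCTRL scaling.

    ``value = raw_gfp_freq / transfection_gfp_freq``;
    ``control_scaled_value = value / mean(control values)`` so the
    control-group mean is exactly 1 after scaling.  A batch is whatever
    list is passed in (callers group per transfection day).  With no
    control measurements, scaling is skipped with a warning and the
    scaled values are NaN.
    """
    if not measurements:
        raise ValueError("empty measurement batch")
    values = []
    for m in measurements:
        if m.transfection_gfp_freq <= 0:
            raise ValueError(
                f"transfection frequency must be > 0 "
                f"(gene {m.gene}, assay {m.assay}, replicate {m.replicate})"
            )
        values.append(m.raw_gfp_freq / m.transfection_gfp_freq)
    control_values = [v for v, m in zip(values, measurements) if m.is_control]
    if control_values:
        scale = float(np.mean(control_values))
        scaled = [v / scale for v in values]
    else:
        warnings.warn("no control measurements in batch; control scaling skipped")
        scaled = [math.nan] * len(values)
    return [
        NormalizedFrequency(
            gene=m.gene,
            assay=m.assay,
            replicate=m.replicate,
            value=v,
            control_scaled_value=s,
            is_control=m.is_control,
        )
        for m, v, s in zip(measurements, values, scaled)
    ]


def fold_effects_and_triage(
    normalized: Sequence[NormalizedFrequency],
    threshold: float = TRIAGE_THRESHOLD,
) -> list[FoldEffect]:
    """Per gene x assay fold effect (mean control-scaled value) and the
    inclusive triage rule: a gene is flagged if any assay fold is
    >= ``threshold`` or <= ``1/threshold``."""
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    folds: dict[tuple[str, str], list[float]] = {}
    for rec in normalized:
        folds.setdefault((rec.gene, rec.assay), []).append(rec.control_scaled_value)
    means = {key: float(np.mean(vals)) for key, vals in folds.items()}
    flagged_genes = set()
    for (gene, _), fold in means.items():
        if np.isfinite(fold) and (fold >= threshold or fold <= 1.0 / threshold):
            flagged_genes.add(gene)
    return [
        FoldEffect(
            gene=gene,
            assay=assay,
            fold=fold,
            direction="up" if fold >= 1.0 else "down",
            flagged=gene in flagged_genes,
        )
        for (gene, assay), fold in means.items()
    ]


def fold_effects_frame(effects: Sequence[FoldEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [e.gene for e in effects],
            "assay": [e.assay for e in effects],
            "fold": [e.fold for e in effects],
            "direction": [e.direction for e in effects],
            "flagged": [e.flagged for e in effects],
        }
    )


def divergent_identical_ratio(
    normalized: Sequence[NormalizedFrequency],
    divergent_label: str = "1%",
    identical_label: str = "identical",
) -> pd.DataFrame:
    """Ratio of divergent to identical repeat deletion frequencies.

    Assay labels follow the ``"<divergence>:<distance>"`` convention
    (e.g. ``"1%:9.1kb"``); for each gene and DSB/repeat distance the
    ratio of mean normalized values (divergent over identical) is
    reported.  A zero or missing denominator yields a NaN ratio with a
    status note.
    """
    cells: dict[tuple[str, str, str], list[float]] = {}
    for rec in normalized:
        variant, _, distance = rec.assay.partition(":")
        cells.setdefault((rec.gene, variant, distance), []).append(
            rec.control_scaled_value
        )
    rows = []
    genes = sorted({g for g, _, _ in cells})
    distances = sorted({d for _, _, d in cells})
    for gene in genes:
        for distance in distances:
            num = cells.get((gene, divergent_label, distance))
            den = cells.get((gene, identical_label, distance))
            if num is None or den is None:
                continue
            num_mean = float(np.mean(num))
            den_mean = float(np.mean(den))
            if den_mean == 0 or not np.isfinite(den_mean):
                ratio, status = math.nan, "zero or undefined denominator"
            else:
                ratio, status = num_mean / den_mean, "ok"
            rows.append(
                {
                    "gene": gene,
                    "distance": distance,
                    "divergent_mean": num_mean,
                    "identical_mean": den_mean,
                    "ratio": ratio,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


def delta_delta_ct(
    records: Sequence[QPCRRecord], control_condition: str = "siCTRL"
) -> pd.DataFrame:
    """Relative mRNA quantity per condition by 2^-ddCt.

    dCt = Ct(target) - Ct(ACTIN reference), averaged over reactions per
    condition; ddCt = dCt(condition) - dCt(control); the control
    condition is exactly 1.
    """
    dcts: dict[str, list[float]] = {}
    for rec in records:
        dcts.setdefault(rec.condition, []).append(rec.ct_target - rec.ct_reference)
    if control_condition not in dcts:
        raise ValueError(f"control condition {control_condition!r} not in records")
    control_dct = float(np.mean(dcts[control_condition]))
    rows = []
    for condition, values in dcts.items():
        ddct = float(np.mean(values)) - control_dct
        rows.append(
            {
                "condition": condition,
                "delta_ct": float(np.mean(values)),
                "delta_delta_ct": ddct,
                "relative_quantity": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group comparisons


def group_compare(
    groups: Mapping[str, Sequence[float]], method: str = "anova_tukey"
) -> pd.DataFrame:
    """All-pairs comparison of replicate groups.

    ``anova_tukey`` runs a one-way ANOVA F-test (p in
    ``result.attrs["anova_p"]``) followed by Tukey's HSD on the
    studentized-range distribution; ``t_holm_sidak`` runs all-pairs
    two-sided equal-variance t-tests with Holm-Sidak step-down
    adjustment.  Groups that are all one identical constant compare at
    p = 1 by convention.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has < 2 replicates")
    pairs = list(itertools.combinations(range(len(labels)), 2))
    degenerate = all(np.ptp(a) == 0 for a in arrays) and len(
        {a[0] for a in arrays}
    ) == 1

    if method == "anova_tukey":
        if degenerate:
            anova_p = 1.0
            pvals = np.ones(len(pairs))
        else:
            anova_p = float(stats.f_oneway(*arrays).pvalue)
            if not np.isfinite(anova_p):
                anova_p = 1.0
            hsd = stats.tukey_hsd(*arrays)
            pvals = np.array([float(hsd.pvalue[i, j]) for i, j in pairs])
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        out = pd.DataFrame(
            {
                "group_a": [labels[i] for i, _ in pairs],
                "group_b": [labels[j] for _, j in pairs],
                "p_adjusted": pvals,
            }
        )
        out.attrs["anova_p"] = anova_p
        return out
    if method == "t_holm_sidak":
        raw = []
        for i, j in pairs:
            a, b = arrays[i], arrays[j]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                raw.append(1.0 if a[0] == b[0] else 0.0)
            else:
                raw.append(float(stats.ttest_ind(a, b, equal_var=True).pvalue))
        raw = np.array(raw)
        return pd.DataFrame(
            {
                "group_a": [labels[i] for i, _ in pairs],
                "group_b": [labels[j] for _, j in pairs],
                "p_raw": raw,
                "p_adjusted": holm_sidak(raw),
            }
        )
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# CSV plumbing


def measurements_to_frame(measurements: Sequence[ScreenMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [m.gene for m in measurements],
            "assay": [m.assay for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "raw_gfp_freq": [m.raw_gfp_freq for m in measurements],
            "transfection_gfp_freq": [m.transfection_gfp_freq for m in measurements],
            "is_control": [m.is_control for m in measurements],
        }
    )


def frame_to_measurements(frame: pd.DataFrame) -> list[ScreenMeasurement]:
    return [
        ScreenMeasurement(
            gene=str(row.gene),
            assay=str(row.assay),
            replicate=int(row.replicate),
            raw_gfp_freq=float(row.raw_gfp_freq),
            transfection_gfp_freq=float(row.transfection_gfp_freq),
            is_control=bool(row.is_control),
        )
        for row in frame.itertuples(index=False)
    ]


def normalized_to_frame(normalized: Sequence[NormalizedFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [n.gene for n in normalized],
            "assay": [n.assay for n in normalized],
            "replicate": [n.replicate for n in normalized],
            "value": [n.value for n in normalized],
            "control_scaled_value": [n.control_scaled_value for n in normalized],
            "is_control": [n.is_control for n in normalized],
        }
    )
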