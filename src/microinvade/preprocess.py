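"""ASV-table cleanup: contaminant removal, curation, normalisation.

Two complementary contaminant screens are applied before any downstream
analysis, mirroring standard amplicon practice:

* a prevalence-based screen comparing detection frequency in sequencing
  negatives (kit / run controls) against true samples, scored with the
  one-sided exact hypergeometric tail probability for enrichment in the
  negatives; and
* a manual-style curation rule discarding any ASV whose mean relative
  abundance in the lab controls strictly exceeds its mean relative
  abundance in the remaining samples.

Also provides relative-abundance normalisation and analytic (hypergeometric
expectation) rarefaction curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import AsvCountTable, ConfigurationError, ValidationError


def presence_matrix(table: AsvCountTable, threshold: int = 1) -> np.ndarray:
    """Boolean detection matrix: count ≥ threshold.

    The default threshold of one read equates "identified" with presence in
    the ASV table.  Raising the threshold can only remove detections.
    """
    if threshold < 1:
        raise ValidationError("detection threshold must be >= 1")
    return table.counts >= threshold


@dataclass
class ContaminantReport:
    """Per-ASV outcome of the prevalence-based contaminant screen."""

    asv_id: str
    prevalence_in_negatives: float
    prevalence_in_samples: float
    score: float
    is_contaminant: bool


def hypergeometric_enrichment_score(
    k_neg: int, n_neg: int, k_true: int, n_true: int
) -> float:
    """P(X ≥ k_neg) for X ~ Hypergeom(n_neg + n_true, k_neg + k_true, n_neg).

    The probability, under random allocation of the ASV's detections across
    all samples, of seeing at least as many detections in the negatives as
    observed — a one-sided exact test for enrichment in negatives.
    """
    total = n_neg + n_true
    detected = k_neg + k_true
    return float(hypergeom.sf(k_neg - 1, total, detected, n_neg))


def prevalence_contaminant_filter(
    table: AsvCountTable,
    negative_ids: Iterable[str],
    score_threshold: float = 0.1,
    detection_threshold: int = 1,
) -> list[ContaminantReport]:
    """Prevalence-mode contaminant identification.

    An ASV is flagged when its enrichment score in the negatives is below
    ``score_threshold`` *and* its detection prevalence is higher in the
    negatives than in true samples.  ASVs detected only in negatives are
    contaminants regardless of score.
    """
    negative_ids = set(negative_ids)
    if not negative_ids:
        raise ConfigurationError("contaminant filter requires >= 1 negative sample")
    unknown = negative_ids - set(table.sample_ids)
    if unknown:
        raise ConfigurationError(
            f"negative sample id(s) not in table: {', '.join(sorted(unknown))}"
        )
    neg_mask = np.array([s in negative_ids for s in table.sample_ids])
    if neg_mask.all():
        raise ConfigurationError("contaminant filter requires >= 1 true sample")
    present = presence_matrix(table, detection_threshold)
    n_neg = int(neg_mask.sum())
    n_true = int((~neg_mask).sum())
    k_neg = present[:, neg_mask].sum(axis=1)
    k_true = present[:, ~neg_mask].sum(axis=1)
    reports = []
    for i, asv in enumerate(table.asv_ids):
        prev_neg = k_neg[i] / n_neg
        prev_true = k_true[i] / n_true
        score = hypergeometric_enrichment_score(
            int(k_neg[i]), n_neg, int(k_true[i]), n_true
        )
        negatives_only = k_neg[i] > 0 and k_true[i] == 0
        flagged = negatives_only or (score < score_threshold and prev_neg > prev_true)
        reports.append(
            ContaminantReport(asv, prev_neg, prev_true, score, bool(flagged))
        )
    return reports


def control_abundance_curation(
    table: AsvCountTable, lab_control_ids: Iterable[str]
) -> tuple[AsvCountTable, list[str]]:
    """Discard ASVs more abundant (mean relative abundance) in lab controls.

    Mean relative abundance — rather than raw counts — makes the rule robust
    to sequencing-depth differences between controls and real samples.
    """
    lab_control_ids = set(lab_control_ids)
    if not lab_control_ids:
        raise ConfigurationError("curation requires >= 1 lab-control sample")
    ctrl_mask = np.array([s in lab_control_ids for s in table.sample_ids])
    if not ctrl_mask.any():
        raise ConfigurationError("no lab-control sample ids found in table")
    if ctrl_mask.all():
        raise ConfigurationError("curation requires >= 1 non-control sample")
    rel = relative_abundance(table)
    mean_ctrl = rel[:, ctrl_mask].mean(axis=1)
    mean_other = rel[:, ~ctrl_mask].mean(axis=1)
    discard = [
        asv for i, asv in enumerate(table.asv_ids) if mean_ctrl[i] > mean_other[i]
    ]
    return table.drop_asvs(discard), discard


def relative_abundance(table: AsvCountTable) -> np.ndarray:
    """Column-normalised abundances; every sample sums to 1."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    return table.counts / totals


def rarefaction_curve(
    sample_counts: Sequence[int], depths: Sequence[int]
) -> np.ndarray:
    """Expected richness when subsampling to each depth, without replacement.

    E[S(d)] = Σ_i [1 − C(N−N_i, d) / C(N, d)], the hypergeometric expectation
    of the number of taxa with at least one read in a random subsample of
    size d.  Exact — no resampling noise — and non-decreasing in d.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        raise ValidationError("sample has zero total count")
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > total).any():
        raise ValidationError(f"depth exceeds sample total {total}")
    if (depths < 1).any():
        raise ValidationError("depths must be >= 1")
    nonzero = counts[counts > 0]
    out = np.empty(len(depths), dtype=float)
    for j, d in enumerate(depths):
        # P(taxon i absent from subsample) = C(N - N_i, d) / C(N, d)
        absent = np.array(
            [_comb_ratio(total - int(ni), total, int(d)) for ni in nonzero]
        )
        out[j] = float(np.sum(1.0 - absent))
    return out


def _comb_ratio(m: int, n: int, d: int) -> float:
    """C(m, d) / C(n, d) computed stably in log space (0 when d > m)."""
    if d > m:
        return 0.0
    from scipy.special import gammaln

    log_ratio = (
        gammaln(m + 1)
        - gammaln(m - d + 1)
        - gammaln(n + 1)
        + gammaln(n - d + 1)
    )
    return float(np.exp(log_ratio))
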