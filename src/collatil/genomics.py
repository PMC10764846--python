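"""Somatic-mutation curation, ssGSEA activity index, and gene selection.

Mutation calls are classified synonymous (Wt) vs non-synonymous (Mut) from
their variant annotations, filtered on read depth and allele frequency, and
cohorts are purged of hypermutated samples by a Tukey-style IQR rule on
per-sample mutation counts.  The ssGSEA activity index scores one gene set
in one sample by the running-sum difference between the weighted in-set and
uniform out-of-set rank CDFs.  Gene selection combines Pearson correlation
with the model's risk score and externally computed differential-expression
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, GeneSet, MafRecord

logger = logging.getLogger(__name__)

# annotations marking a call non-synonymous (Mut) vs synonymous (Wt);
# both MC3 column dialects and plain-English names are accepted
_NONSYNONYMOUS = {
    "missense", "missense_mutation",
    "frame_shift_del", "frame shift deletion", "frame_shift_deletion",
    "nonsense", "nonsense_mutation",
    "in_frame_del", "inframe deletion", "in_frame_deletion", "inframe_del",
    "in_frame_ins", "inframe insertion", "in_frame_insertion", "inframe_ins",
    "splice_site", "splice site",
    "frame_shift_ins", "frame shift insertion", "frame_shift_insertion",
    "translation_start_site", "translation start site",
    "nonstop_mutation", "nonstop",
}
_SYNONYMOUS = {
    "silent", "3'utr", "rna", "intron", "3'flank", "5'utr", "5'flank",
}

# depth/VAF retention rules; equality passes (strict "less than"/"greater than")
MIN_DEPTH = 30
MIN_TUMOR_VAF = 0.10
MAX_NORMAL_VAF = 0.05


@dataclass
class MutationCallSet:
    """Filtered mutation records with per-sample counts and exclusions."""

    records: list[MafRecord]
    sample_counts: dict[str, int]
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def retained_records(self) -> list[MafRecord]:
        return [r for r in self.records if r.sample_id not in self.excluded_samples]


@dataclass(frozen=True)
class ActivityIndex:
    sample_id: str
    gene_set_name: str
    score: float
    exponent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("activity index must be finite")


def _normalize_annotation(s: str) -> str:
    # tolerate Unicode primes and spacing differences across MAF dialects
    return (s.replace("′", "'").replace("ʹ", "'")
            .strip().lower().replace("-", "_"))


def classify_variant(annotations: Sequence[str]) -> str:
    """'Mut' if ANY annotation is non-synonymous, 'Wt' if all are synonymous.

    Unrecognized classification strings raise (no silent dropping).
    """
    if not annotations:
        raise ValueError("need >= 1 annotation")
    norm = [_normalize_annotation(a) for a in annotations]
    unknown = [a for a, n in zip(annotations, norm)
               if n not in _NONSYNONYMOUS and n not in _SYNONYMOUS]
    if unknown:
        raise ValueError(f"unrecognized variant classifications: {unknown}")
    return "Mut" if any(n in _NONSYNONYMOUS for n in norm) else "Wt"


def filter_mutations(records: Sequence[MafRecord]
                     ) -> tuple[list[MafRecord], list[tuple[MafRecord, str]]]:
    """Depth/VAF artifact filter.

    A record is removed iff tumor depth < 30, normal depth < 30, tumor VAF
    < 0.1, or normal VAF > 0.05; boundary values are retained.  Returns
    (retained, removed-with-reason).
    """
    retained, removed = [], []
    for r in records:
        if r.t_depth < MIN_DEPTH:
            removed.append((r, f"t_depth {r.t_depth} < {MIN_DEPTH}"))
        elif r.n_depth < MIN_DEPTH:
            removed.append((r, f"n_depth {r.n_depth} < {MIN_DEPTH}"))
        elif r.t_vaf < MIN_TUMOR_VAF:
            removed.append((r, f"t_vaf {r.t_vaf:.3f} < {MIN_TUMOR_VAF}"))
        elif r.n_vaf > MAX_NORMAL_VAF:
            removed.append((r, f"n_vaf {r.n_vaf:.3f} > {MAX_NORMAL_VAF}"))
        else:
            retained.append(r)
    logger.info("mutation filter: retained %d / removed %d records",
                len(retained), len(removed))
    return retained, removed


def detect_hypermutated(sample_counts: Mapping[str, int],
                        quantile_method: str = "linear") -> set[str]:
    """Samples whose mutation count exceeds Q3 + 1.5*IQR of the cohort.

    Quartiles use linear interpolation between order statistics by default.
    Cohorts of fewer than 4 samples are left untouched with a warning.
    """
    if len(sample_counts) < 4:
        logger.warning("cohort of %d samples too small for hypermutation "
                       "detection; no exclusion", len(sample_counts))
        return set()
    counts = np.array(list(sample_counts.values()), dtype=float)
    q1, q3 = np.percentile(counts, [25, 75], method=quantile_method)
    cutoff = q3 + 1.5 * (q3 - q1)
    excluded = {s for s, c in sample_counts.items() if c > cutoff}
    if excluded:
        logger.info("hypermutated (count > %.1f): %s", cutoff, sorted(excluded))
    return excluded


def build_callset(records: Sequence[MafRecord],
                  count_after_filter: bool = True) -> MutationCallSet:
    """Filter records, count mutations per sample, and flag hypermutated
    samples (counts taken after the depth/VAF filter by default)."""
    retained, _ = filter_mutations(records)
    basis = retained if count_after_filter else list(records)
    counts: dict[str, int] = {}
    for r in basis:
        counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    excluded = {s: "hypermutated" for s in detect_hypermutated(counts)}
    return MutationCallSet(records=retained, sample_counts=counts,
                           excluded_samples=excluded)


def gene_mutation_groups(callset: MutationCallSet, gene: str,
                         samples: Iterable[str] | None = None) -> dict[str, str]:
    """Per-sample Mut/Wt status for one gene over retained records.

    A sample is Mut iff it retains >= 1 record for the gene whose
    annotations classify non-synonymous.
    """
    records = callset.retained_records()
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    status = {s: "Wt" for s in samples}
    gene_records = [r for r in records if r.gene == gene]
    if not gene_records:
        logger.warning("gene %s absent from retained records; all samples Wt", gene)
    for r in gene_records:
        if r.sample_id in status and classify_variant(r.variant_classifications) == "Mut":
            status[r.sample_id] = "Mut"
    return status


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_score(expression: pd.Series, gene_set: GeneSet,
                 exponent: float = 0.25) -> ActivityIndex:
    """Single-sample GSEA activity index of one gene set in one sample.

    Genes are ranked by descending expression (ties broken by gene symbol).
    With rank-normalized values z_i = N, N-1, ..., 1 down the ranking, the
    in-set running CDF weights each member by z_i**exponent while the
    out-of-set CDF is uniform; the score is the running-sum difference
    integrated over the ranking, divided by N so values are comparable
    across gene-set sizes.  exponent = 0 gives the unweighted (rank-only)
    statistic.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    expression = expression.dropna()
    n = len(expression)
    in_set = expression.index.isin(gene_set.genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no members of {gene_set.name!r} present in the profile")
    if n_in == n:
        raise ValueError(f"gene set {gene_set.name!r} covers every profiled gene; "
                         "the out-of-set CDF is undefined")
    order = sorted(range(n), key=lambda i: (-expression.iloc[i], expression.index[i]))
    in_sorted = np.asarray(in_set)[order]
    z = np.arange(n, 0, -1, dtype=float)  # rank-normalized expression
    w = np.where(in_sorted, z ** exponent, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~in_sorted) / (n - n_in)
    score = float((cdf_in - cdf_out).sum() / n)
    return ActivityIndex(sample_id=str(expression.name), gene_set_name=gene_set.name,
                         score=score, exponent=exponent)


def ssgsea_matrix(expr: ExpressionMatrix, gene_sets: Sequence[GeneSet],
                  exponent: float = 0.25) -> pd.DataFrame:
    """Activity indices for every (sample, gene set); sets x samples frame."""
    frame = expr.to_frame()
    return pd.DataFrame(
        {s: [ssgsea_score(frame[s], gs, exponent).score for gs in gene_sets]
         for s in expr.samples},
        index=[gs.name for gs in gene_sets])


# ---------------------------------------------------------------------------
# gene selection


def select_risk_correlated_genes(expr: ExpressionMatrix,
                                 risk_scores: Mapping[str, float],
                                 p_threshold: float = 0.05) -> list[str]:
    """Genes whose expression correlates with the continuous risk score
    (two-sided Pearson p below threshold) over the shared samples."""
    shared = [s for s in expr.samples if s in risk_scores]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    frame = expr.to_frame()[shared]
    risk = np.array([risk_scores[s] for s in shared], dtype=float)
    selected = []
    for gene, row in frame.iterrows():
        values = row.to_numpy(dtype=float)
        if np.all(values == values[0]):
            logger.warning("constant expression for %s; skipped", gene)
            continue
        _, p = stats.pearsonr(values, risk)
        if p < p_threshold:
            selected.append(str(gene))
    return selected


def apply_de_thresholds(de_table: pd.DataFrame, fdr_threshold: float = 0.05,
                        log2fc_threshold: float = 1.0) -> list[str]:
    """Genes passing fdr < threshold AND |log2fc| > threshold (both strict)."""
    missing = {"gene", "log2fc", "fdr"} - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    mask = (de_table["fdr"] < fdr_threshold) & (de_table["log2fc"].abs() > log2fc_threshold)
    return [str(g) for g in de_table.loc[mask, "gene"]]
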