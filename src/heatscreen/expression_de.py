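"""Expression quantities and the differential-expression threshold filter.

Implements the expression arithmetic used around the screening study:

* FPKM — fragments per kilobase of transcript per million mapped fragments,
  ``FPKM_gs = counts_gs · 10^9 / (length_g · total_counts_s)``;
* log2 fold change between group means with a shared pseudocount;
* the DEG call — a gene passes iff ``|log2FC| ≥ 1.4`` AND ``p ≤ 0.05``,
  both boundaries inclusive, direction by the sign of log2FC;
* 2^−ΔΔCt relative quantification for qPCR validation, and the direction
  concordance between qPCR ratios and RNA-seq fold changes.

Per-gene p-values may be supplied from an external DE tool; the internal
default is a two-sided pooled-variance t-test on log2(FPKM + ε) per gene,
which is adequate at bench scale. No multiple-testing correction is applied
to the DE p-values — the filter is a raw-p rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EmptyInputError, IncompleteRecordError, ShapeError

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "log2_fold_change",
    "gene_ttests",
    "de_filter",
    "differential_expression",
    "ddct_ratio",
    "qpcr_ratios_by_gene",
    "concordance",
    "LFC_THRESHOLD",
    "P_THRESHOLD",
]

log = logging.getLogger(__name__)

LFC_THRESHOLD = 1.4
P_THRESHOLD = 0.05

DEFAULT_PSEUDOCOUNT_COUNTS = 1.0
DEFAULT_PSEUDOCOUNT_FPKM = 0.01


@dataclass(frozen=True)
class ExpressionMatrix:
    """Raw counts (genes × samples) with gene lengths and group labels."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]          # one label per sample, e.g. HT / NHT
    counts: np.ndarray               # (n_genes, n_samples), non-negative
    lengths: np.ndarray              # bp, per gene
    p_values: np.ndarray | None = field(default=None)  # optional external p

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "groups", tuple(self.groups))
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ShapeError("one group label required per sample")
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        if lengths.shape != (len(self.gene_ids),) or np.any(lengths <= 0):
            raise DomainError("gene lengths must be positive, one per gene")
        if self.p_values is not None:
            p = np.asarray(self.p_values, dtype=float)
            object.__setattr__(self, "p_values", p)
            if p.shape != (len(self.gene_ids),):
                raise ShapeError("external p-values must be one per gene")

    def group_columns(self, label: str) -> np.ndarray:
        cols = np.flatnonzero(np.asarray(self.groups) == label)
        if cols.size == 0:
            raise DomainError(f"no samples in group {label!r}")
        return cols


def fpkm(counts, lengths) -> np.ndarray:
    """FPKM matrix from raw fragment counts and gene lengths (bp)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    if np.any(lengths <= 0):
        raise DomainError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise DomainError("zero library size: a sample has no counts")
    return counts * 1e9 / (lengths[:, None] * totals[None, :])


def log2_fold_change(expr_a, expr_b, pseudocount: float = DEFAULT_PSEUDOCOUNT_FPKM):
    """log2((mean_A + ε) / (mean_B + ε)) per gene.

    ``expr_a`` / ``expr_b`` are per-group expression values: 1-D group means
    or 2-D genes × samples matrices (means taken over samples). The same
    pseudocount ε applies to both groups; defaults suit FPKM-scale values
    (use ε = 1 on raw counts).
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.ndim == 2:
        a = a.mean(axis=1)
    if b.ndim == 2:
        b = b.mean(axis=1)
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("expression values must be non-negative")
    if pseudocount <= 0:
        raise DomainError("pseudocount must be positive")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return float(out) if out.ndim == 0 else out


def gene_ttests(expr_a: np.ndarray, expr_b: np.ndarray,
                pseudocount: float = DEFAULT_PSEUDOCOUNT_FPKM) -> np.ndarray:
    """Vectorised two-sided pooled t-test on log2(expr + ε), per gene.

    Genes with zero pooled variance get p = NaN (flagged downstream as ns).
    """
    a = np.log2(np.asarray(expr_a, dtype=float) + pseudocount)
    b = np.log2(np.asarray(expr_b, dtype=float) + pseudocount)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise DomainError("need at least 2 samples per group for the t-test")
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        t = (a.mean(axis=1) - b.mean(axis=1)) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = np.nan
    return p


def de_filter(log2fc, p_values, gene_ids=None,
              lfc_threshold: float = LFC_THRESHOLD,
              p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Apply the DEG rule: pass iff |log2FC| ≥ threshold AND p ≤ threshold.

    Both boundaries are inclusive. Genes with NaN fold change or p-value are
    marked ``ns`` with a logged warning, never silently passed. Returns a
    frame with columns ``gene_id``, ``log2fc``, ``p``, ``passes_filter``,
    ``direction`` (``up`` | ``down`` | ``ns``); direction is relative to the
    first (numerator) group.
    """
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if lfc.shape != p.shape:
        raise ShapeError("log2FC and p-value vectors differ in length")
    valid = np.isfinite(lfc) & np.isfinite(p)
    if np.any(np.isfinite(p) & ((p < 0) | (p > 1))):
        raise DomainError("p-values must lie in [0, 1]")
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%d gene(s) with NaN log2FC or p-value marked ns", n_bad)

    passes = valid & (np.abs(lfc) >= lfc_threshold) & (p <= p_threshold)
    direction = np.full(lfc.shape, "ns", dtype=object)
    direction[passes & (lfc > 0)] = "up"
    direction[passes & (lfc < 0)] = "down"
    # |log2FC| ≥ threshold > 0 excludes lfc == 0 from passing by construction
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(lfc.size)]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": lfc,
            "p": p,
            "passes_filter": passes,
            "direction": direction,
        }
    )


def differential_expression(
    expr: ExpressionMatrix,
    group_a: str = "HT",
    group_b: str = "NHT",
    pseudocount: float = DEFAULT_PSEUDOCOUNT_FPKM,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """FPKM → log2FC(group_a vs group_b) → p-values → DEG filter.

    External per-gene p-values on the matrix take precedence over the
    internal log2-FPKM t-test.
    """
    f = fpkm(expr.counts, expr.lengths)
    fa = f[:, expr.group_columns(group_a)]
    fb = f[:, expr.group_columns(group_b)]
    lfc = log2_fold_change(fa, fb, pseudocount=pseudocount)
    if expr.p_values is not None:
        p = expr.p_values
    else:
        p = gene_ttests(fa, fb, pseudocount=pseudocount)
    table = de_filter(lfc, p, gene_ids=expr.gene_ids,
                      lfc_threshold=lfc_threshold, p_threshold=p_threshold)
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    log.info("%d DEGs (%d down, %d up) of %d genes",
             n_up + n_down, n_down, n_up, len(table))
    return table


def ddct_ratio(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """2^−ΔΔCt relative expression per sample, calibrated to one group.

    ``records`` needs columns ``sample_id``, ``group``, ``ct_target``,
    ``ct_reference`` (the normaliser gene's Ct, e.g. GAPDH). Per sample,
    ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator group's
    mean ΔCt; relative expression is 2^−ΔΔCt. Adding a constant to every Ct
    leaves all ratios unchanged (ΔCt is shift-invariant).
    """
    need = {"sample_id", "group", "ct_target", "ct_reference"}
    if not need <= set(records.columns):
        raise DomainError(f"qPCR records need columns {sorted(need)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        bad = records.loc[
            records[["ct_target", "ct_reference"]].isna().any(axis=1), "sample_id"
        ].tolist()
        raise IncompleteRecordError(f"missing Ct value(s) for sample(s) {bad}")
    ct_t = records["ct_target"].to_numpy(dtype=float)
    ct_r = records["ct_reference"].to_numpy(dtype=float)
    if np.any(ct_t <= 0) or np.any(ct_r <= 0) or not (
        np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))
    ):
        raise DomainError("Ct values must be finite and positive")
    dct = ct_t - ct_r
    cal = records["group"].to_numpy() == calibrator
    if not cal.any():
        raise DomainError(f"calibrator group {calibrator!r} is empty")
    ddct = dct - dct[cal].mean()
    out = records[["sample_id", "group"]].copy()
    out["delta_ct"] = dct
    out["delta_delta_ct"] = ddct
    out["relative_expression"] = 2.0 ** (-ddct)
    return out


def qpcr_ratios_by_gene(records: pd.DataFrame, test_group: str = "HT",
                        calibrator: str = "NHT") -> pd.DataFrame:
    """Per-gene relative-expression ratio (test over calibrator group).

    ``records`` is a long frame with a ``gene_id`` column plus the
    :func:`ddct_ratio` columns; each gene's samples are calibrated to the
    calibrator group, then the ratio of group-mean relative expressions is
    taken (the calibrator mean is 2^0-centred by construction).
    """
    if "gene_id" not in records.columns:
        raise DomainError("qPCR records need a gene_id column")
    rows = []
    for gene, sub in records.groupby("gene_id", sort=True):
        rel = ddct_ratio(sub, calibrator=calibrator)
        mean_test = rel.loc[rel["group"] == test_group, "relative_expression"].mean()
        mean_cal = rel.loc[rel["group"] == calibrator, "relative_expression"].mean()
        if not np.isfinite(mean_test):
            raise DomainError(f"gene {gene!r}: no samples in group {test_group!r}")
        rows.append({"gene_id": gene, "ratio": mean_test / mean_cal})
    return pd.DataFrame(rows)


def concordance(deg_table: pd.DataFrame, qpcr_ratios: pd.DataFrame) -> float:
    """Fraction of shared genes whose RNA-seq log2FC sign matches qPCR.

    ``qpcr_ratios`` needs columns ``gene_id`` and ``ratio`` (test group over
    calibrator group relative expression); agreement compares sign(log2FC)
    with sign(log2 ratio).
    """
    need = {"gene_id", "ratio"}
    if not need <= set(qpcr_ratios.columns):
        raise DomainError(f"qPCR ratio table needs columns {sorted(need)}")
    merged = deg_table.merge(qpcr_ratios, on="gene_id", how="inner")
    if merged.empty:
        raise EmptyInputError("no genes shared between RNA-seq and qPCR tables")
    if np.any(merged["ratio"].to_numpy(dtype=float) <= 0):
        raise DomainError("qPCR ratios must be positive")
    seq_sign = np.sign(merged["log2fc"].to_numpy(dtype=float))
    qpcr_sign = np.sign(np.log2(merged["ratio"].to_numpy(dtype=float)))
    return float((seq_sign == qpcr_sign).mean())
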