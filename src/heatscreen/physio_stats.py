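"""Physiological index summaries, group contrasts and ELISA quality checks.

Covers the descriptive arithmetic around the screening: per-cow milk-yield
decline between the thermoneutral and heat months, two-sample Student's
t contrasts between the HT and NHT extremes with Bonferroni adjustment
over an explicit index family, and coefficient-of-variation checks for
ELISA plasma assays (intra-assay CV < 10%, inter-assay CV < 15%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, DomainError, EmptyInputError
from .tolerance_screen import IndexMatrix

__all__ = [
    "GroupContrast",
    "ElisaQCReport",
    "milk_yield_change",
    "group_ttest",
    "bonferroni_adjust",
    "elisa_cv_check",
    "group_contrasts",
    "contrasts_to_frame",
    "index_matrix_from_phenotypes",
]

INTRA_ASSAY_CV_LIMIT = 10.0  # percent
INTER_ASSAY_CV_LIMIT = 15.0  # percent


@dataclass(frozen=True)
class GroupContrast:
    """One index's HT-vs-NHT contrast in Table-1 style (mean ± SEM)."""

    index: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    p_adjusted: float
    significant: bool  # adjusted p < 0.05


@dataclass(frozen=True)
class ElisaQCReport:
    """Coefficient-of-variation QC for one analyte."""

    analyte: str
    intra_cv: tuple[float, ...]  # percent, one per replicate group
    inter_cv: float | None       # percent, across assay runs
    intra_pass: bool
    inter_pass: bool | None

    @property
    def passed(self) -> bool:
        return self.intra_pass and (self.inter_pass is not False)


def milk_yield_change(june, august) -> float:
    """Mean daily yield in the thermoneutral month minus the heat month.

    Positive values are a decline under heat stress.
    """
    june = np.asarray(june, dtype=float)
    august = np.asarray(august, dtype=float)
    if june.size == 0 or august.size == 0:
        raise EmptyInputError("both yield periods must be non-empty")
    if np.any(june < 0) or np.any(august < 0):
        raise DomainError("daily milk yields must be non-negative")
    return float(june.mean() - august.mean())


def group_ttest(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    Returns ``(t, p)`` with df = n_a + n_b − 2 in the pooled case. Welch's
    unequal-variance variant is available by flag but the pooled test is the
    default since group variances are assumed comparable at n = 3.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateVarianceError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bonferroni_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``p_adj = min(1, m·p)``.

    ``family_size`` (m) defaults to the number of p-values given; it is an
    explicit parameter because the family is a modelling decision, never
    inferred from however many tests happen to be in hand.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise EmptyInputError("no p-values supplied")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < 1:
        raise DomainError("family size must be at least 1")
    return np.minimum(1.0, m * p)


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise DomainError("CV undefined: mean of replicates is zero")
    return float(100.0 * values.std(ddof=1) / mean)


def elisa_cv_check(
    intra_replicates: Sequence[Sequence[float]],
    inter_runs: Sequence[float] | None = None,
    analyte: str = "",
) -> ElisaQCReport:
    """Flag an assay's precision against the 10% / 15% CV thresholds.

    Parameters
    ----------
    intra_replicates
        Groups of replicate wells measured within one assay run; each group
        needs ≥ 2 wells. Intra-assay CV is computed per group and every
        group must stay below 10%.
    inter_runs
        Per-run summary values across ≥ 2 independent assay runs; their CV
        must stay below 15%. Optional.
    """
    intra = []
    for grp in intra_replicates:
        arr = np.asarray(grp, dtype=float)
        if arr.size < 2:
            raise DomainError("intra-assay groups need at least 2 replicates")
        intra.append(_cv_percent(arr))
    if not intra:
        raise EmptyInputError("no intra-assay replicate groups supplied")

    inter_cv: float | None = None
    inter_pass: bool | None = None
    if inter_runs is not None:
        runs = np.asarray(inter_runs, dtype=float)
        if runs.size < 2:
            raise DomainError("inter-assay CV needs at least 2 assay runs")
        inter_cv = _cv_percent(runs)
        inter_pass = inter_cv < INTER_ASSAY_CV_LIMIT

    return ElisaQCReport(
        analyte=analyte,
        intra_cv=tuple(intra),
        inter_cv=inter_cv,
        intra_pass=all(cv < INTRA_ASSAY_CV_LIMIT for cv in intra),
        inter_pass=inter_pass,
    )


def group_contrasts(
    values: Mapping[str, tuple[Sequence[float], Sequence[float]]] | pd.DataFrame,
    family_size: int | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> list[GroupContrast]:
    """Student's t per index between two groups, Bonferroni-adjusted.

    ``values`` maps index name → (group A values, group B values), or is a
    long-format frame with columns ``index``, ``group``, ``value`` holding
    exactly two group labels. The Bonferroni family defaults to the number
    of indexes jointly tested.
    """
    if isinstance(values, pd.DataFrame):
        need = {"index", "group", "value"}
        if not need <= set(values.columns):
            raise DomainError(f"long-format contrasts need columns {sorted(need)}")
        groups = sorted(values["group"].unique())
        if len(groups) != 2:
            raise DomainError(f"expected exactly 2 groups, found {groups}")
        ga, gb = groups
        values = {
            name: (
                sub.loc[sub["group"] == ga, "value"].to_numpy(),
                sub.loc[sub["group"] == gb, "value"].to_numpy(),
            )
            for name, sub in values.groupby("index", sort=True)
        }

    names = list(values)
    if not names:
        raise EmptyInputError("no indexes to contrast")
    raw = {}
    for name in names:
        a, b = (np.asarray(v, dtype=float) for v in values[name])
        t, p = group_ttest(a, b, welch=welch)
        raw[name] = (a, b, t, p)
    adj = bonferroni_adjust([raw[n][3] for n in names], family_size=family_size)

    out = []
    for name, p_adj in zip(names, adj):
        a, b, t, p = raw[name]
        out.append(
            GroupContrast(
                index=name,
                mean_a=float(a.mean()),
                sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
                mean_b=float(b.mean()),
                sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
                t=t,
                p=p,
                p_adjusted=float(p_adj),
                significant=bool(p_adj < alpha),
            )
        )
    return out


def index_matrix_from_phenotypes(
    phenotypes: pd.DataFrame,
    hot_month: str = "august",
    reference_month: str = "june",
) -> IndexMatrix:
    """Per-cow heat-stress index matrix from a long daily-readings frame.

    Indexes: mean RT and RR in the hot month and milk-yield decline
    (reference-month mean minus hot-month mean). All three are
    higher-is-worse, the default direction. ``phenotypes`` needs columns
    ``cow_id``, ``month``, ``rt_c``, ``rr_bpm``, ``milk_kg``.
    """
    need = {"cow_id", "month", "rt_c", "rr_bpm", "milk_kg"}
    missing = need - set(phenotypes.columns)
    if missing:
        raise DomainError(f"phenotype table missing column(s): {sorted(missing)}")
    for month in (hot_month, reference_month):
        if not (phenotypes["month"] == month).any():
            raise EmptyInputError(f"no readings for month {month!r}")
    hot = phenotypes[phenotypes["month"] == hot_month]
    ref = phenotypes[phenotypes["month"] == reference_month]
    rows = []
    for cow in sorted(phenotypes["cow_id"].unique()):
        h = hot[hot["cow_id"] == cow]
        r = ref[ref["cow_id"] == cow]
        if h.empty or r.empty:
            raise EmptyInputError(f"cow {cow!r} missing one observation month")
        rows.append(
            {
                "cow_id": cow,
                "rt_c": h["rt_c"].mean(),
                "rr_bpm": h["rr_bpm"].mean(),
                "milk_decline_kg": milk_yield_change(
                    r["milk_kg"].to_numpy(), h["milk_kg"].to_numpy()
                ),
            }
        )
    return IndexMatrix.from_frame(pd.DataFrame(rows))


def contrasts_to_frame(contrasts: Sequence[GroupContrast]) -> pd.DataFrame:
    """Table-1-style frame of contrasts."""
    return pd.DataFrame(
        {
            "index": [c.index for c in contrasts],
            "mean_ht": [c.mean_a for c in contrasts],
            "sem_ht": [c.sem_a for c in contrasts],
            "mean_nht": [c.mean_b for c in contrasts],
            "sem_nht": [c.sem_b for c in contrasts],
            "t": [c.t for c in contrasts],
            "p": [c.p for c in contrasts],
            "p_bonferroni": [c.p_adjusted for c in contrasts],
            "significant": [c.significant for c in contrasts],
        }
    )
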