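"""Seeded synthetic herd, environment and expression generator.

Emulates the screening study's inputs at bench scale so every analysis
stage is testable without field data: a 42-cow herd with two latent
tolerance classes whose index means match the published group summaries
(sd reconstructed from SEM as SEM·√3, n = 3 per group), a hot-month
environment targeting mean THI 86 (thermoneutral month near 72), a
negative-binomial expression matrix with planted fold changes, and a qPCR
panel derived from the planted truth.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical outputs. Hidden class labels are returned as a separate
truth table so the analysis path cannot accidentally consume them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .expression_de import ExpressionMatrix
from .thi import thi_value

__all__ = [
    "ClassParams",
    "EnvParams",
    "ExpressionParams",
    "HerdSimConfig",
    "HerdData",
    "simulate_environment",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_qpcr",
    "simulate_herd",
]

log = logging.getLogger(__name__)

SQRT3 = float(np.sqrt(3.0))  # SEM -> sd at n = 3


@dataclass(frozen=True)
class ClassParams:
    """Latent per-class means/sds for the heat-stress indexes and ELISA analytes.

    Defaults are the published HT / NHT group summaries (mean, SEM·√3).
    """

    rt_mean: float
    rt_sd: float
    rr_mean: float
    rr_sd: float
    decline_mean: float
    decline_sd: float
    hsp70_mean: float
    hsp70_sd: float
    hsp90_mean: float
    hsp90_sd: float
    cortisol_mean: float
    cortisol_sd: float


TOLERANT_DEFAULTS = ClassParams(
    rt_mean=38.7, rt_sd=0.02 * SQRT3,
    rr_mean=57.0, rr_sd=1.0 * SQRT3,
    decline_mean=2.8, decline_sd=0.9 * SQRT3,
    hsp70_mean=391.0, hsp70_sd=59.0 * SQRT3,
    hsp90_mean=2747.0, hsp90_sd=196.0 * SQRT3,
    cortisol_mean=247.0, cortisol_sd=19.0 * SQRT3,
)

INTOLERANT_DEFAULTS = ClassParams(
    rt_mean=39.7, rt_sd=0.05 * SQRT3,
    rr_mean=100.0, rr_sd=6.0 * SQRT3,
    decline_mean=10.7, decline_sd=2.4 * SQRT3,
    hsp70_mean=183.0, hsp70_sd=12.0 * SQRT3,
    hsp90_mean=1075.0, hsp90_sd=84.0 * SQRT3,
    cortisol_mean=144.0, cortisol_sd=11.0 * SQRT3,
)


@dataclass(frozen=True)
class EnvParams:
    """Environment monitoring: 12-h window, 2-h cadence, 7 days per month."""

    june_target_thi: float = 72.0
    august_target_thi: float = 86.0
    days: int = 7
    hours: tuple[int, ...] = (7, 9, 11, 13, 15, 17, 19)
    at_amplitude: float = 5.0     # diurnal AT half-swing, °C
    rh_base: float = 65.0         # percent
    rh_amplitude: float = 12.0    # anti-phase diurnal RH half-swing
    at_noise_sd: float = 1.0
    rh_noise_sd: float = 5.0


@dataclass(frozen=True)
class ExpressionParams:
    """Negative-binomial count model with planted group fold changes."""

    n_genes: int = 2000
    frac_de: float = 0.05
    true_log2fc: float = 2.0      # planted |log2FC|, sign random per gene
    dispersion: float = 0.1       # NB dispersion; variance = mu + disp·mu²
    n_per_group: int = 3
    mean_log: float = 6.0         # log-normal baseline mean parameters
    sd_log: float = 1.2
    min_length: int = 200         # gene length range, bp
    max_length: int = 10000


@dataclass(frozen=True)
class HerdSimConfig:
    """Full study-condition bundle for the synthetic herd."""

    n_cows: int = 42
    tolerant_fraction: float = 0.5
    index_correlation: float = 0.5   # within-class corr among RT/RR/decline
    tolerant: ClassParams = field(default_factory=lambda: TOLERANT_DEFAULTS)
    intolerant: ClassParams = field(default_factory=lambda: INTOLERANT_DEFAULTS)
    env: EnvParams = field(default_factory=EnvParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    # nuisance (non-class) variation
    june_rt_mean: float = 38.5
    june_rt_sd: float = 0.10
    june_rr_mean: float = 45.0
    june_rr_sd: float = 4.0
    milk_base_mean: float = 42.0     # peak daily yield, kg
    milk_base_sd: float = 5.8
    day_noise_rt: float = 0.05       # day-to-day measurement noise
    day_noise_rr: float = 2.0
    day_noise_milk: float = 1.2
    elisa_replicate_cv: float = 0.02
    n_days: int = 7

    def __post_init__(self):
        if not 0.0 < self.tolerant_fraction < 1.0:
            raise ConfigError("tolerant_fraction must be in (0, 1)")
        if self.n_cows < 2:
            raise ConfigError("n_cows must be at least 2")
        if not -1.0 < self.index_correlation < 1.0:
            raise ConfigError("index_correlation must be in (-1, 1)")
        for cls in (self.tolerant, self.intolerant):
            for name, value in asdict(cls).items():
                if name.endswith("_sd") and value < 0:
                    raise ConfigError(f"{name} must be non-negative")
        ex = self.expression
        if ex.dispersion <= 0:
            raise ConfigError("expression dispersion must be positive")
        if not 0.0 <= ex.frac_de < 1.0:
            raise ConfigError("frac_de must be in [0, 1)")
        if ex.n_per_group < 2:
            raise ConfigError("need at least 2 expression samples per group")

    def with_separation(self, factor: float) -> "HerdSimConfig":
        """Scale the class-mean gap around the pooled midpoint by ``factor``.

        ``factor=0`` collapses both classes onto identical means (null
        herd); ``factor=1`` is the configured separation.
        """
        tol, intol = asdict(self.tolerant), asdict(self.intolerant)
        for key in tol:
            if key.endswith("_mean"):
                mid = 0.5 * (tol[key] + intol[key])
                tol[key] = mid + factor * (tol[key] - mid)
                intol[key] = mid + factor * (intol[key] - mid)
        return replace(self, tolerant=ClassParams(**tol),
                       intolerant=ClassParams(**intol))


@dataclass(frozen=True)
class HerdData:
    """Everything one simulated study produces."""

    config: HerdSimConfig
    seed: int
    env: dict[str, pd.DataFrame]          # period -> env series
    phenotypes: pd.DataFrame              # long: cow_id, month, day, rt, rr, milk
    elisa: pd.DataFrame                   # cow_id, analyte, replicate, value
    truth: pd.DataFrame                   # sidecar: cow_id, true_class
    expression: ExpressionMatrix
    expression_truth: pd.DataFrame        # gene_id, true_log2fc, planted
    qpcr: pd.DataFrame                    # gene_id, sample_id, group, ct_*


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_environment(config: HerdSimConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Diurnal sinusoid + noise AT/RH series whose mean THI hits the target.

    Per period: ``days × len(hours)`` readings. AT follows a cosine peaking
    at 14:00 plus Gaussian noise, RH moves in anti-phase; a constant AT
    offset is then solved (THI is strictly increasing in AT) so the period
    mean THI equals the target exactly. Targets whose solved mean AT falls
    outside a plausible −20…55 °C band are rejected.
    """
    env = config.env
    rng_june, rng_august = _streams(seed, 2)
    out = {}
    for period, target, rng in (
        ("june", env.june_target_thi, rng_june),
        ("august", env.august_target_thi, rng_august),
    ):
        hours = np.tile(np.asarray(env.hours, float), env.days)
        days = np.repeat(np.arange(env.days), len(env.hours))
        shape = np.cos(2.0 * np.pi * (hours - 14.0) / 24.0)
        at = env.at_amplitude * shape + rng.normal(0.0, env.at_noise_sd, hours.size)
        rh = env.rh_base - env.rh_amplitude * shape
        rh = rh + rng.normal(0.0, env.rh_noise_sd, hours.size)
        rh = np.clip(rh, 5.0, 100.0)

        def mean_gap(offset, at=at, rh=rh, target=target):
            return float(np.mean(thi_value(at + offset, rh))) - target

        lo, hi = -60.0, 90.0
        try:
            offset = brentq(mean_gap, lo, hi, xtol=1e-10)
        except ValueError as exc:  # no sign change: target out of reach
            raise ConfigError(
                f"period {period!r}: THI target {target} infeasible"
            ) from exc
        at = at + offset
        if not -20.0 <= at.mean() <= 55.0:
            raise ConfigError(
                f"period {period!r}: THI target {target} needs implausible "
                f"mean AT {at.mean():.1f} °C"
            )
        timestamps = pd.to_datetime(
            {"june": "2018-06-01", "august": "2018-08-01"}[period]
        ) + pd.to_timedelta(days * 24 + hours, unit="h")
        out[period] = pd.DataFrame(
            {"timestamp": timestamps, "at_c": at, "rh_pct": rh}
        )
    return out


def _mvn(rng: np.random.Generator, mean: np.ndarray, sds: np.ndarray,
         corr: float, size: int) -> np.ndarray:
    """MVN draws robust to zero sds (degenerate axes collapse to the mean)."""
    k = mean.size
    R = np.full((k, k), corr)
    np.fill_diagonal(R, 1.0)
    cov = R * np.outer(sds, sds)
    w, V = np.linalg.eigh(cov)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((size, k))
    return mean[None, :] + z @ L.T


def simulate_phenotypes(
    config: HerdSimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-cow phenotypes around the two latent class means.

    Returns ``(phenotypes, elisa, truth)``:

    * ``phenotypes`` — long frame of daily readings (cow_id, month, day,
      rt_c, rr_bpm, milk_kg) for both observation months;
    * ``elisa`` — replicate plasma wells per analyte (hot month only);
    * ``truth`` — the hidden class sidecar (cow_id, true_class), for
      evaluation only.

    Cow-level (RT, RR, milk decline) values are multivariate normal within
    class with the configured positive correlation; daily readings add
    measurement noise. Draws below physiological bounds (RT > 35 °C,
    RR ≥ 1, yield ≥ 0) are floored and the events logged.
    """
    rng_class, rng_day, rng_elisa = _streams(seed, 3)
    n = config.n_cows
    n_tol = int(round(config.tolerant_fraction * n))
    classes = np.array(["tolerant"] * n_tol + ["intolerant"] * (n - n_tol))
    cow_ids = np.array([f"cow{i + 1:03d}" for i in range(n)])

    latent = np.empty((n, 3))
    for label, params in (("tolerant", config.tolerant),
                          ("intolerant", config.intolerant)):
        mask = classes == label
        latent[mask] = _mvn(
            rng_class,
            np.array([params.rt_mean, params.rr_mean, params.decline_mean]),
            np.array([params.rt_sd, params.rr_sd, params.decline_sd]),
            config.index_correlation,
            int(mask.sum()),
        )
    june_rt = rng_class.normal(config.june_rt_mean, config.june_rt_sd, n)
    june_rr = rng_class.normal(config.june_rr_mean, config.june_rr_sd, n)
    milk_base = rng_class.normal(config.milk_base_mean, config.milk_base_sd, n)

    d = config.n_days
    rows = []
    n_floored = 0
    for i, cow in enumerate(cow_ids):
        for month, rt_mu, rr_mu, milk_mu in (
            ("june", june_rt[i], june_rr[i], milk_base[i]),
            ("august", latent[i, 0], latent[i, 1], milk_base[i] - latent[i, 2]),
        ):
            rt = rt_mu + rng_day.normal(0.0, config.day_noise_rt, d)
            rr = rr_mu + rng_day.normal(0.0, config.day_noise_rr, d)
            milk = milk_mu + rng_day.normal(0.0, config.day_noise_milk, d)
            floored = (rt <= 35.0).sum() + (rr < 1.0).sum() + (milk < 0.0).sum()
            n_floored += int(floored)
            rt = np.maximum(rt, 35.0 + 1e-6)
            rr = np.maximum(rr, 1.0)
            milk = np.maximum(milk, 0.0)
            for day in range(d):
                rows.append((cow, month, day + 1, rt[day], rr[day], milk[day]))
    if n_floored:
        log.info("floored %d reading(s) at physiological bounds", n_floored)
    phenotypes = pd.DataFrame(
        rows, columns=["cow_id", "month", "day", "rt_c", "rr_bpm", "milk_kg"]
    )

    elisa_rows = []
    analytes = ("hsp70", "hsp90", "cortisol")
    for i, cow in enumerate(cow_ids):
        params = config.tolerant if classes[i] == "tolerant" else config.intolerant
        for analyte in analytes:
            mu = getattr(params, f"{analyte}_mean")
            sd = getattr(params, f"{analyte}_sd")
            level = max(rng_elisa.normal(mu, sd), 1e-6)
            for rep in (1, 2):
                well = level * (1.0 + rng_elisa.normal(0.0, config.elisa_replicate_cv))
                elisa_rows.append((cow, analyte, rep, max(well, 1e-6)))
    elisa = pd.DataFrame(
        elisa_rows, columns=["cow_id", "analyte", "replicate", "value"]
    )
    truth = pd.DataFrame({"cow_id": cow_ids, "true_class": classes})
    return phenotypes, elisa, truth


def simulate_expression(
    config: HerdSimConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted HT-vs-NHT fold changes.

    A ``frac_de`` fraction of genes receives a group mean shift of
    ``2**(±true_log2fc)`` applied to the HT samples (sign random per gene).
    Returns the count matrix and the planted-truth table (gene_id,
    true_log2fc, planted).
    """
    ex = config.expression
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    g, m = ex.n_genes, ex.n_per_group
    gene_ids = [f"gene{i + 1:05d}" for i in range(g)]
    sample_ids = tuple(
        [f"HT{j + 1}" for j in range(m)] + [f"NHT{j + 1}" for j in range(m)]
    )
    groups = ("HT",) * m + ("NHT",) * m

    lengths = rng.integers(ex.min_length, ex.max_length + 1, g)
    base_mu = rng.lognormal(ex.mean_log, ex.sd_log, g)
    n_de = int(round(ex.frac_de * g))
    planted = np.zeros(g, dtype=bool)
    planted[rng.choice(g, size=n_de, replace=False)] = True
    signs = np.where(rng.random(g) < 0.5, 1.0, -1.0)
    true_lfc = np.where(planted, signs * ex.true_log2fc, 0.0)

    mu = np.tile(base_mu[:, None], (1, 2 * m))
    mu[:, :m] *= 2.0 ** true_lfc[:, None]  # shift the HT group

    size = 1.0 / ex.dispersion  # NB shape so that var = mu + disp·mu²
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    matrix = ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=sample_ids,
        groups=groups,
        counts=counts.astype(float),
        lengths=lengths.astype(float),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_log2fc": true_lfc, "planted": planted}
    )
    return matrix, truth


def simulate_qpcr(
    config: HerdSimConfig,
    expression_truth: pd.DataFrame,
    seed: int,
    n_panel: int = 7,
    ct_noise_sd: float = 0.15,
) -> pd.DataFrame:
    """qPCR Ct records for a validation panel drawn from the planted truth.

    Panel genes are sampled from the planted DE genes (topped up with null
    genes if fewer exist). Per sample, the reference-gene Ct sits near 20
    and the target Ct encodes the gene's true fold change in the HT group,
    plus technical noise. Columns: gene_id, sample_id, group, ct_target,
    ct_reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    planted = expression_truth.loc[expression_truth["planted"], "gene_id"]
    pool = planted.tolist()
    if len(pool) < n_panel:
        extra = expression_truth.loc[~expression_truth["planted"], "gene_id"]
        pool = pool + extra.tolist()
    panel = list(rng.choice(pool, size=n_panel, replace=False))
    lfc = expression_truth.set_index("gene_id")["true_log2fc"]

    m = config.expression.n_per_group
    samples = [(f"HT{j + 1}", "HT") for j in range(m)] + [
        (f"NHT{j + 1}", "NHT") for j in range(m)
    ]
    rows = []
    for gene in panel:
        base_dct = rng.normal(8.0, 1.5)  # gene-specific offset vs reference
        for sample_id, group in samples:
            ct_ref = rng.normal(20.0, 0.1)
            shift = -float(lfc[gene]) if group == "HT" else 0.0
            ct_t = ct_ref + base_dct + shift + rng.normal(0.0, ct_noise_sd)
            rows.append((gene, sample_id, group, ct_t, ct_ref))
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "group", "ct_target", "ct_reference"]
    )


def simulate_herd(config: HerdSimConfig | None = None, seed: int = 0) -> HerdData:
    """Run all generators with independent sub-streams of one seed."""
    config = config or HerdSimConfig()
    s_env, s_pheno, s_expr, s_qpcr = (
        int(s.generate_state(1)[0] % (2**31)) for s in
        np.random.SeedSequence(seed).spawn(4)
    )
    env = simulate_environment(config, s_env)
    phenotypes, elisa, truth = simulate_phenotypes(config, s_pheno)
    expression, expression_truth = simulate_expression(config, s_expr)
    qpcr = simulate_qpcr(config, expression_truth, s_qpcr)
    return HerdData(
        config=config,
        seed=seed,
        env=env,
        phenotypes=phenotypes,
        elisa=elisa,
        truth=truth,
        expression=expression,
        expression_truth=expression_truth,
        qpcr=qpcr,
    )
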