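"""Gene-set enrichment, expected bi-allelic counts, and power analysis.

Per-gene carrier counts are modelled with Poisson regression on gene-set
membership and the per-transcript mutation rate; the rate ratio for
membership quantifies enrichment or depletion of bi-allelic variation in
the set.  Closed-form probabilities of homozygous and compound-heterozygous
genotypes under Hardy-Weinberg equilibrium and inter-site independence
provide the analytic expectation that the Bernoulli haplotype simulation is
checked against, and a chi-square non-centrality solver returns the
minimal detectable odds ratio at a target power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm


@dataclass
class EnrichmentResult:
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    n_in_set: int
    n_out_set: int
    ci_method: str = "profile"


def _profile_ci_bound(counts, design, offset_base, j, beta_hat, llf_max, direction):
    """One profile-likelihood bound for coefficient j of a Poisson GLM."""
    target = llf_max - stats.chi2.ppf(0.95, 1) / 2.0
    others = [k for k in range(design.shape[1]) if k != j]

    def profile_llf(beta_j):
        off = offset_base + design[:, j] * beta_j
        try:
            res = sm.GLM(
                counts, design[:, others], family=sm.families.Poisson(), offset=off
            ).fit()
            return res.llf
        except Exception:
            return -np.inf

    step = 0.5
    bound = beta_hat
    for _ in range(60):
        trial = bound + direction * step
        if profile_llf(trial) < target:
            try:
                return optimize.brentq(
                    lambda b: profile_llf(b) - target, min(bound, trial), max(bound, trial)
                )
            except ValueError:
                return np.nan
        bound = trial
        step *= 1.6
    return direction * np.inf


def poisson_gene_set_enrichment(
    counts: np.ndarray,
    in_set: np.ndarray,
    mutation_rate: np.ndarray,
    rate_as_offset: bool = False,
) -> EnrichmentResult:
    """Poisson regression of per-gene carrier counts on set membership.

    ``counts[g]`` is the number of samples with >= 1 variant of the class
    under study in gene ``g``; ``mutation_rate`` enters on the log scale as
    a covariate (or as an offset when ``rate_as_offset``).  The rate ratio
    is ``exp`` of the membership coefficient, with a profile-likelihood 95%
    interval.  An all-zero stratum is flagged with an unbounded interval.
    """
    counts = np.asarray(counts, dtype=float)
    in_set = np.asarray(in_set, dtype=float)
    mutation_rate = np.asarray(mutation_rate, dtype=float)
    if (mutation_rate <= 0).any():
        raise ValueError("mutation rates must be positive")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    n_in = int(in_set.sum())
    n_out = int(in_set.size - n_in)
    if n_in < 2 or n_out < 2:
        raise ValueError("need >= 2 genes inside and outside the set")

    log_rate = np.log(mutation_rate)
    if rate_as_offset:
        design = np.column_stack([np.ones_like(counts), in_set])
        offset = log_rate
    else:
        design = np.column_stack([np.ones_like(counts), in_set, log_rate])
        offset = np.zeros_like(counts)
    res = sm.GLM(counts, design, family=sm.families.Poisson(), offset=offset).fit()
    coef = float(res.params[1])
    p = float(res.pvalues[1])

    degenerate = counts[in_set == 1].sum() == 0 or counts[in_set == 0].sum() == 0
    if degenerate:
        warnings.warn("all-zero counts in one stratum; CI unbounded")
        lo = -np.inf if counts[in_set == 1].sum() == 0 else float(res.params[1])
        hi = np.inf if counts[in_set == 0].sum() == 0 else float(res.params[1])
        return EnrichmentResult(
            float(np.exp(coef)), float(np.exp(lo)), float(np.exp(hi)), p, coef,
            n_in, n_out,
        )
    lo = _profile_ci_bound(counts, design, offset, 1, coef, res.llf, -1.0)
    hi = _profile_ci_bound(counts, design, offset, 1, coef, res.llf, +1.0)
    return EnrichmentResult(
        rate_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=p,
        coef=coef,
        n_in_set=n_in,
        n_out_set=n_out,
    )


def analytic_biallelic_probability(mafs: np.ndarray) -> tuple[float, float]:
    """Exact P(hom) and P(CH) for one gene under HWE and site independence.

    Each haplotype carries the allele at site ``v`` independently with
    probability ``q_v``.  Then::

        P(hom) = 1 - prod(1 - q_v^2)
        P(CH)  = prod(1 - q_v^2) - 2 prod(1 - q_v) + prod(1 - q_v)^2

    where CH means both haplotypes carry at least one qualifying allele
    with no site homozygous (homozygosity takes precedence).
    """
    q = np.asarray(mafs, dtype=float)
    if ((q <= 0) | (q > 0.5)).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    no_hom = np.prod(1.0 - q * q)
    hap_empty = np.prod(1.0 - q)
    p_hom = 1.0 - no_hom
    p_ch = no_hom - 2.0 * hap_empty + hap_empty * hap_empty
    return float(p_hom), float(max(p_ch, 0.0))


def expected_biallelic_counts(
    mafs: np.ndarray, n_samples: int, n_reps: int = 10, seed: int = 0
) -> dict:
    """Monte-Carlo expected hom and CH carrier counts for one gene.

    Haplotypes carry each allele as independent Bernoulli(MAF) draws and
    are paired into diploids; counts are averaged over ``n_reps``
    replicates.  Agrees with :func:`analytic_biallelic_probability` times
    ``n_samples`` within Monte-Carlo error.
    """
    q = np.asarray(mafs, dtype=float)
    if q.size == 0 or (q == 0).all():
        return {"hom": 0.0, "ch": 0.0}
    rng = np.random.default_rng(seed)
    hom_counts = np.empty(n_reps)
    ch_counts = np.empty(n_reps)
    for r in range(n_reps):
        h1 = rng.random((n_samples, q.size)) < q
        h2 = rng.random((n_samples, q.size)) < q
        hom = (h1 & h2).any(axis=1)
        ch = ~hom & h1.any(axis=1) & h2.any(axis=1)
        hom_counts[r] = hom.sum()
        ch_counts[r] = ch.sum()
    return {"hom": float(hom_counts.mean()), "ch": float(ch_counts.mean())}


def downsample_curve(
    carriers,
    sizes: np.ndarray,
    carrier_classes: tuple[str, ...] = ("CH", "hom"),
    n_boot: int = 100,
    seed: int = 0,
    resample: bool = True,
) -> pd.DataFrame:
    """Unique-gene counts by down-sampled cohort size, with quantile bands.

    For each size, samples individuals with replacement ``n_boot`` times
    and counts unique genes with >= 1 carrier in each requested class;
    reports the mean and the 2.5% / 97.5% quantiles.  With
    ``resample=False`` a single pass over the first ``size`` samples is
    used (at full size this is the exact observed count).
    """
    from .caller import CLASS_NAMES

    rng = np.random.default_rng(seed)
    n = carriers.classes.shape[0]
    rows = []
    for cls_name in carrier_classes:
        code = CLASS_NAMES.index(cls_name)
        member = carriers.classes == code  # samples x genes
        for size in np.asarray(sizes, dtype=int):
            if size > n:
                raise ValueError(f"size {size} exceeds cohort size {n}")
            if size == 0:
                rows.append(
                    {"carrier_class": cls_name, "size": 0, "mean": 0.0,
                     "q025": 0.0, "q975": 0.0}
                )
                continue
            if resample:
                vals = np.empty(n_boot)
                for b in range(n_boot):
                    idx = rng.integers(0, n, size=size)
                    vals[b] = member[idx].any(axis=0).sum()
                rows.append(
                    {
                        "carrier_class": cls_name,
                        "size": int(size),
                        "mean": float(vals.mean()),
                        "q025": float(np.quantile(vals, 0.025)),
                        "q975": float(np.quantile(vals, 0.975)),
                    }
                )
            else:
                v = float(member[:size].any(axis=0).sum())
                rows.append(
                    {"carrier_class": cls_name, "size": int(size),
                     "mean": v, "q025": v, "q975": v}
                )
    return pd.DataFrame(rows)


def _expected_table(carrier_freq, n, prevalence, or_):
    """Expected 2x2 counts at a carrier odds ratio, holding prevalence."""

    def prev_at(p0):
        odds0 = p0 / (1 - p0)
        p1 = or_ * odds0 / (1 + or_ * odds0)
        return carrier_freq * p1 + (1 - carrier_freq) * p0 - prevalence

    p0 = optimize.brentq(prev_at, 1e-12, 1 - 1e-12)
    odds0 = p0 / (1 - p0)
    p1 = or_ * odds0 / (1 + or_ * odds0)
    f = carrier_freq
    return np.array(
        [
            [n * f * p1, n * f * (1 - p1)],
            [n * (1 - f) * p0, n * (1 - f) * (1 - p0)],
        ]
    )


def association_power(
    carrier_freq: float,
    n_samples: int,
    prevalence: float,
    odds_ratio: float,
    alpha: float,
) -> float:
    """Power of the 1-df carrier-vs-trait association test at a given OR.

    Two-proportion normal approximation with distinct null and alternative
    variances (the form behind standard genetic-association power
    calculators): the pooled-variance z statistic of the carrier case rate
    against the non-carrier case rate is rejected at ``alpha`` two-sided.
    At OR = 1 the power equals ``alpha`` exactly.
    """
    table = _expected_table(carrier_freq, n_samples, prevalence, odds_ratio)
    p1 = table[0, 0] / table[0].sum()
    p0 = table[1, 0] / table[1].sum()
    n1 = n_samples * carrier_freq
    n0 = n_samples * (1.0 - carrier_freq)
    s0 = np.sqrt(prevalence * (1 - prevalence) * (1 / n1 + 1 / n0))
    s1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    d = p1 - p0
    return float(
        stats.norm.cdf((d - z_crit * s0) / s1)
        + stats.norm.cdf((-d - z_crit * s0) / s1)
    )


def detectable_or_at_power(
    carrier_freq: float,
    n_samples: int,
    prevalence: float,
    alpha: float,
    power: float = 0.8,
    or_max: float = 1e6,
) -> float:
    """Minimal detectable odds ratio at the target power and alpha.

    Solves :func:`association_power` for the OR at which the 1-df
    association test on expected case-control counts (bi-allelic carrier
    frequency standing in for allele frequency) reaches the requested
    power.  Monotone decreasing in carrier frequency, sample size and
    prevalence; returns ``inf`` when even an arbitrarily large OR is
    underpowered.
    """
    for name, v in (
        ("carrier_freq", carrier_freq),
        ("prevalence", prevalence),
        ("alpha", alpha),
        ("power", power),
    ):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")

    def gap(or_):
        return association_power(
            carrier_freq, n_samples, prevalence, or_, alpha
        ) - power

    if gap(or_max) < 0:
        return np.inf
    return float(optimize.brentq(gap, 1.0 + 1e-9, or_max))
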