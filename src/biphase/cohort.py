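"""Synthetic phased cohorts with planted phase errors and liability phenotypes.

This module generates the kind of data the downstream analysis assumes:
diploid haplotypes over rare coding variants (MAF spectrum dominated by
singletons), parent-offspring trios obeying Mendelian transmission,
MAC-dependent phase errors carrying per-genotype phasing-confidence (PP)
scores, liability-threshold binary phenotypes with spike-and-slab recessive
gene effects, and exponential age-at-onset times under proportional hazards.

Haplotypes are simulated per site independently (no linkage disequilibrium):
compound-heterozygosity calling and every statistic built on it depend only
on within-gene phase configurations, which are planted explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MASK_CATEGORIES = ("pLoF", "damaging_missense", "other_missense", "synonymous")

#: canonical minor-allele-count bins used for switch-error stratification
MAC_BIN_LABELS = ("1", "2-5", "6-10", "11+")


def mac_bin(mac: int | np.ndarray) -> np.ndarray:
    """Assign MAC values to the canonical bins ``1, 2-5, 6-10, 11+``."""
    mac = np.asarray(mac)
    out = np.empty(mac.shape, dtype=object)
    out[mac == 1] = "1"
    out[(mac >= 2) & (mac <= 5)] = "2-5"
    out[(mac >= 6) & (mac <= 10)] = "6-10"
    out[mac >= 11] = "11+"
    if (mac < 1).any():
        raise ValueError("MAC must be >= 1 for polymorphic variants")
    return out


@dataclass
class CohortConfig:
    """Parameters of the synthetic phased cohort.

    Defaults emulate the statistical structure of a phased exome call set
    after confidence filtering: 12% of retained variants are singletons and
    qualifying variants have MAF <= 5%.

    Parameters
    ----------
    n_samples : int
        Total samples, including trio children and their parents.
    n_genes : int
        Number of protein-coding genes.
    mean_variants_per_gene : float
        Poisson mean of the per-gene variant count (minimum one variant).
    maf_spectrum : dict
        Mixture weights over MAC bins ``{"1", "2-5", "6-10", "11+"}``; the
        ``11+`` component draws a low-frequency MAF uniform on (0.005, 0.05].
    mask_proportions : dict
        Fractions of consequence categories; must sum to one.
    n_trios : int
        Number of (child, mother, father) triples carved out of the cohort.
    seed : int
        Seed for all randomness in :func:`simulate_haplotypes`.
    """

    n_samples: int = 5000
    n_genes: int = 100
    mean_variants_per_gene: float = 12.0
    maf_spectrum: dict[str, float] = field(
        default_factory=lambda: {"1": 0.12, "2-5": 0.28, "6-10": 0.10, "11+": 0.50}
    )
    mask_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "pLoF": 0.03,
            "damaging_missense": 0.05,
            "other_missense": 0.57,
            "synonymous": 0.35,
        }
    )
    n_trios: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.mean_variants_per_gene <= 0:
            raise ValueError("mean_variants_per_gene must be positive")
        if self.n_trios < 0 or 3 * self.n_trios > self.n_samples:
            raise ValueError("n_trios * 3 must not exceed n_samples")
        for name, weights in (
            ("maf_spectrum", self.maf_spectrum),
            ("mask_proportions", self.mask_proportions),
        ):
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} weights must sum to 1 (got {total})")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} weights must be non-negative")
        unknown = set(self.maf_spectrum) - set(MAC_BIN_LABELS)
        if unknown:
            raise ValueError(f"unknown MAC bins in maf_spectrum: {unknown}")
        unknown = set(self.mask_proportions) - set(MASK_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown mask categories: {unknown}")


@dataclass
class PhasedCohort:
    """Diploid haplotype matrix plus variant and sample tables.

    ``haplotypes`` has shape ``(2 * n_samples, n_variants)`` with rows
    ``2*i`` and ``2*i + 1`` holding sample ``i``'s two haplotypes; columns
    are in genomic order.  ``pp`` holds the per-genotype phasing confidence
    (NaN where undefined: homozygous or never error-injected genotypes).
    ``truth_haplotypes`` is populated by :func:`inject_phase_errors` and
    retains the pre-error matrix.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    pp: np.ndarray | None = None
    truth_haplotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def diploid(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return sample ``i``'s two haplotypes."""
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]

    def genotype_matrix(self) -> np.ndarray:
        """Allele-count matrix of shape (n_samples, n_variants) in {0,1,2}."""
        return self.haplotypes[0::2] + self.haplotypes[1::2]

    def het_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_variants) marking heterozygous genotypes."""
        return self.haplotypes[0::2] != self.haplotypes[1::2]

    def recompute_allele_counts(self) -> None:
        """Refresh the MAC/MAF columns from the haplotype matrix."""
        mac = self.haplotypes.sum(axis=0).astype(int)
        self.variants["mac"] = mac
        self.variants["maf"] = mac / self.haplotypes.shape[0]

    def copy(self) -> "PhasedCohort":
        return PhasedCohort(
            haplotypes=self.haplotypes.copy(),
            variants=self.variants.copy(),
            samples=self.samples.copy(),
            pp=None if self.pp is None else self.pp.copy(),
            truth_haplotypes=(
                None if self.truth_haplotypes is None else self.truth_haplotypes.copy()
            ),
        )


def _draw_target_macs(rng, n_variants, spectrum, n_haplotypes):
    labels = list(spectrum)
    probs = np.array([spectrum[l] for l in labels])
    bins = rng.choice(len(labels), size=n_variants, p=probs)
    macs = np.empty(n_variants, dtype=int)
    max_mac = max(2, int(0.05 * n_haplotypes))
    for i, b in enumerate(bins):
        label = labels[b]
        if label == "1":
            macs[i] = 1
        elif label == "2-5":
            macs[i] = rng.integers(2, 6)
        elif label == "6-10":
            macs[i] = rng.integers(6, 11)
        else:  # low-frequency, MAF <= 5%
            macs[i] = rng.integers(11, max(12, max_mac + 1))
    return np.minimum(macs, n_haplotypes // 2)


def simulate_haplotypes(config: CohortConfig) -> PhasedCohort:
    """Generate a phased diploid cohort with trios and variant annotations.

    Alleles are placed uniformly at random on founder haplotypes (unrelated
    samples and trio parents) at a target MAC drawn from the configured
    spectrum; each trio child then inherits one whole haplotype from each
    parent, so truth trios have zero Mendelian errors by construction.
    MAC/MAF columns are recomputed from the final matrix, children included.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_samples
    n_trio = config.n_trios
    # sample layout: [child_0, mother_0, father_0, child_1, ..., unrelated...]
    roles = []
    trio_ids = []
    for t in range(n_trio):
        roles += ["child", "mother", "father"]
        trio_ids += [t, t, t]
    roles += ["unrelated"] * (n - 3 * n_trio)
    trio_ids += [-1] * (n - 3 * n_trio)

    child_idx = np.arange(0, 3 * n_trio, 3)
    founder_idx = np.setdiff1d(np.arange(n), child_idx)
    founder_hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in founder_idx]) \
        if len(founder_idx) else np.array([], dtype=int)

    # variant layout: genes in consecutive 1 Mb blocks on one chromosome
    n_var_per_gene = np.maximum(1, rng.poisson(config.mean_variants_per_gene, config.n_genes))
    m = int(n_var_per_gene.sum())
    gene_of = np.repeat(np.arange(config.n_genes), n_var_per_gene)
    pos = np.empty(m, dtype=int)
    start = 0
    for g, k in enumerate(n_var_per_gene):
        base = 1_000_000 * (g + 1)
        offsets = np.sort(rng.choice(np.arange(1, 900_000), size=k, replace=False))
        pos[start : start + k] = base + offsets
        start += k

    targets = _draw_target_macs(rng, m, config.maf_spectrum, len(founder_hap_rows))
    hap = np.zeros((2 * n, m), dtype=np.uint8)
    for v in range(m):
        carriers = rng.choice(founder_hap_rows, size=targets[v], replace=False)
        hap[carriers, v] = 1
    # Mendelian transmission: child hap0 <- one maternal hap, hap1 <- one paternal
    for t in range(n_trio):
        c, mo, fa = 3 * t, 3 * t + 1, 3 * t + 2
        hap[2 * c] = hap[2 * mo + rng.integers(2)]
        hap[2 * c + 1] = hap[2 * fa + rng.integers(2)]

    masks = rng.choice(
        MASK_CATEGORIES,
        size=m,
        p=[config.mask_proportions.get(c, 0.0) for c in MASK_CATEGORIES],
    )
    refs = rng.choice(list("ACGT"), size=m)
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in refs], dtype=object
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "gene": np.char.add("GENE", np.char.zfill((gene_of + 1).astype(str), 4)),
            "mask": masks,
        }
    )
    age = rng.integers(40, 71, size=n)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "role": roles,
            "trio_id": trio_ids,
            "sex": rng.integers(0, 2, size=n),
            "age": age,
            "birth_year": 2008 - age,
        }
    )
    cohort = PhasedCohort(haplotypes=hap, variants=variants, samples=samples)
    cohort.recompute_allele_counts()
    # monomorphic columns can arise when a founder singleton is untransmitted;
    # keep them out of the universe (MAC >= 1 invariant)
    keep = cohort.variants["mac"].to_numpy() >= 1
    if not keep.all():
        cohort.haplotypes = cohort.haplotypes[:, keep]
        cohort.variants = cohort.variants.loc[keep].reset_index(drop=True)
    return cohort


@dataclass
class PPModel:
    """Phasing-confidence (PP) score generator for one MAC bin.

    Draws PP for correctly phased heterozygotes from
    ``Uniform(correct_low, correct_high)`` and for phase-flipped ones from
    ``Uniform(error_low, error_high)``.  The defaults make PP informative
    (errors concentrate below the conventional 0.9 cutoff) without being
    perfectly separable.
    """

    correct_low: float = 0.95
    correct_high: float = 1.0
    error_low: float = 0.5
    error_high: float = 0.95

    def draw(self, rng: np.random.Generator, n: int, is_error: bool) -> np.ndarray:
        lo, hi = (
            (self.error_low, self.error_high)
            if is_error
            else (self.correct_low, self.correct_high)
        )
        return rng.uniform(lo, hi, size=n)


def inject_phase_errors(
    cohort: PhasedCohort,
    ser_by_mac: dict[str, float],
    pp_model: dict[str, PPModel] | None = None,
    seed: int = 0,
) -> PhasedCohort:
    """Plant phase flips at MAC-bin-specific rates and attach PP scores.

    Each heterozygous genotype whose variant falls in MAC bin *b* has its
    two alleles swapped between haplotypes independently with probability
    ``ser_by_mac[b]``.  Unphased genotype content is untouched.  The truth
    matrix is retained on the returned cohort, and every heterozygous
    genotype receives a PP score drawn from the bin's model conditional on
    whether it was flipped.

    Note on rates: a per-genotype flip probability *r* produces a pair-level
    switch-error rate of exactly *r* for pairs in which the partner genotype
    is correctly phased, which is the regime of rare variants anchored
    between confidently phased common hets.
    """
    for b, r in ser_by_mac.items():
        if b not in MAC_BIN_LABELS:
            raise ValueError(f"unknown MAC bin {b!r}")
        if not 0.0 <= r <= 1.0:
            raise ValueError("switch rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pp_model = pp_model or {}

    out = cohort.copy()
    out.truth_haplotypes = cohort.haplotypes.copy()
    out.pp = np.full((cohort.n_samples, cohort.n_variants), np.nan)

    bins = mac_bin(cohort.variants["mac"].to_numpy())
    het = cohort.het_mask()
    for b in MAC_BIN_LABELS:
        cols = np.flatnonzero(bins == b)
        if cols.size == 0:
            continue
        rate = ser_by_mac.get(b, 0.0)
        model = pp_model.get(b, PPModel())
        sub_het = het[:, cols]
        flips = sub_het & (rng.random(sub_het.shape) < rate)
        si, vi = np.nonzero(flips)
        v_global = cols[vi]
        h0 = out.haplotypes[2 * si, v_global].copy()
        out.haplotypes[2 * si, v_global] = out.haplotypes[2 * si + 1, v_global]
        out.haplotypes[2 * si + 1, v_global] = h0
        si_ok, vi_ok = np.nonzero(sub_het & ~flips)
        out.pp[si, v_global] = model.draw(rng, si.size, is_error=True)
        out.pp[si_ok, cols[vi_ok]] = model.draw(rng, si_ok.size, is_error=False)
    return out


@dataclass
class LiabilityConfig:
    """Spike-and-slab liability-threshold phenotype parameters.

    ``h2`` is the liability variance explained by causal genes, ``b`` the
    mean scaled effect, ``pi_theta`` the causal-gene proportion, and
    ``prevalence`` the case fraction under the threshold model (study value
    0.10).
    """

    h2: float = 0.0
    b: float = 0.0
    pi_theta: float = 0.25
    prevalence: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.pi_theta <= 1.0:
            raise ValueError("pi_theta must lie in (0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class CarrierMatrix:
    """Binary bi-allelic carrier matrix and its column-standardized form.

    ``B_tilde[i, j]`` is 1 iff sample *i* carries a damaging bi-allelic
    (compound-heterozygous or homozygous) variant in gene *j*.  ``B`` holds
    the standardized retained columns (mean 0, unit variance); constant
    columns are dropped and their gene labels recorded in ``dropped``.
    """

    B_tilde: np.ndarray
    B: np.ndarray
    genes: np.ndarray
    dropped: np.ndarray

    @classmethod
    def from_binary(cls, B_tilde: np.ndarray, genes=None) -> "CarrierMatrix":
        B_tilde = np.asarray(B_tilde)
        if not np.isin(B_tilde, (0, 1)).all():
            raise ValueError("B_tilde must be binary")
        if genes is None:
            genes = np.array([f"GENE{j + 1:04d}" for j in range(B_tilde.shape[1])])
        genes = np.asarray(genes)
        sd = B_tilde.std(axis=0)
        keep = sd > 0
        if (~keep).any():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant carrier column(s) "
                "before standardization"
            )
        Bk = B_tilde[:, keep].astype(float)
        B = (Bk - Bk.mean(axis=0)) / Bk.std(axis=0)
        return cls(B_tilde=B_tilde, B=B, genes=genes[keep], dropped=genes[~keep])


def simulate_liability_phenotype(
    carriers: CarrierMatrix, config: LiabilityConfig
) -> dict:
    """Simulate a binary trait from bi-allelic carrier status.

    The latent liability is ``y_i = sum_j B_ij theta_j + eps_i`` with
    spike-and-slab effects: gene *j* is causal with probability ``pi_theta``
    and then draws ``theta_j ~ N(b / (m pi), h2 / (m pi))``, otherwise
    ``theta_j = 0``; ``eps_i ~ N(0, 1 - h2)``, so ``E[Var(y)] = 1``.  Cases
    are samples whose liability exceeds the normal quantile at
    ``1 - prevalence``.

    Returns a dict with ``phenotype`` (0/1), ``liability``, ``theta`` and
    ``causal`` (per retained gene).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    B = carriers.B
    m = B.shape[1]
    if m == 0:
        raise ValueError("no non-constant carrier columns to simulate from")
    causal = rng.random(m) < config.pi_theta
    theta = np.zeros(m)
    k = int(causal.sum())
    if k and (config.h2 > 0 or config.b != 0):
        mean = config.b / (m * config.pi_theta)
        sd = np.sqrt(config.h2 / (m * config.pi_theta))
        theta[causal] = rng.normal(mean, sd, size=k)
    eps = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=B.shape[0])
    liability = B @ theta + eps
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    phenotype = (liability > threshold).astype(int)
    return {
        "phenotype": phenotype,
        "liability": liability,
        "theta": theta,
        "causal": causal,
    }


def simulate_onset_times(
    carrier_class: np.ndarray,
    hazard_ratios: dict[str, float],
    baseline_rate: float = 0.02,
    entry_range: tuple[float, float] = (30.0, 40.0),
    censor_range: tuple[float, float] = (65.0, 80.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential age-at-onset times under per-class proportional hazards.

    Entry age (left truncation) is uniform on ``entry_range``; by the
    memoryless property, drawing the residual onset time as
    ``entry + Exp(rate * HR)`` samples exactly from the left-truncated
    proportional-hazards model.  Administrative right-censoring age is
    uniform on ``censor_range``.

    Returns a table with ``entry_age``, ``exit_age``, ``event`` and
    ``carrier_class`` columns.
    """
    for cls_, hr in hazard_ratios.items():
        if hr <= 0:
            raise ValueError(f"hazard ratio for class {cls_!r} must be positive")
    if censor_range[0] < 0 or entry_range[0] < 0:
        raise ValueError("ages must be non-negative")
    carrier_class = np.asarray(carrier_class)
    rng = np.random.default_rng(seed)
    n = carrier_class.shape[0]
    hr = np.array([hazard_ratios.get(c, 1.0) for c in carrier_class])
    entry = rng.uniform(*entry_range, size=n)
    onset = entry + rng.exponential(1.0 / (baseline_rate * hr))
    censor = rng.uniform(*censor_range, size=n)
    censor = np.maximum(censor, entry + 1e-6)
    event = onset <= censor
    return pd.DataFrame(
        {
            "entry_age": entry,
            "exit_age": np.where(event, onset, censor),
            "event": event.astype(int),
            "carrier_class": carrier_class,
        }
    )
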