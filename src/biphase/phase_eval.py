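"""Phasing-quality evaluation.

Implements the trio benchmark for statistical phasing: phase assignment by
Mendelian transmission, switch-error rates (SER) stratified by minor-allele
count with binomial confidence intervals, and pairwise phase concordance
between two independent phase assignments (the surrogate for comparing a
statistical phaser against read-backed phasing).

A switch error is counted between *contiguous* resolvable heterozygous
sites in one sample: the pair contributes an error when its relative phase
in the estimated haplotypes disagrees with the truth phase.  Phase is
relative, so all quantities are invariant to globally flipping a sample's
two haplotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import MAC_BIN_LABELS, mac_bin

UNRESOLVABLE = -1
MENDEL_ERROR = -2


def trio_phase_by_transmission(
    child_gt: np.ndarray, mother_gt: np.ndarray, father_gt: np.ndarray
) -> pd.DataFrame:
    """Resolve a child's phase from parental genotypes, site by site.

    Genotypes are diploid allele dosages in {0, 1, 2}; anything negative is
    treated as missing.  Phase is assigned only where the child is
    heterozygous, exactly one parent is heterozygous, and the other parent
    is homozygous (reference or alternate).  De-novo sites and Mendelian
    inconsistencies are marked and excluded from phasing.

    Returns a table with columns ``maternal_allele`` and ``paternal_allele``
    (-1 where unresolvable, -2 for Mendelian inconsistency) and boolean
    ``resolvable`` / ``mendelian_error`` flags.
    """
    c = np.asarray(child_gt)
    m = np.asarray(mother_gt)
    f = np.asarray(father_gt)
    if not (c.shape == m.shape == f.shape):
        raise ValueError("genotype vectors must share a shape")

    maternal = np.full(c.shape, UNRESOLVABLE, dtype=int)
    missing = (c < 0) | (m < 0) | (f < 0)

    # Mendelian consistency: the child's allele pair must be realizable with
    # one allele from each parent's allele set ({0}, {0,1} or {1}).
    lo = np.where(m == 2, 1, 0) + np.where(f == 2, 1, 0)  # min transmissible dosage
    hi = np.where(m == 0, 0, 1) + np.where(f == 0, 0, 1)  # max transmissible dosage
    inconsistent = ~missing & ((c < lo) | (c > hi))
    maternal[inconsistent] = MENDEL_ERROR

    # a child het is resolvable whenever at least one parent is homozygous
    # (hom x het and hom x hom crosses both force the transmitted alleles);
    # two heterozygous parents leave the phase ambiguous
    ok = ~missing & ~inconsistent & (c == 1)
    mother_hom = ok & ((m == 0) | (m == 2))
    father_hom = ok & ~mother_hom & ((f == 0) | (f == 2))
    maternal[mother_hom] = (m[mother_hom] // 2).astype(int)
    maternal[father_hom] = 1 - (f[father_hom] // 2).astype(int)

    resolvable = maternal >= 0
    paternal = np.where(resolvable, 1 - maternal, maternal)
    return pd.DataFrame(
        {
            "maternal_allele": maternal,
            "paternal_allele": paternal,
            "resolvable": resolvable,
            "mendelian_error": inconsistent,
        }
    )


def _wilson(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = proportion_confint(k, np.maximum(n, 1), alpha=0.05, method="wilson")
    lo = np.where(n > 0, lo, np.nan)
    hi = np.where(n > 0, hi, np.nan)
    return lo, hi


def switch_error_rate(
    estimated_haps: np.ndarray,
    truth_haps: np.ndarray,
    macs: np.ndarray,
    pp: np.ndarray | None = None,
    pp_threshold: float | None = None,
    sample_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Switch-error rates by MAC bin from estimated vs truth haplotypes.

    Both haplotype matrices have shape ``(2 * n_samples, n_variants)`` with
    columns in genomic order over one chromosome; the two phase sets must
    agree on genotype content (only phase may differ).  Heterozygous
    genotypes with PP below ``pp_threshold`` are removed before pairing.
    Each contiguous pair of retained hets contributes one comparison to the
    bin of its rarer variant (``min(MAC)``); a switch is counted when the
    pair's relative phase disagrees between the two sets.

    Returns one row per MAC bin plus an ``all`` row, with counts, the SER
    and Wilson 95% bounds.
    """
    est = np.asarray(estimated_haps)
    tru = np.asarray(truth_haps)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth matrices must share a shape")
    if ((est[0::2] + est[1::2]) != (tru[0::2] + tru[1::2])).any():
        raise ValueError("genotype content differs between phase sets")
    macs = np.asarray(macs)
    bins = mac_bin(macs)
    bin_code = {b: i for i, b in enumerate(MAC_BIN_LABELS)}
    codes = np.array([bin_code[b] for b in bins])

    n_samples = est.shape[0] // 2
    het = tru[0::2] != tru[1::2]
    usable = het.copy()
    if pp_threshold is not None:
        if pp is None:
            raise ValueError("pp matrix required when pp_threshold is set")
        usable &= ~(np.nan_to_num(pp, nan=np.inf) < pp_threshold)
    flipped = est[0::2] != tru[0::2]

    switches = np.zeros(len(MAC_BIN_LABELS), dtype=int)
    comparisons = np.zeros(len(MAC_BIN_LABELS), dtype=int)
    samples = range(n_samples) if sample_indices is None else sample_indices
    for i in samples:
        idx = np.flatnonzero(usable[i])
        if idx.size < 2:
            continue
        a, b = idx[:-1], idx[1:]
        sw = flipped[i, a] ^ flipped[i, b]
        pair_codes = np.minimum(codes[a], codes[b])
        np.add.at(comparisons, pair_codes, 1)
        np.add.at(switches, pair_codes, sw)

    table = pd.DataFrame(
        {
            "mac_bin": list(MAC_BIN_LABELS) + ["all"],
            "n_switches": list(switches) + [switches.sum()],
            "n_comparisons": list(comparisons) + [comparisons.sum()],
        }
    )
    with np.errstate(invalid="ignore"):
        table["ser"] = table["n_switches"] / table["n_comparisons"]
    lo, hi = _wilson(table["n_switches"].to_numpy(), table["n_comparisons"].to_numpy())
    table["ci_low"] = lo
    table["ci_high"] = hi
    return table


def gene_level_ser(
    estimated_haps: np.ndarray,
    truth_haps: np.ndarray,
    genes: np.ndarray,
    pp: np.ndarray | None = None,
    pp_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-gene switch summary: fraction of (sample, gene) units error free.

    A (sample, gene) unit enters the denominator when the sample has >= 2
    resolvable hets inside the gene body (our convention for which hets
    count toward a gene); it is error free when no contiguous within-gene
    pair switches.
    """
    est = np.asarray(estimated_haps)
    tru = np.asarray(truth_haps)
    genes = np.asarray(genes)
    het = tru[0::2] != tru[1::2]
    usable = het.copy()
    if pp_threshold is not None:
        if pp is None:
            raise ValueError("pp matrix required when pp_threshold is set")
        usable &= ~(np.nan_to_num(pp, nan=np.inf) < pp_threshold)
    flipped = est[0::2] != tru[0::2]

    units = 0
    clean = 0
    for i in range(est.shape[0] // 2):
        idx = np.flatnonzero(usable[i])
        if idx.size < 2:
            continue
        for g in np.unique(genes[idx]):
            gi = idx[genes[idx] == g]
            if gi.size < 2:
                continue
            units += 1
            if not (flipped[i, gi[:-1]] ^ flipped[i, gi[1:]]).any():
                clean += 1
    frac = clean / units if units else np.nan
    return pd.DataFrame(
        {"n_units": [units], "n_error_free": [clean], "fraction_error_free": [frac]}
    )


def pairwise_phase_concordance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Concordance between two independent relative-phase assignments.

    ``pairs`` has one row per variant pair within one sample, with boolean
    (or 0/1) columns ``phase_a`` and ``phase_b`` giving each method's
    relative phase (e.g. True for *trans*) and a ``mac`` column holding the
    pair's ``min(MAC)``.  Rows with a missing assignment (pairs spanning a
    homozygous genotype) are excluded.  Returns concordance with Wilson 95%
    bounds per MAC bin plus an ``all`` row.
    """
    usable = pairs.dropna(subset=["phase_a", "phase_b"])
    if usable.empty:
        raise ValueError("no comparable pairs")
    agree = (
        usable["phase_a"].astype(bool) == usable["phase_b"].astype(bool)
    ).to_numpy()
    bins = mac_bin(usable["mac"].to_numpy())
    rows = []
    for b in list(MAC_BIN_LABELS) + ["all"]:
        sel = np.ones(len(usable), dtype=bool) if b == "all" else bins == b
        n = int(sel.sum())
        k = int(agree[sel].sum())
        lo, hi = _wilson(np.array([k]), np.array([n]))
        rows.append(
            {
                "mac_bin": b,
                "n_concordant": k,
                "n_pairs": n,
                "concordance": k / n if n else np.nan,
                "ci_low": lo[0],
                "ci_high": hi[0],
            }
        )
    return pd.DataFrame(rows)
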