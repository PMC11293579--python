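"""Carrier classification from phased genotypes.

Classifies every (sample, gene) pair as wild type (``WT``), heterozygous
(``het``), multi-hit *cis* (two or more qualifying variants on one
haplotype), compound heterozygous (``CH``: at least one qualifying variant
on each haplotype) or homozygous (``hom``: a qualifying homozygous
genotype), and emits the two association encodings:

* recessive 0/2 — presence of a damaging bi-allelic (CH or hom) variant;
* additive 0/1/2 — number of affected gene copies (het and cis count one).

Precedence when several configurations co-occur in one gene is
``hom > CH > cis > het > WT``; a sample that is both hom and CH is flagged
but counts once, as bi-allelic.  Heterozygous genotypes whose phasing
confidence (PP) falls below the mask threshold are phase unknown: they can
never create a CH or cis call but still imply at least one affected copy,
so they contribute to ``het`` status and the additive encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PhasedCohort

CLASS_NAMES = ("WT", "het", "cis", "CH", "hom")
WT, HET, CIS, CH, HOM = range(5)

_MASK_SETS = {
    "pLoF": {"pLoF"},
    "damaging_missense_protein_altering": {"damaging_missense"},
    "pLoF_plus_damaging": {"pLoF", "damaging_missense"},
    "other_missense": {"other_missense"},
    "synonymous": {"synonymous"},
}


@dataclass
class VariantMask:
    """Qualifying-variant filter: consequence category, MAF cap, PP floor."""

    category: str = "pLoF_plus_damaging"
    maf_max: float = 0.05
    pp_min: float = 0.9

    def __post_init__(self) -> None:
        if self.category not in _MASK_SETS:
            raise ValueError(
                f"unknown mask category {self.category!r}; "
                f"choose from {sorted(_MASK_SETS)}"
            )
        if not 0.0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must lie in (0, 0.5]")
        if not 0.0 <= self.pp_min <= 1.0:
            raise ValueError("pp_min must lie in [0, 1]")

    @property
    def categories(self) -> set[str]:
        return _MASK_SETS[self.category]


def qualify_variants(variants: pd.DataFrame, mask: VariantMask) -> np.ndarray:
    """Indices of variants passing the mask (category and MAF <= maf_max).

    Variants with missing MAF are rejected with a warning.  PP filtering is
    genotype-level and applied during classification, not here.
    """
    required = {"mask", "maf"}
    missing_cols = required - set(variants.columns)
    if missing_cols:
        raise ValueError(f"annotation columns missing: {sorted(missing_cols)}")
    maf = variants["maf"]
    no_maf = maf.isna()
    if no_maf.any():
        warnings.warn(f"rejecting {int(no_maf.sum())} variant(s) with missing MAF")
    keep = (
        variants["mask"].isin(mask.categories) & ~no_maf & (maf <= mask.maf_max)
    )
    return np.flatnonzero(keep.to_numpy())


@dataclass
class CarrierTable:
    """Per (sample, gene) carrier classes with per-gene count summaries.

    ``classes`` is an int8 matrix (n_samples x n_genes) of codes indexing
    :data:`CLASS_NAMES`; ``hom_and_ch`` flags samples with both a
    qualifying homozygote and a CH pair in the same gene.
    """

    classes: np.ndarray
    genes: np.ndarray
    sample_ids: np.ndarray
    hom_and_ch: np.ndarray

    def class_counts(self) -> pd.DataFrame:
        """Per-gene counts of each class; rows sum to n_samples."""
        counts = np.stack(
            [(self.classes == c).sum(axis=0) for c in range(len(CLASS_NAMES))], axis=1
        )
        return pd.DataFrame(counts, index=self.genes, columns=CLASS_NAMES)

    def biallelic(self) -> np.ndarray:
        """Boolean (n_samples x n_genes): CH or hom."""
        return (self.classes == CH) | (self.classes == HOM)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (sample, gene, class) table of non-WT rows."""
        si, gi = np.nonzero(self.classes != WT)
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids[si],
                "gene": self.genes[gi],
                "carrier_class": [CLASS_NAMES[c] for c in self.classes[si, gi]],
                "hom_and_ch": self.hom_and_ch[si, gi],
            }
        )


def _phase_known(cohort: PhasedCohort, pp_min: float) -> np.ndarray:
    """Heterozygous genotypes whose phase may be trusted.

    A het is phase known unless its PP score is present and below the
    threshold, or the reader flagged the genotype as unphased.  Absent PP
    (truth cohorts, homozygotes) implies no evidence against the phase.
    """
    het = cohort.het_mask()
    known = het.copy()
    if cohort.pp is not None:
        known &= ~(np.nan_to_num(cohort.pp, nan=np.inf) < pp_min)
    phased = getattr(cohort, "phased_mask", None)
    if phased is not None:
        known &= phased | ~het
    return known


def classify_carriers(
    cohort: PhasedCohort, mask: VariantMask, qualifying: np.ndarray | None = None
) -> CarrierTable:
    """Classify every (sample, gene) pair under a variant mask."""
    if qualifying is None:
        qualifying = qualify_variants(cohort.variants, mask)
    genes = cohort.variants["gene"].to_numpy()
    gene_names = np.unique(genes[qualifying]) if qualifying.size else np.array([], dtype=object)
    all_genes = np.unique(genes)

    h0 = cohort.haplotypes[0::2]
    h1 = cohort.haplotypes[1::2]
    known = _phase_known(cohort, mask.pp_min)
    het = cohort.het_mask()

    n = cohort.n_samples
    classes = np.zeros((n, len(all_genes)), dtype=np.int8)
    flags = np.zeros((n, len(all_genes)), dtype=bool)
    gene_pos = {g: j for j, g in enumerate(all_genes)}
    for g in gene_names:
        q = qualifying[genes[qualifying] == g]
        a0 = (h0[:, q] == 1) & (h1[:, q] == 0)
        a1 = (h1[:, q] == 1) & (h0[:, q] == 0)
        hom = ((h0[:, q] == 1) & (h1[:, q] == 1)).any(axis=1)
        n0 = (a0 & known[:, q]).sum(axis=1)
        n1 = (a1 & known[:, q]).sum(axis=1)
        n_unknown = (het[:, q] & ~known[:, q]).sum(axis=1)
        is_ch_pair = (n0 >= 1) & (n1 >= 1)
        cls = np.select(
            [
                hom,
                is_ch_pair,
                (n0 >= 2) | (n1 >= 2),
                (n0 + n1 + n_unknown) >= 1,
            ],
            [HOM, CH, CIS, HET],
            default=WT,
        ).astype(np.int8)
        j = gene_pos[g]
        classes[:, j] = cls
        flags[:, j] = hom & is_ch_pair
    return CarrierTable(
        classes=classes,
        genes=all_genes,
        sample_ids=cohort.samples["sample_id"].to_numpy(),
        hom_and_ch=flags,
    )


def classify_gene_carriers(
    cohort: PhasedCohort, gene: str, mask: VariantMask
) -> pd.DataFrame:
    """Detailed classification of one gene, with qualifying variant ids.

    Returns one row per non-WT sample with the qualifying variant indices
    carried on each haplotype and as homozygotes.
    """
    genes = cohort.variants["gene"].to_numpy()
    if gene not in genes:
        raise KeyError(f"gene {gene!r} absent from the annotation table")
    qualifying = qualify_variants(cohort.variants, mask)
    q = qualifying[genes[qualifying] == gene]
    table = classify_carriers(cohort, mask, qualifying=qualifying)
    j = int(np.flatnonzero(table.genes == gene)[0])

    h0 = cohort.haplotypes[0::2][:, q]
    h1 = cohort.haplotypes[1::2][:, q]
    known = _phase_known(cohort, mask.pp_min)[:, q]
    rows = []
    for i in np.flatnonzero(table.classes[:, j] != WT):
        hap0 = q[(h0[i] == 1) & (h1[i] == 0) & known[i]]
        hap1 = q[(h1[i] == 1) & (h0[i] == 0) & known[i]]
        hom_sites = q[(h0[i] == 1) & (h1[i] == 1)]
        unknown = q[(h0[i] != h1[i]) & ~known[i]]
        rows.append(
            {
                "sample_id": table.sample_ids[i],
                "gene": gene,
                "carrier_class": CLASS_NAMES[table.classes[i, j]],
                "hap0_variants": list(hap0),
                "hap1_variants": list(hap1),
                "hom_variants": list(hom_sites),
                "phase_unknown_variants": list(unknown),
                "hom_and_ch": bool(table.hom_and_ch[i, j]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene",
            "carrier_class",
            "hap0_variants",
            "hap1_variants",
            "hom_variants",
            "phase_unknown_variants",
            "hom_and_ch",
        ],
    )


@dataclass
class EncodedGenotypes:
    """Recessive 0/2 and additive 0/1/2 encodings per sample per gene."""

    recessive: np.ndarray
    additive: np.ndarray
    genes: np.ndarray
    sample_ids: np.ndarray


def encode(carriers: CarrierTable) -> EncodedGenotypes:
    """Derive the recessive and additive encodings from carrier classes."""
    cls = carriers.classes
    biallelic = (cls == CH) | (cls == HOM)
    recessive = np.where(biallelic, 2, 0).astype(np.int8)
    additive = np.where(biallelic, 2, np.where(cls != WT, 1, 0)).astype(np.int8)
    return EncodedGenotypes(
        recessive=recessive,
        additive=additive,
        genes=carriers.genes,
        sample_ids=carriers.sample_ids,
    )


def collapse_ultra_rare(
    cohort: PhasedCohort,
    qualifying: np.ndarray,
    mac_threshold: int = 10,
    maf_max: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse ultra-rare qualifying variants into a super-variant.

    Returns ``(indicator, residual_dosages, residual_idx)``: the indicator
    is 1 iff the sample carries at least one qualifying variant with
    MAC <= ``mac_threshold`` (a carrier indicator, not a count); variants
    with MAC > threshold and MAF <= ``maf_max`` are returned individually
    as dosage columns for direct conditioning.
    """
    mac = cohort.variants["mac"].to_numpy()
    maf = cohort.variants["maf"].to_numpy()
    gt = cohort.genotype_matrix()
    ultra = qualifying[mac[qualifying] <= mac_threshold]
    rare = qualifying[(mac[qualifying] > mac_threshold) & (maf[qualifying] <= maf_max)]
    indicator = (gt[:, ultra] > 0).any(axis=1).astype(np.int8) if ultra.size else np.zeros(
        cohort.n_samples, dtype=np.int8
    )
    return indicator, gt[:, rare].astype(float), rare
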