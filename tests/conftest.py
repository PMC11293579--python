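import numpy as np
import pandas as pd
import pytest

from biphase import CohortConfig, PhasedCohort, simulate_haplotypes


@pytest.fixture(scope="session")
def small_cohort() -> PhasedCohort:
    """300 samples, 10 genes, 10 trios; shared read-only fixture."""
    return simulate_haplotypes(
        CohortConfig(n_samples=300, n_genes=10, n_trios=10, seed=42)
    )


def make_cohort(haplotypes, genes, macs=None, pp=None, positions=None):
    """Hand-build a PhasedCohort from an explicit haplotype matrix."""
    hap = np.asarray(haplotypes, dtype=np.uint8)
    n2, m = hap.shape
    n = n2 // 2
    mac = hap.sum(axis=0).astype(int) if macs is None else np.asarray(macs)
    pos = np.arange(1, m + 1) * 100 if positions is None else np.asarray(positions)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "gene": np.asarray(genes),
            "mask": "pLoF",
            "mac": mac,
            "maf": mac / n2,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "role": "unrelated",
            "trio_id": -1,
            "sex": 0,
            "age": 50,
            "birth_year": 1958,
        }
    )
    return PhasedCohort(
        haplotypes=hap,
        variants=variants,
        samples=samples,
        pp=None if pp is None else np.asarray(pp, dtype=float),
    )
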