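import numpy as np
import pytest

from paleodiff.datamodel import ANC_ALT, ANC_REF, ANC_UNKNOWN, GeneticMap, SiteTable


def build_table(
    genotypes,
    chrom="chr1",
    spacing=1000,
    ref="A",
    alt="C",
    anc="ref",
    start=1,
):
    """Small SiteTable from a dict {sample: [dosages]} (rows = sites)."""
    samples = list(genotypes)
    gt = np.array([genotypes[s] for s in samples], dtype=np.int8).T
    n = gt.shape[0]
    anc_code = {"ref": ANC_REF, "alt": ANC_ALT, "unknown": ANC_UNKNOWN}[anc]
    return SiteTable(
        np.full(n, chrom, dtype=object),
        start + spacing * np.arange(n),
        np.full(n, ref, dtype=object),
        np.full(n, alt, dtype=object),
        np.full(n, anc_code, dtype=np.int8),
        samples,
        gt,
    )


@pytest.fixture
def uniform_map():
    def make(n_chrom=1, length=10_000_000, cm_per_mb=1.0):
        return GeneticMap.uniform(
            {f"chr{i + 1}": length for i in range(n_chrom)}, cm_per_mb=cm_per_mb
        )

    return make
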