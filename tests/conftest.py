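import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bcltools.diagnostics as dx
import bcltools.synthetic_locus as sl

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def models():
    """All five BCL haplotype models, built once."""
    return {name: sl.build_haplotype(name)
            for name in sl.HAPLOTYPE_GENE_ORDER}


@pytest.fixture(scope="session")
def marker_panel(models):
    return dx.default_marker_panel(models["HapF2"])


@pytest.fixture(scope="session")
def probe():
    return sl.r2r3_probe()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


def write_sam(path, reference, ref_len, records):
    """Minimal SAM writer for hand-built alignments.

    ``records`` is an iterable of (name, pos0, cigar, seq[, flag]).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference}\tLN:{ref_len}\n")
        for rec in records:
            name, pos, cigar, seq = rec[:4]
            flag = rec[4] if len(rec) > 4 else 0
            fh.write(f"{name}\t{flag}\t{reference}\t{pos + 1}\t60\t{cigar}\t"
                     f"*\t0\t0\t{seq}\t*\n")
    return path
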