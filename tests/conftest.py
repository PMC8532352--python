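import warnings

import numpy as np
import pytest

from ectvar.genome import AnnotationIndex, GenomicInterval, SequenceStore, Transcript
from ectvar.pipeline import run_simulated_benchmark
from ectvar.synth import generate_synthetic_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 30-gene synthetic genome shared by read-only tests."""
    return generate_synthetic_genome(30, seed=11)


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-built two-gene annotation on one random chromosome.

    geneA (+): exons [100,200), [500,650), [1000,1100)
    geneB (-): exons [2000,2100), [2500,2600), [3000,3120)
    plus an isoform of geneA sharing its middle exon.
    """
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
    store = SequenceStore({"chrT": seq})
    iv = lambda s, e, st="+": GenomicInterval("chrT", s, e, st)
    txs = [
        Transcript("A.1", "geneA", (iv(100, 200), iv(500, 650), iv(1000, 1100))),
        Transcript("A.2", "geneA", (iv(120, 200), iv(500, 650), iv(900, 1100))),
        Transcript(
            "B.1", "geneB",
            (iv(2000, 2100, "-"), iv(2500, 2600, "-"), iv(3000, 3120, "-")),
        ),
    ]
    return store, AnnotationIndex(txs)


@pytest.fixture(scope="session")
def mini_benchmark(tmp_path_factory):
    """A small end-to-end benchmark run (3 variants/type, 50x, 1 control)."""
    outdir = str(tmp_path_factory.mktemp("mini_bench"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_simulated_benchmark(
            n_per_type=3, n_background=20, coverage=50, seed=3, outdir=outdir
        )
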