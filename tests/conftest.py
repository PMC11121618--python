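import numpy as np
import pytest

from g4mm.synth import SampleSpec, SynthConfig, build_study


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_reference():
    # 1000 nt A/T background with no G/C so nothing matches by accident
    return {"chr1": ("AT" * 500), "chr2": "GGGG" + "AT" * 48}


@pytest.fixture(scope="session")
def small_study():
    """Three-sample synthetic study: one enriched, two background-only."""
    config = SynthConfig(
        seed=41,
        n_contigs=1,
        contig_length=80_000,
        samples=(
            SampleSpec("T1", 100, 0.6),
            SampleSpec("T2", 90, 0.0),
            SampleSpec("T3", 80, 0.0),
        ),
        snp_group=("T1",),
        dp_range=(20, 40),  # deep calls so the depth filter keeps everything
    )
    return build_study(config)


def write_fasta(path, contigs):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path
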