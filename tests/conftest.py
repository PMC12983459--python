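import pytest

from psmb8kit.pipeline import RunConfig, default_references, run
from psmb8kit.synthetic_data import simulate_transcriptome, study_mirror_spec


@pytest.fixture(scope="session")
def references():
    return default_references()


@pytest.fixture(scope="session")
def study_sim():
    """One study-mirroring simulated transcriptome (seed 1) with its truth."""
    spec = study_mirror_spec(seed=1)
    contigs, truth = simulate_transcriptome(spec)
    return spec, contigs, truth


@pytest.fixture(scope="session")
def study_report(study_sim):
    """Pipeline report on the study-mirroring transcriptome (point tree only)."""
    _, contigs, _ = study_sim
    return run(RunConfig(contigs=contigs, bootstrap_reps=1, seed=42))
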