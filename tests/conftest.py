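import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cernet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_3v3():
    """Single-tissue 3 vs 3 design (one tissue of the full HPM layout)."""
    return cernet.generate_design(tissues=("hypothalamus",))


@pytest.fixture(scope="session")
def full_design():
    """Three tissues x NHS/HS x 3 replicates (18 samples)."""
    return cernet.generate_design()


def make_matrix(counts, design=None, rna_class="mRNA", tissue="hypothalamus",
                feature_prefix="f"):
    """Wrap a 2-D array into an ExpressionMatrix with design sample IDs."""
    counts = np.asarray(counts)
    if design is None:
        design = cernet.generate_design(tissues=(tissue,))
    samples = design.samples(tissue)["sample_id"].tolist()[: counts.shape[1]]
    df = pd.DataFrame(
        counts,
        index=[f"{feature_prefix}{i}" for i in range(counts.shape[0])],
        columns=samples,
    )
    return cernet.ExpressionMatrix(counts=df, rna_class=rna_class, tissue=tissue)


@pytest.fixture(scope="session")
def recovery_manifest(tmp_path_factory):
    """End-to-end run on the planted-triad benchmark fixture.

    Coupling 0.95, 20 replicates per condition, 30 planted triads, decoy
    interaction density 0.05, one tissue at the 300/100/500 desk scale.
    """
    outdir = tmp_path_factory.mktemp("recovery_run")
    cfg = cernet.PipelineConfig(
        seed=1,
        outdir=str(outdir),
        tissues=("hypothalamus",),
        replicates=20,
        simulate=cernet.SimulationConfig(
            n_features={"circRNA": 300, "miRNA": 100, "mRNA": 500},
            n_planted_triads=30,
            triad_coupling_strength=0.95,
            interaction_density=0.05,
        ),
    )
    manifest = cernet.run_pipeline(cfg)
    return manifest, outdir


@pytest.fixture(scope="session")
def demo_manifest(tmp_path_factory):
    """End-to-end run on the small 3 vs 3 demo fixture (nonempty network)."""
    outdir = tmp_path_factory.mktemp("demo_run")
    cfg = cernet.PipelineConfig(
        seed=0,
        outdir=str(outdir),
        tissues=("hypothalamus",),
        replicates=3,
        simulate=cernet.SimulationConfig(n_planted_triads=30, de_fraction=0.3),
    )
    manifest = cernet.run_pipeline(cfg)
    return manifest, outdir
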