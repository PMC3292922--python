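import pytest

from orthoverlap.fixtures import (
    load_fixture,
    load_reference_aliases,
    load_reference_orthology,
)
from orthoverlap.pipeline import RunConfig, run_full_pipeline
from orthoverlap.synthetic_data import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def table1_studies():
    return load_fixture("table1_catalog")


@pytest.fixture(scope="session")
def table2_entries():
    return load_fixture("table2_overlaps")


@pytest.fixture(scope="session")
def reference_orthology():
    return load_reference_orthology()


@pytest.fixture(scope="session")
def reference_aliases():
    return load_reference_aliases()


@pytest.fixture()
def synth_bundle(tmp_path):
    """A small deterministic bundle with planted overlaps and paralogue pairs."""
    config = SyntheticConfig(
        seed=11,
        n_planted_shared=5,
        paralogue_pair_rate=0.4,
        isoform_suffix_rate=0.25,
    )
    bundle = tmp_path / "bundle"
    truth = generate_synthetic_dataset(config, bundle)
    return config, bundle, truth


def run_bundle(bundle, out, **overrides):
    """Run the full pipeline over a generated bundle directory."""
    kwargs = dict(
        studies_path=str(bundle / "studies.tsv"),
        genes_dir=str(bundle / "genes"),
        groups_path=str(bundle / "groups.txt"),
        aliases_path=str(bundle / "aliases.tsv"),
        annotations_path=str(bundle / "annotations.tsv"),
        vocabulary_path=str(bundle / "vocabulary.txt"),
        out_dir=str(out),
    )
    kwargs.update(overrides)
    return run_full_pipeline(RunConfig(**kwargs))
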