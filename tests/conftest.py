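import pytest

from ggaa_switch import synthetic


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One complete synthetic study (seed 7), files written once per session."""
    out = tmp_path_factory.mktemp("study")
    return synthetic.simulate_study(7, outdir=out)


@pytest.fixture(scope="session")
def study_dir(study):
    from pathlib import Path

    return Path(study.genome_path).parent
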