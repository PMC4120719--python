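import pathlib

import pytest

from classalign.synthgen import SynthSpec, generate, table8_fixture


@pytest.fixture(scope="session")
def table8_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("table8")
    table8_fixture(d)
    return d


@pytest.fixture(scope="session")
def table8_bundle():
    return table8_fixture()


@pytest.fixture(scope="session")
def clean_bundle_dir(tmp_path_factory) -> pathlib.Path:
    """Default synthetic bundle, zero noise, written to disk."""
    d = tmp_path_factory.mktemp("synth")
    generate(SynthSpec(seed=7, noise=0.0), d)
    return d


def bundle_config(d: pathlib.Path, out=None, **kw):
    from classalign.cli import RunConfig

    return RunConfig(
        classes=str(d / "classes.tsv"),
        drugs=str(d / "drugs.tsv"),
        membership=str(d / "membership.tsv"),
        normmap=str(d / "normmap.tsv"),
        synonyms=str(d / "synonyms.tsv"),
        out_dir=str(out) if out else None,
        **kw,
    )
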