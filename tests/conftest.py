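import pytest

from achropuce.fixtures import (
    FixtureSpec,
    build_bundle,
    generate_bundle,
    generate_labeled_cnvs,
    generate_piev_cnvs,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def bundle(spec):
    return build_bundle(spec)


@pytest.fixture(scope="session")
def bundle_dir(spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    generate_bundle(spec, d)
    return d


@pytest.fixture(scope="session")
def planted(spec):
    return generate_labeled_cnvs(spec)


@pytest.fixture(scope="session")
def planted_piev(spec):
    return generate_piev_cnvs(spec, n=60)
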