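import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    from nrdmotif.synthetic import reference_anchor

    return reference_anchor()


@pytest.fixture(scope="session")
def extractor(reference):
    from nrdmotif.anchor import PairwiseMotifExtractor

    return PairwiseMotifExtractor(reference=reference).fit()


def loop_variant(reference, motif: str) -> str:
    """Reference sequence with the apical loop replaced by ``motif``."""
    lo, hi = reference.apical_span
    return reference.sequence[:lo - 1] + motif + reference.sequence[hi:]
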