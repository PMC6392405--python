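import pytest

from cascensus.offtargets import find_offtargets
from cascensus.profiles import get_profile
from cascensus.scan import scan_targets
from cascensus.simulate import demo_spec, generate_genome


def pair_key(pair):
    """Hashable identity of an ordered pair for set comparisons."""
    return (
        pair.target.key,
        pair.offtarget.key,
        pair.distance,
        pair.mismatch_position,
        pair.mismatch_class,
    )


@pytest.fixture(scope="session")
def demo():
    """The canonical planted-structure fixture: (genome, annotation, truth)."""
    return generate_genome(demo_spec())


@pytest.fixture(scope="session")
def demo_spcas9(demo):
    """SpCas9 coding-exon targets and off-target pairs of the demo genome."""
    genome, annotation, _ = demo
    profile = get_profile("SpCas9")
    targets = scan_targets(genome, profile, annotation)
    pairs = find_offtargets(targets, profile=profile)
    return targets, pairs
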