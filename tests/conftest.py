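import pytest

from ddnipt.droplet_stats import ChannelCounts
from ddnipt.genotype_model import FetalGenotype
from ddnipt.simulator import SimulationSpec, simulate_sample


@pytest.fixture
def make_sim():
    """Factory for simulated samples with chosen truth."""

    def _make(
        f=0.10,
        genotype=FetalGenotype.HOM_REF,
        seed=0,
        **spec_kwargs,
    ):
        spec = SimulationSpec(
            true_genotype=genotype, true_f=f, seed=seed, **spec_kwargs
        )
        return simulate_sample(spec)

    return _make


@pytest.fixture
def cc():
    """Shorthand ChannelCounts constructor."""

    def _cc(k, n, n_wells=1):
        return ChannelCounts(k=k, n=n, n_wells=n_wells)

    return _cc
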