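import pytest

from dhfrough import DualHesitantElement, random_instance, worked_example


@pytest.fixture(scope="session")
def fever():
    """The packaged three-expert, five-diagnosis fever case study."""
    return worked_example()


@pytest.fixture
def example_pair():
    """The two elements whose union/intersection/complement are worked
    out in the source literature's element-operations example."""
    d1 = DualHesitantElement.of((0.1, 0.4, 0.5), (0.2, 0.3))
    d2 = DualHesitantElement.of((0.2, 0.3, 0.4), (0.4, 0.5))
    return d1, d2


@pytest.fixture
def make_instance():
    """Factory for small reproducible random instances."""

    def factory(seed, n_diagnoses=4, n_symptoms=5, n_experts=3, max_hesitancy=3):
        return random_instance(
            n_diagnoses, n_symptoms, n_experts, max_hesitancy, seed=seed
        )

    return factory
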