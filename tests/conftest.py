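import numpy as np
import pytest

import damfretkit as dk


@pytest.fixture(scope="session")
def spillover():
    opt = dk.OpticsModel()
    return dk.SpilloverModel(opt.s_donor, opt.s_acceptor)


@pytest.fixture(scope="session")
def negative_table(spillover):
    """Gated, compensated, AmFRET-derived monomeric control (1e5 events)."""
    control = dk.simulate_negative_control(n_cells=100_000, seed=42)
    table, _, _ = dk.process_events(control.events, spillover)
    return table


@pytest.fixture(scope="session")
def negative_gate(negative_table):
    return dk.build_negative_gate(negative_table)


@pytest.fixture(scope="session")
def nucleated_sample():
    """A moderately nucleating Q_B population."""
    return dk.simulate_population(
        nucleation=dk.NucleationParams(k=0.05, n=1.0), n_cells=20_000, seed=7
    )


@pytest.fixture(scope="session")
def nucleated_table(nucleated_sample, spillover):
    table, _, _ = dk.process_events(nucleated_sample.events, spillover)
    return table


def positive_truth_curve(sample, edges, statuses=("positive", "intermediate")):
    return dk.truth_fraction_positive(sample, np.asarray(edges, float), statuses=statuses)
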