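import numpy as np
import pytest

import paleomacro as pm


def random_matrix(seed: int, n_taxa: int = 7, n_chars: int = 10,
                  n_states: int = 3, missing: float = 0.0) -> pm.CharacterMatrix:
    """Small i.i.d. random character matrix for search oracles."""
    rng = np.random.default_rng(seed)
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_chars):
            if missing and rng.random() < missing:
                row.append(frozenset())
            else:
                row.append(frozenset({int(rng.integers(0, n_states))}))
        cells.append(row)
    return pm.CharacterMatrix(taxa, cells)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated study system shared across tests: tree with ranges,
    Mk matrix, and trend traits."""
    cfg = pm.SimConfig(seed=11, n_taxa=10, n_characters=60)
    timetree, records = pm.simulate_tree_with_ranges(cfg)
    matrix = pm.simulate_matrix(timetree, cfg)
    traits = pm.simulate_traits(timetree, cfg)
    return cfg, timetree, records, matrix, traits
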