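"""Seed-stream management.

A single root seed drives every stage of a run.  Each component draws from
its own child stream, derived from the root by a fixed, named offset, so a
stage can be re-run in isolation and still see exactly the bits it saw in
the full pipeline.
"""

from __future__ import annotations

import numpy as np

# Fixed offsets: never renumber, or archived runs stop being reproducible.
_COMPONENT_OFFSETS = {
    "design": 1,
    "behavior": 2,
    "epochs_encoding": 3,
    "epochs_retrieval": 4,
    "permutation": 5,
    "simulation": 6,
}


def component_seed_sequence(seed: int, component: str) -> np.random.SeedSequence:
    """SeedSequence for a named pipeline component under a root seed."""
    try:
        offset = _COMPONENT_OFFSETS[component]
    except KeyError:
        raise KeyError(
            f"unknown RNG component {component!r}; "
            f"known: {sorted(_COMPONENT_OFFSETS)}"
        ) from None
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(offset,))


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Generator for a named pipeline component under a root seed."""
    return np.random.default_rng(component_seed_sequence(seed, component))
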