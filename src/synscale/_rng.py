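"""Seeding helpers.

Every stochastic entry point accepts either an integer seed, a
``numpy.random.Generator`` or ``None``.  Generators built from the same
integer seed reproduce bit-identical output; substreams for independent
components (individual synapses, electrode noise, cells) are derived by
spawning ``SeedSequence`` children so that adding components never perturbs
the draws of existing ones.
"""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce into a SeedSequence (Generators are not accepted here because
    their state cannot be split reproducibly)."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError(
            "this entry point derives independent substreams and therefore "
            "needs an integer seed or a SeedSequence, not a Generator"
        )
    return np.random.SeedSequence(seed)
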