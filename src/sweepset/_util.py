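"""Small shared helpers: seed derivation and validation errors."""
from __future__ import annotations

import numpy as np

# Stage indices for the declared seed-derivation scheme: every consumer of
# randomness draws its seed as derive_seed(master, STREAM[stage]), so stages
# are decoupled (changing the RNG consumption of one stage never perturbs
# another) while the whole pipeline stays reproducible from one integer.
STREAMS = {
    "synth": 0,
    "haplostats": 1,
    "matching": 2,
    "nulls": 3,
    "wfsim": 4,
    "pipeline": 5,
}


def derive_seed(master_seed: int, stream: int | str) -> int:
    """Derive a per-stage seed (< 2**31) from a single master seed."""
    if isinstance(stream, str):
        stream = STREAMS[stream]
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


class ValidationError(ValueError):
    """Raised when an input file or table violates a loader invariant."""
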