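"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def spawn_seeds(root_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one root seed.

    All randomness in the package flows through a single root seed; stages
    and replicate loops draw their own child seeds from it so results are
    reproducible end to end.
    """
    ss = np.random.SeedSequence(int(root_seed))
    return np.array(
        [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(int(n))]
    )
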