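"""Deterministic seed derivation.

All randomness in a run flows from a single integer ``run_seed``. Stage-level
seeds are derived by hashing ``(run_seed, *stage_labels)`` with a stable
cryptographic hash, so adding a stage never perturbs the seeds of existing
stages and every derived seed fits in 31 bits (safe for every RNG backend).
"""

from __future__ import annotations

import hashlib


def derive_seed(run_seed: int, *stage: object) -> int:
    """Derive a stage seed from the run seed and a label path.

    Parameters
    ----------
    run_seed:
        The top-level seed of the run.
    stage:
        Any sequence of strings/ints identifying the stage, e.g.
        ``("iteration", 12, "dropout")``.
    """
    key = ":".join([str(run_seed), *[str(s) for s in stage]])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
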