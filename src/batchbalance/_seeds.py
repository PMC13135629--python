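"""Deterministic sub-seed derivation.

One user-facing master seed drives several independent random streams
(annealer moves, each covariate's Monte-Carlo Fisher null, cohort
simulation replicates).  Sub-seeds are derived by stable hashing so that
streams never alias and results are reproducible across processes.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, label: str) -> int:
    """Derive a stream-specific seed from ``master`` and a text label.

    Returns an integer in ``[0, 2**31)``; stable across Python processes
    (unlike built-in ``hash``).
    """
    digest = hashlib.blake2b(f"{master}|{label}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
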