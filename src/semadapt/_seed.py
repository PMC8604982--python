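"""Deterministic seed derivation for pipeline stages.

A single global seed is split into independent per-stage substreams so that
rerunning one stage reproduces its output without consuming random numbers
meant for another stage.
"""

from __future__ import annotations

import hashlib

__all__ = ["stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable 31-bit seed for ``stage`` from ``global_seed``.

    The mapping is a SHA-256 hash of ``"{global_seed}:{stage}"``; it is
    platform-independent and insensitive to the order in which stages run.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
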