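"""Shared helpers: warning category and deterministic seed fan-out."""

from __future__ import annotations

import warnings


class TRMWarning(UserWarning):
    """Non-fatal data loss during parsing/filtering (dropped rows, unmapped ids)."""


def warn(message: str) -> None:
    warnings.warn(message, TRMWarning, stacklevel=3)


# Per-stage offsets so one user seed reproduces every stage independently.
STAGE_OFFSETS = {
    "ppi": 101,
    "enrichment": 211,
    "expression": 307,
    "study": 401,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a single user seed (kept below 2**31)."""
    return (int(seed) * 1009 + STAGE_OFFSETS[stage]) % (2**31 - 1)
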