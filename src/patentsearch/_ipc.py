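"""International Patent Classification code handling.

IPC codes (e.g. ``C07D 239/47``) are hierarchical: section letter, class
digits, subclass letter, then main group / subgroup.  The engine indexes and
queries them as prefixed pseudo-tokens at two granularities: the 4-character
subclass and the full compacted code.
"""

from __future__ import annotations

import re

IPC_PREFIX = "IPC_"


def normalize_ipc_code(raw: str) -> set[str]:
    """Turn one raw IPC code into its set of index tokens.

    Uppercases, removes internal whitespace, and emits the subclass token
    (first 4 characters) plus the full-code token; the two coincide for a
    bare subclass like ``C07D``.  Codes shorter than 4 characters after
    compaction are rejected.
    """
    compact = re.sub(r"\s+", "", raw).upper()
    if len(compact) < 4:
        raise ValueError(f"IPC code too short after compaction: {raw!r}")
    return {IPC_PREFIX + compact[:4], IPC_PREFIX + compact}
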