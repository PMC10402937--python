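"""Small shared helpers: seed derivation, rounding, config hashing."""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping

import numpy as np


def spawn_seed(base_seed: int, *keys: object) -> int:
    """Derive a stable child seed (< 2**31) from a base seed and string keys.

    Used so that every pipeline stage gets its own reproducible stream and a
    stage can be re-run in isolation with the same randomness.
    """
    material = f"{int(base_seed)}|" + "|".join(str(k) for k in keys)
    digest = hashlib.sha256(material.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties going away from zero (report style)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def config_hash(obj: Mapping[str, Any] | list | tuple) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray, tuple, set)):
            return list(o)
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=_default)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]
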