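"""Small shared helpers: canonicalization, float formatting, seed derivation."""

from __future__ import annotations

import json
import math
from typing import Any


def canonical(s: str) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    return " ".join(str(s).split())


def round_sig(x: float, sig: int = 6) -> float:
    """Round to `sig` significant digits (stable text formatting for reports)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _roundtree(obj: Any, sig: int = 6) -> Any:
    if isinstance(obj, float):
        return round_sig(obj, sig)
    if isinstance(obj, dict):
        return {k: _roundtree(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtree(v, sig) for v in obj]
    return obj


def write_json(path, obj: Any, sig: int = 6) -> None:
    """Serialize with sorted keys and floats at 6 significant digits.

    Fixed formatting makes repeated runs byte-identical, which the pipeline
    manifest hash relies on.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_roundtree(obj, sig), fh, indent=2, sort_keys=True)
        fh.write("\n")


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed from one root seed; result always < 2**31."""
    h = root_seed & 0x7FFFFFFF
    for ch in stage:
        h = (h * 1000003 + ord(ch)) & 0x7FFFFFFF
    return h
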