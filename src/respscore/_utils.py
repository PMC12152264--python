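"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
import math
from typing import Any

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with halves going toward +inf (0.125 -> 0.13, -0.115 -> -0.11).

    This is the convention that reproduces printed two-decimal scores such
    as -0.39 + 0.005*55 = -0.115 -> -0.11.
    """
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from a master generator."""
    return int(rng.integers(0, 2**31 - 1))


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


class DegenerateInputError(ValueError):
    """Raised when an estimator receives input it cannot meaningfully use."""
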