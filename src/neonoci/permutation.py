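"""Shared container for permutation-based tests.

Two p-value conventions are used and always recorded:

* ``exhaustive`` — the null is fully enumerated (sign patterns or
  permutations, identity included); p = c / total where c counts null
  statistics at least as extreme as the observed one.
* ``monte_carlo`` — B random draws; p = (1 + c) / (1 + B), which is valid
  (never anti-conservative) and never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PermResult:
    """An observed statistic with its permutation null and p-value."""

    statistic: float
    null: np.ndarray
    p: float
    tails: str                 # "one" | "two"
    convention: str            # "exhaustive" | "monte_carlo"
    n_perm: int
    seed: int | None = None

    def __post_init__(self):
        self.null = np.asarray(self.null, dtype=float)
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.convention not in ("exhaustive", "monte_carlo"):
            raise ValueError("unknown p-value convention")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p": float(self.p),
            "tails": self.tails,
            "convention": self.convention,
            "n_perm": int(self.n_perm),
            "seed": None if self.seed is None else int(self.seed),
        }


def mc_p(count_extreme: int, n_perm: int) -> float:
    return (1.0 + count_extreme) / (1.0 + n_perm)


def exhaustive_p(count_extreme: int, total: int) -> float:
    return count_extreme / total
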