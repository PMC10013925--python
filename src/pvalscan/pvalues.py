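"""Container for a set of unadjusted p-values.

A p-value set is the unit of analysis throughout the package: one set per
differential-expression contrast, typically ~20,000 values (one per genomic
feature). Values may contain NaN before validation; ground-truth labels are
carried only by synthetic sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class PValueSet:
    """A vector of unadjusted p-values with source metadata.

    Parameters
    ----------
    values : ndarray
        Raw p-values; NaN permitted prior to validation.
    source_column : str
        Name of the table column (or simulator) the set came from.
    is_alternative : ndarray of bool, optional
        Ground-truth labels for synthetic sets: True where the value was
        drawn from the alternative law. None for mined sets.
    meta : dict
        Free-form provenance (seed, generator config, file path, ...).
    """

    values: np.ndarray
    source_column: str = ""
    is_alternative: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("p-value set must be one-dimensional")
        if self.is_alternative is not None:
            self.is_alternative = np.asarray(self.is_alternative, dtype=bool)
            if self.is_alternative.shape != self.values.shape:
                raise ValueError("labels must align with values")

    @property
    def n(self) -> int:
        """Number of finite values (NaN excluded)."""
        return int(np.isfinite(self.values).sum())

    def finite(self) -> np.ndarray:
        """Return the finite values only."""
        return self.values[np.isfinite(self.values)]
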