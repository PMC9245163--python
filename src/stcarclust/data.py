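"""Core data container for areal count panels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, List, Optional, Sequence

import numpy as np

__all__ = ["CountData"]


@dataclass
class CountData:
    """Observed and expected disease counts on an ``n x T`` areal panel.

    ``Y[i, t]`` is the observed count for area ``i`` in period ``t`` and
    ``E[i, t] > 0`` the matching expected count from indirect
    standardisation, so ``Y/E`` is the standardised incidence ratio.  ``X``
    optionally holds ``p`` covariates per cell (``n x T x p``); the default
    analyses are intercept-only.
    """

    Y: np.ndarray
    E: np.ndarray
    X: Optional[np.ndarray] = None
    area_ids: Optional[List[Hashable]] = None
    times: Optional[List[Hashable]] = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.E = np.asarray(self.E, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape != self.E.shape:
            raise ValueError("Y and E must be matching n x T matrices")
        if np.any(self.E <= 0):
            raise ValueError("expected counts must be strictly positive")
        if np.any(self.Y < 0) or not np.allclose(self.Y, np.round(self.Y)):
            raise ValueError("observed counts must be non-negative integers")
        self.Y = np.round(self.Y).astype(np.int64)
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape[:2] != self.Y.shape:
                raise ValueError("X must be n x T x p")
        if self.area_ids is None:
            self.area_ids = list(range(self.n))
        if self.times is None:
            self.times = list(range(1, self.T + 1))

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return 0 if self.X is None else self.X.shape[2]

    def sir(self) -> np.ndarray:
        """Standardised incidence ratio ``Y / E``."""
        return self.Y / self.E
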