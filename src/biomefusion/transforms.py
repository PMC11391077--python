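"""Monotone transforms that make the bioclimatic fields roughly normal.

Fractional variables (FPC, evergreen/tropical/temperate fractions) use a
logit; vegetation height uses a logit of ``H / 130`` since ~130 m is the
hydrological limit of tree height; GDD uses ``log(GDD + 1)`` for its
[0, inf) range.  Bias correction, and the synthetic bias injection, both
operate in these transformed spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VARIABLES

__all__ = ["VariableTransform", "default_transforms"]


@dataclass(frozen=True)
class VariableTransform:
    """Strictly monotone map between a bounded physical range and the line.

    kind:
        ``"logit"``      — logit((x - lower)/(upper - lower)), for
                           fractions and for bounded height;
        ``"log-positive"`` — log(x + offset), for GDD-like variables.
    eps:
        clip margin keeping values strictly inside an open domain before
        a logit (fractions of the scaled range).
    """

    kind: str
    lower: float = 0.0
    upper: float = 1.0
    offset: float = 1.0
    eps: float = 1e-6

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "logit":
            p = (x - self.lower) / (self.upper - self.lower)
            p = np.clip(p, self.eps, 1.0 - self.eps)
            return np.log(p / (1.0 - p))
        if self.kind == "log-positive":
            return np.log(np.maximum(x, 0.0) + self.offset)
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def invert(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "logit":
            p = 1.0 / (1.0 + np.exp(-t))
            return self.lower + p * (self.upper - self.lower)
        if self.kind == "log-positive":
            return np.maximum(np.exp(t) - self.offset, 0.0)
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def clip_physical(self, x):
        """Clip raw values to the transform's open domain."""
        x = np.asarray(x, dtype=float)
        if self.kind == "logit":
            span = self.upper - self.lower
            return np.clip(x, self.lower + self.eps * span, self.upper - self.eps * span)
        return np.maximum(x, 0.0)


def default_transforms(height_limit: float = 130.0) -> dict[str, VariableTransform]:
    """Per-variable transforms keyed by the canonical variable names."""
    tr = {
        name: VariableTransform(kind="logit")
        for name in ("fpc", "evergreen", "tropical", "temperate")
    }
    tr["height"] = VariableTransform(kind="logit", lower=0.0, upper=height_limit)
    tr["gdd"] = VariableTransform(kind="log-positive", offset=1.0)
    assert set(tr) == set(VARIABLES)
    return tr
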