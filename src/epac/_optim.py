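"""Minimal Adam optimizer over a list of named numpy arrays."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AdamState:
    """First/second-moment accumulators plus the step counter."""

    m: dict
    v: dict
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def for_params(cls, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> "AdamState":
        return cls(m={k: np.zeros_like(p) for k, p in params.items()},
                   v={k: np.zeros_like(p) for k, p in params.items()},
                   t=0, beta1=beta1, beta2=beta2, eps=eps)

    def step(self, params: dict, grads: dict, lr: float) -> None:
        """One in-place Adam descent step along ``grads``."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2)
                                                   + self.eps)
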