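"""Bounded FIFO experience store with seeded uniform minibatch sampling."""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import List

import numpy as np


@dataclass
class Transition:
    """One experience tuple (s, a, r, s', terminal)."""

    s: np.ndarray
    a: int
    r: float
    s_next: np.ndarray
    terminal: bool

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.s_next = np.asarray(self.s_next, dtype=float)
        if self.s.shape != self.s_next.shape:
            raise ValueError("state and next-state dimensions differ")


class NotReadyError(RuntimeError):
    """Raised when a minibatch is requested before enough transitions exist."""


class ReplayBuffer:
    """Ring buffer of transitions; oldest entry is evicted first.

    Sampling draws a minibatch uniformly without replacement from the
    buffer's own seeded generator, so runs replay identically for a
    given seed.
    """

    def __init__(self, capacity: int, seed: int = 0):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._storage: deque = deque(maxlen=capacity)
        self._rng = np.random.default_rng(seed)

    def __len__(self) -> int:
        return len(self._storage)

    def __iter__(self):
        return iter(self._storage)

    def push(self, t: Transition) -> "ReplayBuffer":
        self._storage.append(t)
        return self

    def is_ready(self, k: int) -> bool:
        return len(self._storage) >= k

    def sample(self, k: int) -> List[Transition]:
        if len(self._storage) < k:
            raise NotReadyError(
                f"buffer holds {len(self._storage)} < batch size {k}")
        idx = self._rng.choice(len(self._storage), size=k, replace=False)
        return [self._storage[i] for i in idx]

    def sample_arrays(self, k: int):
        """Sampled minibatch as stacked arrays (S, a, r, S_next, terminal)."""
        batch = self.sample(k)
        return (np.stack([t.s for t in batch]),
                np.array([t.a for t in batch], dtype=int),
                np.array([t.r for t in batch], dtype=float),
                np.stack([t.s_next for t in batch]),
                np.array([t.terminal for t in batch], dtype=bool))

    def dump(self, path) -> None:
        """Debug dump as JSON lines (one transition per line)."""
        with open(path, "w") as fh:
            for t in self._storage:
                fh.write(json.dumps({
                    "s": t.s.tolist(), "a": int(t.a), "r": float(t.r),
                    "s_next": t.s_next.tolist(), "terminal": bool(t.terminal),
                }) + "\n")

    @classmethod
    def load(cls, path, capacity: int, seed: int = 0) -> "ReplayBuffer":
        buf = cls(capacity, seed)
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                buf.push(Transition(np.array(d["s"]), d["a"], d["r"],
                                    np.array(d["s_next"]), d["terminal"]))
        return buf
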