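"""The per-execution record: one row of the sweep output table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import build_init_string, parse_init_string

#: the 16 node-state column labels, "0000" .. "1111"
NODE_STATES = tuple(format(v, "04b") for v in range(16))


@dataclass
class RunRecord:
    """One circuit execution: register initialization, mark, and the 16
    node-state hit counts out of ``shots`` measurements."""

    aux: str
    coin: str
    node: str
    theta: str
    mark: str
    counts: np.ndarray
    shots: int = 1024

    def __post_init__(self):
        # validates widths/charset as a side effect
        build_init_string(self.aux, self.coin, self.node, self.theta)
        if len(self.mark) != 4 or any(c not in "01" for c in self.mark):
            raise ValueError(f"mark must be 4 binary characters, got {self.mark!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (16,):
            raise ValueError(f"expected 16 counts, got shape {self.counts.shape}")
        if self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if int(self.counts.sum()) != self.shots:
            raise ValueError(
                f"counts sum to {int(self.counts.sum())}, expected {self.shots} shots"
            )

    @property
    def init_string(self) -> str:
        return build_init_string(self.aux, self.coin, self.node, self.theta)

    @classmethod
    def from_init_string(
        cls, init: str, mark: str, counts, shots: int = 1024
    ) -> "RunRecord":
        aux, coin, node, theta = parse_init_string(init)
        return cls(aux, coin, node, theta, mark, counts, shots)

    def marked_hits(self) -> int:
        """Hits on the marked node state."""
        return int(self.counts[int(self.mark, 2)])
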