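"""Binned observables: histograms, free-energy profiles, g(r)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Profile"]


@dataclass
class Profile:
    """A binned observable with explicit normalization semantics.

    ``kind`` is one of ``probability`` (values sum to 1), ``free_energy_kBT``
    (zeroed at the bulk plateau, masked bins are NaN), ``g_of_r``
    (dimensionless, non-negative) or ``raw_count`` / ``raw_sum``.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    kind: str = "raw_count"
    n_samples: int = 0
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_edges) != len(self.values) + 1:
            raise ValueError("need len(bin_edges) == len(values) + 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "value": self.values,
        })
        if self.stderr is not None:
            df["stderr"] = self.stderr
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kind: str = "raw_count") -> "Profile":
        df = pd.read_csv(path, sep="\t")
        edges = np.append(df["bin_left"].to_numpy(), df["bin_right"].iloc[-1])
        stderr = df["stderr"].to_numpy() if "stderr" in df else None
        return cls(edges, df["value"].to_numpy(), kind=kind, stderr=stderr)
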