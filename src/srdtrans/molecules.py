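"""Per-frame emitter records: localization ground truth and detection output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MoleculeSet"]


@dataclass
class MoleculeSet:
    """Emitter records: frame index, position in nm, photon count."""

    frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    x_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    photons: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        n = len(self.frame)
        if not (len(self.x_nm) == len(self.y_nm) == len(self.photons) == n):
            raise ValueError("molecule record columns have unequal lengths")
        self.frame = np.asarray(self.frame, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.photons = np.asarray(self.photons, dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def in_frame(self, k: int) -> "MoleculeSet":
        sel = self.frame == k
        return MoleculeSet(self.frame[sel], self.x_nm[sel], self.y_nm[sel], self.photons[sel])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame, "x_nm": self.x_nm, "y_nm": self.y_nm, "photons": self.photons}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MoleculeSet":
        df = pd.read_csv(path)
        return cls(
            frame=df["frame"].to_numpy(),
            x_nm=df["x_nm"].to_numpy(),
            y_nm=df["y_nm"].to_numpy(),
            photons=df["photons"].to_numpy(),
        )

    @classmethod
    def concatenate(cls, sets: list["MoleculeSet"]) -> "MoleculeSet":
        if not sets:
            return cls()
        return cls(
            frame=np.concatenate([s.frame for s in sets]),
            x_nm=np.concatenate([s.x_nm for s in sets]),
            y_nm=np.concatenate([s.y_nm for s in sets]),
            photons=np.concatenate([s.photons for s in sets]),
        )
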