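"""Per-cell molecule-count distributions — the unit of fitting."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountDistribution:
    """Single-cell protein (and optionally mRNA) counts at one condition."""

    protein: np.ndarray
    mrna: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.protein = np.asarray(self.protein, dtype=np.int64)
        if self.protein.size < 1:
            raise ValueError("need at least one cell")
        if np.any(self.protein < 0):
            raise ValueError("counts must be non-negative")
        if self.mrna is not None:
            self.mrna = np.asarray(self.mrna, dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.protein.size

    def to_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"cell_id": np.arange(self.n_cells),
                              "species": "protein",
                              "count": self.protein})]
        if self.mrna is not None:
            rows.append(pd.DataFrame({"cell_id": np.arange(self.n_cells),
                                      "species": "mrna",
                                      "count": self.mrna}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        for key, val in self.metadata.items():
            df.attrs[key] = val
        with open(path, "w") as fh:
            for key, val in self.metadata.items():
                fh.write(f"# {key}: {val}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountDistribution":
        metadata = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                metadata[key.strip()] = _parse(val.strip())
                body_start = i + 1
            else:
                break
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        protein = df.loc[df.species == "protein", "count"].to_numpy()
        mrna_rows = df.loc[df.species == "mrna", "count"]
        mrna = mrna_rows.to_numpy() if len(mrna_rows) else None
        return cls(protein=protein, mrna=mrna, metadata=metadata)


def _parse(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text
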