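"""Discrete morphological trait matrices (input to Mk ancestral-state
reconstruction). Cells are small integer state codes; -1 marks missing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = ["TraitMatrix"]


@dataclass
class TraitMatrix:
    taxa: list[str]
    characters: list[str]
    states: np.ndarray            # int16 (n_taxa, n_chars); -1 = missing
    state_counts: list[int]       # size of each character's state space
    true_internal: Optional[dict] = None   # clade (frozenset of leaves) -> state row
    generating_tree: Optional[object] = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("states shape mismatch")
        for j, k in enumerate(self.state_counts):
            col = self.states[:, j]
            obs = col[col >= 0]
            if obs.size and obs.max() >= k:
                raise ValueError(f"character {self.characters[j]}: state out of range")

    def observed_state_count(self, j: int) -> int:
        col = self.states[:, j]
        return int(np.unique(col[col >= 0]).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.taxa, columns=self.characters)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        states = df.to_numpy(dtype=np.int16)
        counts = [int(states[:, j][states[:, j] >= 0].max()) + 1
                  for j in range(states.shape[1])]
        return cls(list(df.index), list(df.columns), states, counts)

    @classmethod
    def from_nexus(cls, path) -> "TraitMatrix":
        mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        taxa = [t.label for t in mat.taxon_namespace]
        n_chars = max(len(mat[t]) for t in mat.taxon_namespace)
        states = np.full((len(taxa), n_chars), -1, dtype=np.int16)
        for i, t in enumerate(mat.taxon_namespace):
            for j, cell in enumerate(mat[t]):
                sym = str(cell.symbol)
                states[i, j] = int(sym) if sym.isdigit() else -1
        counts = [max(int(states[:, j].max()) + 1, 2) for j in range(n_chars)]
        chars = [f"char{j+1}" for j in range(n_chars)]
        return cls(taxa, chars, states, counts)
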