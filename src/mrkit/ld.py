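"""Pairwise linkage-disequilibrium (r^2) lookup used by LD clumping.

Real-panel LD computation is out of scope; r^2 values come either from a
user-supplied file (3-column ``id1  id2  r2`` pairs, or a dense matrix with
an ID header) or from the synthetic-data generator.  A source may declare
itself *complete* over its variant set, in which case an unstored pair is
taken as r^2 = 0; an incomplete source raises on unstored pairs so that
independence is never silently assumed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, MissingLDError


class LDInfo:
    """Symmetric pairwise r^2 lookup with diagonal 1."""

    def __init__(self, pairs=None, variants: Iterable[str] = (), complete: bool = False):
        self._r2 = {}
        self.variants = set(variants)
        self.complete = complete
        for id1, id2, r2 in pairs or []:
            self.add(id1, id2, r2)

    def add(self, id1: str, id2: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"r2({id1},{id2})={r2} outside [0,1]")
        self.variants.update((id1, id2))
        if id1 != id2:
            self._r2[frozenset((id1, id2))] = r2

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variants

    def r2(self, id1: str, id2: str) -> float:
        if id1 == id2:
            return 1.0
        key = frozenset((id1, id2))
        if key in self._r2:
            return self._r2[key]
        if self.complete and id1 in self.variants and id2 in self.variants:
            return 0.0
        raise MissingLDError(f"no r2 entry for pair ({id1}, {id2})")

    @classmethod
    def from_file(cls, path, complete: bool = False) -> "LDInfo":
        """Read either the 3-column pair format or a dense matrix.

        A dense matrix (first column = variant id, remaining columns named
        by variant id) is always treated as complete over its variants.
        """
        path = Path(path)
        head = pd.read_csv(path, sep="\t", nrows=1)
        if list(head.columns[:3]) == ["id1", "id2", "r2"]:
            df = pd.read_csv(path, sep="\t")
            return cls(pairs=df[["id1", "id2", "r2"]].itertuples(index=False),
                       complete=complete)
        mat = pd.read_csv(path, sep="\t", index_col=0)
        if list(mat.index) != list(mat.columns):
            raise ConfigurationError(f"{path}: matrix rows and columns disagree")
        vals = mat.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T):
            raise ConfigurationError(f"{path}: LD matrix is not symmetric")
        info = cls(variants=mat.index, complete=True)
        ids = list(mat.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if vals[i, j] != 0.0:
                    info.add(ids[i], ids[j], vals[i, j])
        return info

    def to_file(self, path) -> Path:
        path = Path(path)
        rows = [(min(k), max(k), v) for k, v in self._r2.items()]
        pd.DataFrame(rows, columns=["id1", "id2", "r2"]).sort_values(
            ["id1", "id2"]
        ).to_csv(path, sep="\t", index=False)
        return path
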