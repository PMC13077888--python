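"""Core-proteome average amino acid identity (cpAAI) under pairwise deletion.

cpAAI between two strains is the percentage of identical residues over the
columns of the concatenated alignment where *neither* strain has missing data
(gap '-' or unknown 'X'). Treating X as missing is what makes the all-X gap
proteins for absent markers signal-free: a padded marker contributes no
compared sites for that strain.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import SuperMatrix

DEFAULT_MISSING = "-X"


def pairwise_identity(row_a: str, row_b: str,
                      missing_chars: str = DEFAULT_MISSING) -> tuple[int, int]:
    """(matches, compared) over columns where neither row is missing."""
    if len(row_a) != len(row_b):
        raise ValueError(f"row length mismatch: {len(row_a)} vs {len(row_b)}")
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")
    missing = np.array([c.encode() for c in missing_chars], dtype="S1")
    ok = ~(np.isin(a, missing) | np.isin(b, missing))
    return int(np.count_nonzero(ok & (a == b))), int(np.count_nonzero(ok))


@dataclass
class CpaaiMatrix:
    """Symmetric percent-identity matrix plus compared-site counts."""

    strain_order: list[str]
    values: np.ndarray          # percent, diagonal 100
    compared_sites: np.ndarray  # int counts, symmetric

    def get(self, a: str, b: str) -> float:
        i, j = self.strain_order.index(a), self.strain_order.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_order,
                            columns=self.strain_order)

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.strain_order):
            for j in range(i + 1, len(self.strain_order)):
                recs.append((a, self.strain_order[j],
                             round(float(self.values[i, j]), 2),
                             int(self.compared_sites[i, j])))
        return pd.DataFrame(recs, columns=["a", "b", "cpaai", "compared_sites"])

    def write(self, prefix) -> None:
        self.to_dataframe().round(2).to_csv(f"{prefix}.csv")
        self.to_long().to_csv(f"{prefix}.long.tsv", sep="\t", index=False)

    @classmethod
    def read_csv(cls, path) -> "CpaaiMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(strain_order=list(df.index), values=df.to_numpy(float),
                   compared_sites=np.zeros(df.shape, dtype=int))


def cpaai_matrix(sm: SuperMatrix,
                 missing_chars: str = DEFAULT_MISSING) -> CpaaiMatrix:
    """All-pairs cpAAI for a supermatrix.

    A pair with zero comparable sites (disjoint placeholder patterns) is an
    error: no identity can be defined for it.
    """
    n = len(sm.strain_order)
    if n < 2:
        raise ValueError("cpAAI needs at least 2 strains")
    chars = np.frombuffer("".join(sm.rows).encode(), dtype="S1").reshape(n, -1)
    chars = np.char.upper(chars)
    missing = np.array([c.encode() for c in missing_chars], dtype="S1")
    present = ~np.isin(chars, missing)
    values = np.full((n, n), 100.0)
    compared = np.zeros((n, n), dtype=np.int64)
    # self-comparison under pairwise deletion: the row's non-missing sites
    np.fill_diagonal(compared, present.sum(axis=1))
    for i in range(n):
        for j in range(i + 1, n):
            ok = present[i] & present[j]
            ncomp = int(np.count_nonzero(ok))
            if ncomp == 0:
                raise ValueError(
                    f"no comparable sites between {sm.strain_order[i]!r} and "
                    f"{sm.strain_order[j]!r}")
            nmatch = int(np.count_nonzero(ok & (chars[i] == chars[j])))
            values[i, j] = values[j, i] = 100.0 * nmatch / ncomp
            compared[i, j] = compared[j, i] = ncomp
    return CpaaiMatrix(strain_order=list(sm.strain_order), values=values,
                       compared_sites=compared)
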