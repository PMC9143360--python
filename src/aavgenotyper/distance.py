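"""Pairwise p-distances with pairwise deletion.

The p-distance between two aligned sequences is the proportion of differing
sites among *comparable* sites: columns where both sequences carry an
unambiguous residue (A/C/G/T for nucleotides, the 20 standard amino acids
for proteins). Gaps and ambiguity codes are excluded per pair (pairwise
deletion), not per column across the whole alignment, so every pair uses
the maximum amount of data available to it. No evolutionary-model
correction is applied: the genotype threshold is defined on raw proportions
of differing nucleotides.

A pair with zero comparable sites has an undefined distance, stored as NaN
(never silently 0) and excluded downstream with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .msa import Msa

logger = logging.getLogger(__name__)

Alphabet = Literal["nt", "aa"]

_NT_VALID = "ACGT"
_AA_VALID = "ACDEFGHIKLMNPQRSTVWY"
_INVALID = 255


def _encoder(alphabet: Alphabet) -> dict[str, int]:
    valid = _NT_VALID if alphabet == "nt" else _AA_VALID
    return {c: i for i, c in enumerate(valid)}


# char -> code lookup tables, built once
_TABLES: dict[str, np.ndarray] = {}
for _alpha in ("nt", "aa"):
    _t = np.full(256, _INVALID, dtype=np.uint8)
    for _c, _i in _encoder(_alpha).items():
        _t[ord(_c)] = _i
    _TABLES[_alpha] = _t


def encode(seq: str, alphabet: Alphabet = "nt") -> np.ndarray:
    """Encode a sequence as uint8 codes; gaps/ambiguities -> 255 (ignored)."""
    return _TABLES[alphabet][np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_msa(msa: Msa, alphabet: Alphabet = "nt") -> np.ndarray:
    """(n_records, alignment_length) uint8 code matrix."""
    return np.vstack([encode(s, alphabet) for s in msa.seqs])


class PDistance(NamedTuple):
    distance: float  # NaN when undefined
    comparable_sites: int


def p_distance(a: str, b: str, alphabet: Alphabet = "nt") -> PDistance:
    """p-distance between two equal-length aligned sequences.

    Returns ``(NaN, 0)`` when no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    ca, cb = encode(a, alphabet), encode(b, alphabet)
    valid = (ca != _INVALID) & (cb != _INVALID)
    n = int(valid.sum())
    if n == 0:
        return PDistance(float("nan"), 0)
    diff = int(((ca != cb) & valid).sum())
    return PDistance(diff / n, n)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts.

    ``values[i, j]`` is NaN where the distance is undefined (no comparable
    sites). ``comparable_sites`` is None for matrices transcribed from a
    printed table, where the underlying site counts are unknown.
    """

    labels: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.nan_to_num(np.diag(self.values)), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            fin = np.isfinite(self.values)
            if ((self.values < 0) & fin).any() or ((self.values > 1) & fin).any():
                raise ValueError("distances must lie in [0, 1]")
        if not _nan_symmetric(self.values):
            raise ValueError("matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def pairs(self):
        """Yield (label_i, label_j, distance) over unordered pairs i<j."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major (scipy condensed) order."""
        return self.values[np.triu_indices(len(self.labels), k=1)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path, decimals: int | None = None) -> None:
        """Square TSV: header row of labels, NaN written as ``NA``."""
        df = self.to_dataframe()
        if decimals is not None:
            df = df.round(decimals)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ValueError("row and column labels differ in distance TSV")
        return cls(labels, df.to_numpy(dtype=float))


def _nan_symmetric(m: np.ndarray) -> bool:
    a, b = m, m.T
    both = np.isnan(a) == np.isnan(b)
    close = np.isclose(a, b, equal_nan=True)
    return bool(both.all() and close.all())


def pairwise_matrix(msa: Msa, alphabet: Alphabet = "nt") -> DistanceMatrix:
    """All-pairs p-distance matrix (pairwise deletion) for an alignment.

    Vectorised over the full code matrix; for n records this computes
    n(n-1)/2 unordered pairs. Undefined pairs are stored as NaN and logged.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 records for a pairwise matrix")
    codes = encode_msa(msa, alphabet)
    return pairwise_matrix_from_codes(codes, list(msa.ids))


def pairwise_matrix_from_codes(
    codes: np.ndarray, labels: list[str]
) -> DistanceMatrix:
    """Distance matrix from a pre-encoded (n, L) uint8 code matrix."""
    valid = codes != _INVALID  # (n, L)
    # comparable sites per pair and mismatches per pair, via broadcasting
    comp = valid.astype(np.int32) @ valid.astype(np.int32).T
    n = codes.shape[0]
    diff = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        mism = (codes[i] != codes) & valid[i] & valid  # (n, L)
        diff[i] = mism.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comp > 0, diff / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(labels, d, comp)
    if dm.n_missing_pairs:
        logger.warning(
            "%d sequence pair(s) share no comparable sites; distances undefined",
            dm.n_missing_pairs,
        )
    return dm


class EvenOddSplit(NamedTuple):
    even: Msa  # alignment columns 2, 4, 6, ...
    odd: Msa  # alignment columns 1, 3, 5, ...


def even_odd_split(msa: Msa) -> EvenOddSplit:
    """Split an alignment into its even- and odd-numbered columns.

    Columns are counted 1-based, so the odd output starts with column 1.
    Interleaving odd and even columns reconstructs the input; the two
    halves are the classic negative control for distance-congruence scans
    (both halves sample the same evolutionary history, so any scatter
    between their distances is sampling noise, not recombination).
    """
    if msa.alignment_length < 2:
        raise ValueError("need at least 2 columns to split")
    odd = Msa(list(msa.ids), [s[0::2] for s in msa.seqs], list(msa.descriptions))
    even = Msa(list(msa.ids), [s[1::2] for s in msa.seqs], list(msa.descriptions))
    return EvenOddSplit(even=even, odd=odd)
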