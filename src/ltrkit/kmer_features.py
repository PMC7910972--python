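"""Alignment-free k-mer featurization of nucleotide sequences.

Features are concatenated k-mer counts for ``kmin <= k <= kmax`` (default
1..6, giving sum(4**k) = 5460 columns), laid out lexicographically within
each k-block with blocks concatenated in increasing k.  Windows containing
N are skipped.  A fit/transform pipeline standardizes columns and reduces
dimensionality with PCA; its state is fitted once on training rows and
reused for validation, test and new data.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_ALPHABET):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerSpec:
    """K-mer range and layout of the concatenated count vector."""

    kmin: int = 1
    kmax: int = 6

    def __post_init__(self) -> None:
        if not (1 <= self.kmin <= self.kmax):
            raise ValueError(f"require 1 <= kmin <= kmax, got ({self.kmin}, {self.kmax})")

    @property
    def dim(self) -> int:
        """Total feature dimension: sum of 4**k over the k range (5460 for 1..6)."""
        return sum(4**k for k in range(self.kmin, self.kmax + 1))

    def block_offset(self, k: int) -> int:
        """Start column of the k-block in the concatenated layout."""
        if not (self.kmin <= k <= self.kmax):
            raise ValueError(f"k={k} outside [{self.kmin}, {self.kmax}]")
        return sum(4**j for j in range(self.kmin, k))

    def block_slice(self, k: int) -> slice:
        off = self.block_offset(k)
        return slice(off, off + 4**k)

    def kmer_labels(self) -> list[str]:
        """All k-mers in layout order (mainly for reports; 5460 strings for 1..6)."""
        from itertools import product

        labels = []
        for k in range(self.kmin, self.kmax + 1):
            labels.extend("".join(p) for p in product(_ALPHABET, repeat=k))
        return labels


DEFAULT_SPEC = KmerSpec(1, 6)


def kmer_index(kmer: str, spec: KmerSpec = DEFAULT_SPEC) -> int:
    """0-based position of a k-mer in the concatenated lexicographic layout."""
    k = len(kmer)
    if not (spec.kmin <= k <= spec.kmax):
        raise ValueError(f"k-mer {kmer!r} has length {k} outside [{spec.kmin}, {spec.kmax}]")
    idx = 0
    for ch in kmer.upper():
        code = _BASE_CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"k-mer {kmer!r} contains character {ch!r} outside ACGT")
        idx = idx * 4 + int(code)
    return spec.block_offset(k) + idx


def kmer_vector(
    seq: str, spec: KmerSpec = DEFAULT_SPEC, normalize: bool = False
) -> np.ndarray:
    """Concatenated k-mer count vector of one sequence.

    Windows containing N (or any non-ACGT character) are skipped.  With
    ``normalize``, each k-block is divided by its number of valid windows
    (counts become frequencies); all-invalid blocks stay zero.
    """
    if not seq:
        raise ValueError("cannot featurize an empty sequence")
    arr = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    L = arr.size
    out = np.zeros(spec.dim, dtype=np.float64)
    valid = arr >= 0
    safe = np.where(valid, arr, 0)
    for k in range(spec.kmin, spec.kmax + 1):
        n_win = L - k + 1
        if n_win <= 0:
            continue
        codes = np.zeros(n_win, dtype=np.int64)
        ok = np.ones(n_win, dtype=bool)
        for j in range(k):
            codes = codes * 4 + safe[j : j + n_win]
            ok &= valid[j : j + n_win]
        counts = np.bincount(codes[ok], minlength=4**k).astype(np.float64)
        if normalize:
            total = ok.sum()
            if total > 0:
                counts /= total
        out[spec.block_slice(k)] = counts
    return out


def kmer_matrix(
    sequences: Iterable[str], spec: KmerSpec = DEFAULT_SPEC, normalize: bool = False
) -> np.ndarray:
    """Stack kmer_vector over a collection of sequences (rows = elements)."""
    return np.vstack([kmer_vector(s, spec, normalize=normalize) for s in sequences])


class NotFittedError(RuntimeError):
    """transform requested before fit."""


@dataclass
class FeaturePipeline:
    """Standardization + PCA with strict fit/transform separation.

    ``n_components`` may be a variance fraction in (0, 1) (default 0.95) or a
    fixed integer count; ``max_components`` caps the retained count either
    way.  Zero-variance columns on the training rows are dropped (logged)
    before scaling so standardization never divides by zero.  ``whiten``
    rescales PCA scores to unit variance — recommended when the scores feed
    a neural network, whose softmax saturates on eigenvalue-scale inputs.
    """

    n_components: float | int = 0.95
    max_components: int | None = None
    whiten: bool = False
    _keep: np.ndarray | None = field(default=None, repr=False)
    _scaler: StandardScaler | None = field(default=None, repr=False)
    _pca: PCA | None = field(default=None, repr=False)

    @property
    def fitted(self) -> bool:
        return self._pca is not None

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit requires a 2-D matrix with at least 2 rows")
        variances = X.var(axis=0)
        keep = variances > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d zero-variance feature columns", n_dropped)
        if not keep.any():
            raise ValueError(
                "degenerate input: every feature column is constant on the training rows"
            )
        self._keep = keep
        self._scaler = StandardScaler()
        Xs = self._scaler.fit_transform(X[:, keep])
        n_comp: float | int = self.n_components
        limit = min(Xs.shape[0], Xs.shape[1])
        if isinstance(n_comp, int):
            n_comp = min(n_comp, limit)
        if self.max_components is not None and not isinstance(n_comp, int):
            # resolve the variance fraction first, then cap
            probe = PCA(n_components=n_comp, svd_solver="full")
            probe.fit(Xs)
            n_comp = min(probe.n_components_, self.max_components, limit)
            self._pca = PCA(n_components=n_comp, svd_solver="full", whiten=self.whiten)
            self._pca.fit(Xs)
            return self._pca.transform(Xs)
        if self.max_components is not None:
            n_comp = min(int(n_comp), self.max_components)
        self._pca = PCA(n_components=n_comp, svd_solver="full", whiten=self.whiten)
        return self._pca.fit_transform(Xs)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("FeaturePipeline.transform called before fit_transform")
        X = np.asarray(X, dtype=np.float64)
        return self._pca.transform(self._scaler.transform(X[:, self._keep]))

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("pipeline not fitted")
        return self._pca.explained_variance_ratio_

    @property
    def n_components_(self) -> int:
        if not self.fitted:
            raise NotFittedError("pipeline not fitted")
        return int(self._pca.n_components_)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Map reduced rows back to the scaled feature space (kept columns)."""
        if not self.fitted:
            raise NotFittedError("pipeline not fitted")
        return self._pca.inverse_transform(Z)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FeaturePipeline":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, FeaturePipeline):
            raise TypeError(f"{path} does not contain a FeaturePipeline")
        return obj


@dataclass
class FeatureMatrix:
    """Raw and reduced feature matrices for a set of elements."""

    ids: list[str]
    raw: np.ndarray
    spec: KmerSpec = DEFAULT_SPEC
    pipeline: FeaturePipeline | None = None
    reduced: np.ndarray | None = None

    @classmethod
    def from_elements(cls, elements: Sequence, spec: KmerSpec = DEFAULT_SPEC,
                      normalize: bool = False) -> "FeatureMatrix":
        ids = [el.id for el in elements]
        raw = kmer_matrix((el.sequence for el in elements), spec, normalize=normalize)
        return cls(ids=ids, raw=raw, spec=spec)
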