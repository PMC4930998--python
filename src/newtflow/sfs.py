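"""Joint site-frequency-spectrum container and text I/O.

The central object is :class:`Spectrum`, a dense ``(n1+1) x (n2+1)`` array of
per-cell values indexed by the derived-allele count in each population sample.
It is used both for observed SNP counts (integers, with an effective sequence
length ``L``) and for expected per-unit-theta spectra (floats).  The two
"corner" cells -- all-ancestral ``(0, 0)`` and all-derived ``(n1, n2)`` -- do
not correspond to observable polymorphisms and are always masked.

Spectra are serialized in the dadi text dialect: a header line
``"<n1+1> <n2+1> unfolded"``, a line of row-major cell values, and a line of
row-major mask indicators (1 = masked).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

__all__ = ["Spectrum", "corner_mask"]


def corner_mask(n1: int, n2: int) -> np.ndarray:
    """Boolean mask over an ``(n1+1, n2+1)`` spectrum with both corners masked."""
    mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = True
    mask[n1, n2] = True
    return mask


class Spectrum:
    """Unfolded two-population site frequency spectrum.

    Parameters
    ----------
    data:
        ``(n1+1, n2+1)`` array; cell ``(i, j)`` counts (or expects) sites with
        ``i`` derived copies in population 1 and ``j`` in population 2.
    mask:
        Boolean array of the same shape; ``True`` cells are excluded from all
        sums and likelihoods.  Defaults to the corner mask.
    pop_ids:
        Labels for (population 1, population 2).
    L:
        Effective sequence length in bp (callable sites, variant plus
        invariant) underlying an observed spectrum; ``None`` for expected
        spectra.
    """

    def __init__(self, data, mask=None, pop_ids=("Lv", "Lm"), L=None):
        self.data = np.array(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("spectrum data must be a 2-D array")
        n1, n2 = self.data.shape[0] - 1, self.data.shape[1] - 1
        if mask is None:
            mask = corner_mask(n1, n2)
        else:
            mask = np.array(mask, dtype=bool)
            if mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")
        self.mask = mask
        self.pop_ids = tuple(pop_ids)
        self.L = L

    # -- basic introspection ------------------------------------------------
    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    @property
    def shape(self):
        return self.data.shape

    def unmasked(self) -> np.ndarray:
        """Values of unmasked cells, row-major."""
        return self.data[~self.mask]

    def sum(self) -> float:
        """Total over unmasked cells."""
        return float(self.data[~self.mask].sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.data.copy(), self.mask.copy(), self.pop_ids, self.L)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"Spectrum(n1={self.n1}, n2={self.n2}, pop_ids={self.pop_ids}, "
            f"sum={self.sum():.6g}, L={self.L})"
        )

    # -- arithmetic used by mixtures and likelihoods ------------------------
    def _binary(self, other, op) -> "Spectrum":
        if isinstance(other, Spectrum):
            if other.shape != self.shape:
                raise ValueError("spectrum shapes differ")
            out = op(self.data, other.data)
            mask = self.mask | other.mask
        else:
            out = op(self.data, other)
            mask = self.mask.copy()
        return Spectrum(out, mask, self.pop_ids, self.L)

    def __add__(self, other):
        return self._binary(other, np.add)

    def __mul__(self, other):
        return self._binary(other, np.multiply)

    __rmul__ = __mul__

    # -- projection ---------------------------------------------------------
    def project(self, m1: int, m2: int) -> "Spectrum":
        """Hypergeometric projection down to smaller sample sizes ``(m1, m2)``.

        Each cell is redistributed according to the distribution of derived
        counts in a subsample drawn without replacement, the standard SFS
        projection.  Corners of the projected spectrum are re-masked.
        """
        if m1 > self.n1 or m2 > self.n2:
            raise ValueError("cannot project up")
        proj1 = _projection_matrix(self.n1, m1)
        proj2 = _projection_matrix(self.n2, m2)
        data = proj1 @ self.data @ proj2.T
        return Spectrum(data, None, self.pop_ids, self.L)

    def marginal(self, axis: int) -> np.ndarray:
        """One-population marginal spectrum (full-array sum over the other axis)."""
        return self.data.sum(axis=1 - axis)

    # -- I/O in the dadi text dialect ---------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n1 + 1} {self.n2 + 1} unfolded\n")
            fh.write(" ".join(repr(float(v)) for v in self.data.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path, pop_ids=("Lv", "Lm"), L=None) -> "Spectrum":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) < 3 or header[2] != "unfolded":
                raise ValueError(f"not an unfolded SFS file: {path}")
            shape = (int(header[0]), int(header[1]))
            data = np.array(fh.readline().split(), dtype=float).reshape(shape)
            mask = np.array(fh.readline().split(), dtype=int).reshape(shape).astype(bool)
        return cls(data, mask, pop_ids, L)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """Matrix ``P`` with ``P[i', i] = P(i' derived in subsample of m | i of n)``."""
    P = np.zeros((m + 1, n + 1))
    for i in range(n + 1):
        lo = max(0, m - (n - i))
        hi = min(m, i)
        ks = np.arange(lo, hi + 1)
        P[ks, i] = hypergeom.pmf(ks, n, i, m)
    return P
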