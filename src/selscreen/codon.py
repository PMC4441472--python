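"""Codon state space and the GY94 substitution process.

The sense-codon alphabet (universal genetic code, 61 states; stop codons
are excluded from the state space entirely) and the Goldman-Yang style
codon rate matrix used throughout: substitutions touching more than one
nucleotide have rate zero, single-nucleotide changes are weighted by the
transition/transversion ratio kappa, the nonsynonymous/synonymous ratio
omega, and the target codon's equilibrium frequency.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_table = CodonTable.unambiguous_dna_by_id[1]

#: Sense codons in TCAG lexical order (codeml's conventional ordering).
CODONS = tuple(
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in _table.stop_codons
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_table.stop_codons)

#: Amino acid translated by each sense codon, aligned with CODONS.
AMINO_ACIDS = tuple(_table.forward_table[c] for c in CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


@lru_cache(maxsize=1)
def _change_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nt change, transition, synonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transit = np.zeros_like(single)
    synon = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            k = diff[0]
            transit[i, j] = is_transition(ci[k], cj[k])
            synon[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return single, transit, synon


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(sequences: list[str], floor: float = 1e-6) -> np.ndarray:
    """Position-specific nucleotide frequency (F3x4) codon frequencies.

    Counts nucleotides at each codon position over all in-frame sequences
    (gaps and ambiguity codes skipped), builds codon frequencies as the
    product of the three positional frequencies, zeroes the stop codons
    and renormalizes. A small floor keeps rare codons off exact zero.
    """
    counts = np.zeros((3, 4))
    for seq in sequences:
        s = seq.upper()
        for i in range(0, len(s) - 2, 3):
            for pos in range(3):
                n = s[i + pos]
                if n in NUC_INDEX:
                    counts[pos, NUC_INDEX[n]] += 1
    if counts.sum() == 0:
        return equal_frequencies()
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, NUC_INDEX[c[0]]]
            * pos_freq[1, NUC_INDEX[c[1]]]
            * pos_freq[2, NUC_INDEX[c[2]]]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray, normalize: bool = True) -> np.ndarray:
    """GY94 61x61 rate matrix Q.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for
    single-nucleotide changes, 0 otherwise.  When ``normalize`` the matrix
    is scaled so branch lengths read as expected substitutions per codon.
    """
    single, transit, synon = _change_masks()
    q = np.zeros((N_CODONS, N_CODONS))
    q[single] = 1.0
    q[single & transit] *= kappa
    q[single & ~synon] *= omega
    q *= pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        rate = -(pi * np.diag(q)).sum()
        if rate > 0:
            q /= rate
    return q


def mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected flux -(sum_i pi_i q_ii) of the UNnormalized GY94 matrix.

    Site-class mixtures share one time scale: the mixture-weighted average
    of these per-class rates is the factor that converts branch lengths
    into expected substitutions per codon.
    """
    q = rate_matrix(kappa, omega, pi, normalize=False)
    return float(-(pi * np.diag(q)).sum())


class TransitionKernel:
    """Eigendecomposition of one GY94 matrix for fast P(t) on many branches.

    GY94 with frequencies pi is reversible, so D = diag(sqrt(pi)) Q
    diag(1/sqrt(pi)) is symmetric and P(t) = B exp(L t) B^{-1} with a real
    eigensystem; one decomposition serves every branch length.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, normalize: bool = True, rate_scale: float = 1.0):
        self.pi = pi
        q = rate_matrix(kappa, omega, pi, normalize=normalize)
        if rate_scale != 1.0:
            q = q / rate_scale
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = (sym + sym.T) / 2.0
        eigval, eigvec = np.linalg.eigh(sym)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[None, :].T  # diag(1/sqrt_pi) @ U
        self._right = (eigvec * sqrt_pi[:, None]).T  # U.T @ diag(sqrt_pi)

    def probability_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to one, small negatives clipped."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def probability_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for a vector of branch lengths -> (len(ts), 61, 61)."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be non-negative")
        w = np.exp(self._eigval[None, :] * ts[:, None])
        p = (self._left[None, :, :] * w[:, None, :]) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '-' for all-gap, 'X' otherwise."""
    c = codon.upper()
    if c in CODON_INDEX:
        return AMINO_ACIDS[CODON_INDEX[c]]
    if c == "---":
        return "-"
    if c in STOP_CODONS:
        return "*"
    return "X"
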