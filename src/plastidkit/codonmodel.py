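"""Goldman-Yang (GY94) codon substitution model machinery.

The rate matrix over the 61 sense codons of the standard genetic code is

    q_ij = 0                      if i and j differ at >1 position
         = pi_j                   synonymous transversion
         = kappa * pi_j           synonymous transition
         = omega * pi_j           nonsynonymous transversion
         = kappa * omega * pi_j   nonsynonymous transition

with codon frequencies ``pi`` built by the F3x4 construction (per-codon-
position nucleotide frequencies, renormalised over sense codons).  The
matrix is scaled so one unit of branch length is one expected nucleotide
substitution per codon — the PAML convention, which makes dN and dS
per-site quantities after dividing by the mutational-opportunity site
counts computed at omega = 1.

The model is time-reversible, so transition matrices are computed through
a symmetric eigendecomposition: with D = diag(pi),
A = D^1/2 Q D^-1/2 is symmetric and P(t) = D^-1/2 U exp(L t) U' D^1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NT = "TCAG"
_CODON_TABLE = {}  # codon string -> amino acid (standard code); '*' = stop
_BASES = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_CODON_TABLE.update(_BASES)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(c for c in sorted(_CODON_TABLE) if _CODON_TABLE[c] != "*")
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon, "X")


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


def _single_diff_tables():
    """Masks over ordered sense-codon pairs differing at one position."""
    n = N_SENSE
    diff_one = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)       # transition at the differing site
    nonsyn = np.zeros((n, n), dtype=bool)   # amino acid changes
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            diff_one[i, j] = True
            ts[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return diff_one, ts, nonsyn


DIFF_ONE, TS_MASK, NONSYN_MASK = _single_diff_tables()
SYN_MASK = DIFF_ONE & ~NONSYN_MASK


def f3x4_frequencies(codon_seqs) -> np.ndarray:
    """F3x4 sense-codon frequencies from in-frame coding sequences.

    Per-codon-position nucleotide frequencies are estimated over all
    sequences; the product measure is renormalised over the 61 sense
    codons (stop-codon mass redistributed).
    """
    counts = np.zeros((3, 4))  # position x nucleotide (order TCAG)
    nt_idx = {c: i for i, c in enumerate(NT)}
    for seq in codon_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            for k in range(3):
                b = seq[i + k]
                if b in nt_idx:
                    counts[k, nt_idx[b]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous codons to estimate frequencies from")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freq[0, nt_idx[c[0]]] * pos_freq[1, nt_idx[c[1]]] * pos_freq[2, nt_idx[c[2]]]
        for c in SENSE_CODONS
    ])
    if pi.sum() <= 0:
        raise ValueError("degenerate F3x4 frequencies")
    # zero-frequency codons break reversible eigendecomposition; give them
    # a vanishing floor instead
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      normalize: bool = True):
    """GY94 generator Q; scaled (optionally) to one substitution per codon.

    Returns (Q, flux_syn, flux_nonsyn) where the fluxes are the proportions
    of the total substitution rate that are synonymous / nonsynonymous.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    rate = np.where(DIFF_ONE, 1.0, 0.0)
    rate = np.where(TS_MASK, kappa, rate) * DIFF_ONE
    rate = rate * np.where(NONSYN_MASK, omega, 1.0)
    q = rate * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    total = -(pi * np.diag(q)).sum()
    if total <= 0:
        raise ValueError("degenerate rate matrix (omega=0 with no synonymous moves?)")
    syn_flux = (pi[:, None] * q * SYN_MASK).sum() / total
    if normalize:
        q = q / total
    return q, syn_flux, 1.0 - syn_flux


@dataclass
class CodonModelConfig:
    """Parameters shared by the pairwise and site-model likelihoods."""

    kappa_init: float = 2.0
    pi: np.ndarray | None = None  # F3x4 estimated from the data when None


class SpectralModel:
    """Eigendecomposed GY94 chain for cheap P(t) at many branch lengths."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray,
                 normalize: bool = True):
        self.kappa, self.omega, self.pi = kappa, omega, pi
        q, self.syn_flux, self.nonsyn_flux = build_rate_matrix(
            kappa, omega, pi, normalize=normalize)
        self.q = q
        sqrt_pi = np.sqrt(pi)
        a = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        lam, u = np.linalg.eigh((a + a.T) / 2.0)
        self.lam = lam
        self._left = u / sqrt_pi[:, None]          # D^-1/2 U
        self._right = (u * sqrt_pi[:, None]).T     # U' D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._left * np.exp(self.lam * t)) @ self._right
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@lru_cache(maxsize=256)
def _cached_spectral(kappa: float, omega: float, pi_key) -> SpectralModel:
    pi = np.array(pi_key)
    return SpectralModel(kappa, omega, pi)


def spectral_model(kappa: float, omega: float, pi: np.ndarray) -> SpectralModel:
    """Cache-aware constructor (optimisers re-visit parameter values)."""
    return _cached_spectral(round(float(kappa), 12), round(float(omega), 12),
                            tuple(np.round(pi, 15)))


def site_counts(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts per codon, PAML style.

    Sites are mutational opportunities under the neutral (omega = 1)
    version of the fitted chain: S = 3 * rho_syn(omega=1), N = 3 - S.
    """
    _, syn_flux1, _ = build_rate_matrix(kappa, 1.0, pi)
    s = 3.0 * syn_flux1
    return s, 3.0 - s


def dn_ds_from_fit(t: float, kappa: float, omega: float, pi: np.ndarray
                   ) -> tuple[float, float]:
    """Convert (t, kappa, omega) on the normalised chain into (dN, dS)."""
    _, syn_flux, nonsyn_flux = build_rate_matrix(kappa, omega, pi)
    s_sites, n_sites = site_counts(kappa, pi)
    ds = t * syn_flux / s_sites if s_sites > 0 else np.nan
    dn = t * nonsyn_flux / n_sites if n_sites > 0 else np.nan
    return dn, ds
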