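"""Monte-Carlo null model for transmembrane content of random ORFs.

A claimed transmembrane architecture in a novel ORF is only meaningful
relative to what random coding sequence of the same base composition would
show: AT-rich codons are enriched for hydrophobic residues, so low-GC
random ORFs look "membrane-like" by chance.  This module generates random
ORFs across a GC grid, scores the fraction of residues in predicted
transmembrane helices, and places a query protein on the resulting null
distribution as a percentile.

Helix prediction is pluggable.  The built-in predictor is a transparent
Kyte-Doolittle hydropathy heuristic (window 19, threshold 1.6, merged
helices of >= 19 residues), not a re-implementation of a full membrane
HMM; per-residue annotations from an external predictor can be ingested
for exact reproduction of published helix masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .codonmodel import translate_codon

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6


@dataclass
class RandomOrfSpec:
    nt_length: int = 999
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.nt_length % 3 != 0:
            raise ValueError("nt_length must be divisible by 3")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")


@dataclass
class TMPrediction:
    mask: np.ndarray      # boolean per-residue helix membership
    tm_fraction: float


def random_orf(spec: RandomOrfSpec, rng: np.random.Generator) -> str:
    """Random protein from a GC-constrained random nucleotide sequence.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2
    (the maximum-entropy split of a GC constraint).  The sequence is read
    as codons, stop codons are deleted, and the remainder is translated
    with the standard code, so the protein is at most nt_length/3 long.
    """
    n = spec.nt_length
    g = spec.gc
    # fixed draw order (one uniform per base) keeps output seed-stable
    u = rng.random(n)
    # order: G, C, A, T by cumulative probability
    bases = np.where(u < g / 2, "G",
                     np.where(u < g, "C",
                              np.where(u < g + (1 - g) / 2, "A", "T")))
    seq = "".join(bases)
    residues = []
    for i in range(0, n, 3):
        aa = translate_codon(seq[i:i + 3])
        if aa != "*":
            residues.append(aa)
    return "".join(residues)


def predict_tm_hydropathy(protein: str, window: int = DEFAULT_WINDOW,
                          threshold: float = DEFAULT_THRESHOLD,
                          min_helix: int = DEFAULT_WINDOW) -> TMPrediction:
    """Sliding-window Kyte-Doolittle helix caller.

    Residues covered by any window of mean hydropathy > threshold are
    candidate helix residues; runs shorter than ``min_helix`` are dropped.
    Proteins shorter than the window have an empty helix mask.
    """
    if not protein:
        raise ValueError("empty protein")
    try:
        kd = np.array([KYTE_DOOLITTLE[a] for a in protein])
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None
    n = len(kd)
    mask = np.zeros(n, dtype=bool)
    if n >= window:
        means = np.convolve(kd, np.ones(window) / window, mode="valid")
        hot = means > threshold
        for i in np.nonzero(hot)[0]:
            mask[i:i + window] = True
        # enforce minimum helix length on merged runs
        run_start = None
        for i in range(n + 1):
            inside = i < n and mask[i]
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                if i - run_start < min_helix:
                    mask[run_start:i] = False
                run_start = None
    return TMPrediction(mask=mask, tm_fraction=float(mask.mean()))


def ingest_tm_annotation(path: str) -> np.ndarray:
    """Read a per-residue two-column annotation (index, in-helix flag)."""
    flags = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx_s, flag_s = line.split()[:2]
            flags[int(idx_s)] = flag_s not in ("0", "o", "O", "outside", "False")
    n = max(flags) if flags else 0
    mask = np.zeros(n, dtype=bool)
    for i, v in flags.items():
        mask[i - 1] = v
    return mask


Predictor = Callable[[str], TMPrediction]


def predict_tm(protein: str, predictor: Predictor | None = None) -> TMPrediction:
    return (predictor or predict_tm_hydropathy)(protein)


@dataclass
class GCSweepTable:
    gc_grid: np.ndarray
    replicates: np.ndarray   # (n_gc, n_reps) tm fractions
    mean: np.ndarray
    sd: np.ndarray


def gc_sweep(n_reps: int = 1000, grid: np.ndarray | None = None,
             predictor: Predictor | None = None, seed: int = 0,
             nt_length: int = 999) -> GCSweepTable:
    """TM-fraction null distribution across a GC grid (default 0..1 by 0.05).

    Fully reproducible from the seed: one child RNG per grid point, in
    grid order.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates for an SD")
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    rng = np.random.default_rng(seed)
    reps = np.empty((len(grid), n_reps))
    for gi, gc in enumerate(grid):
        spec = RandomOrfSpec(nt_length=nt_length, gc=float(gc))
        for r in range(n_reps):
            protein = random_orf(spec, rng)
            reps[gi, r] = predict_tm(protein, predictor).tm_fraction if protein \
                else 0.0
    return GCSweepTable(gc_grid=np.asarray(grid, float), replicates=reps,
                        mean=reps.mean(axis=1), sd=reps.std(axis=1, ddof=1))


def percentile_test(query_protein: str, query_gc: float, n_reps: int = 1000,
                    predictor: Predictor | None = None, seed: int = 0,
                    nt_length: int = 999,
                    query_prediction: TMPrediction | None = None) -> float:
    """Percentile of the query's TM fraction in its GC-matched null.

    Random ORFs are generated at the query's exact GC (not a grid point).
    Percentile = 100 * (#null values strictly below + half the ties) / n.
    ``query_prediction`` lets an externally predicted helix mask stand in
    for the built-in heuristic on the query itself.
    """
    if not query_protein:
        raise ValueError("empty query protein")
    q = (query_prediction or predict_tm(query_protein, predictor)).tm_fraction
    rng = np.random.default_rng(seed)
    spec = RandomOrfSpec(nt_length=nt_length, gc=query_gc)
    below = ties = 0
    for _ in range(n_reps):
        protein = random_orf(spec, rng)
        v = predict_tm(protein, predictor).tm_fraction if protein else 0.0
        if v < q:
            below += 1
        elif v == q:
            ties += 1
    return 100.0 * (below + 0.5 * ties) / n_reps
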