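"""Replicated validation studies over the synthetic-data generators.

Each study simulates data with known truth at the conditions the package
is designed for (mate-pair libraries with a 3 kb insert mean and 300 bp
SD, plastome-scale references, few-taxon codon alignments) and scores an
estimator against that truth.  They are used both by the acceptance tests
and by the standalone acceptance script, so the numbers reported in the
two places come from the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repeat_resolver import TandemRegion, estimate_copy_number, polish_consensus
from .selection import fit_site_model, ml_pairwise_dnds
from .synthetic_data import (EvolSimConfig, PlastomeSimConfig, _random_seq,
                             simulate_codon_alignment, simulate_matepairs,
                             simulate_plastome)
from .genomestats import detect_quadripartite
from .tm_null import RandomOrfSpec, percentile_test, random_orf


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# tandem copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberStudyResult:
    n_replicates: int
    n_exact: int
    errors: list[int]            # estimated - true per replicate

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_exact / self.n_replicates

    @property
    def max_abs_error(self) -> int:
        return max((abs(e) for e in self.errors), default=0)


def copy_number_recovery_study(n_replicates: int = 100, seed: int = 0,
                               mu_insert: float = 3000.0,
                               sigma_insert: float = 300.0,
                               read_len: int = 100,
                               flank: int = 9000,
                               n_pairs: int = 1500) -> CopyNumberStudyResult:
    """Recover planted tandem copy numbers from simulated mate pairs.

    Units of 50-500 bp and true copy numbers 2-8 are sampled with the
    physical constraint unit * copies <= mu_insert - 3.3 sigma (~2 kb):
    beyond that no mate pair can flank the array, so the flanking-pair
    insert comparison that defines the estimator is undefined.  The
    starting reference mis-states the copy number by +/-1 or 2.

    Library depth is a power calculation, not a tuning knob: resolving
    adjacent copy numbers requires the SE of the flanking-vs-control mean
    difference to sit below the half-unit decision boundary, i.e. at
    least 2*(4 sigma/unit)^2 flanking pairs per arm; pair counts are
    sized from that with a conservative 4x flanking yield.
    """
    seeds = _child_seeds(seed, n_replicates)
    combos = [(u, c) for u in (50, 200, 500) for c in range(2, 9)
              if u * c <= mu_insert - 3.3 * sigma_insert]
    errors = []
    n_exact = 0
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        unit_len, true_copies = combos[rng.integers(len(combos))]
        left = _random_seq(rng, flank)
        right = _random_seq(rng, flank)
        unit = _random_seq(rng, unit_len)
        genome = left + unit * true_copies + right
        # mis-stated starting reference (never below one copy)
        offset = int(rng.choice([-2, -1, 1, 2]))
        ref_copies = max(1, true_copies + offset)
        ref = left + unit * ref_copies + right
        required_span = int(2 * (4 * sigma_insert / unit_len) ** 2)
        n_pairs_rep = max(n_pairs, 6 * required_span)
        lib, _ = simulate_matepairs(genome, n_pairs=n_pairs_rep,
                                    mu_insert=mu_insert,
                                    sigma_insert=sigma_insert,
                                    read_len=read_len, seed=s)
        region = TandemRegion(flank, flank + unit_len * ref_copies,
                              unit_len, ref_copies)
        _, est, _ = estimate_copy_number(ref, region, lib, min_pairs=30)
        errors.append(est - true_copies)
        n_exact += est == true_copies
    return CopyNumberStudyResult(n_replicates=n_replicates, n_exact=n_exact,
                                 errors=errors)


# ---------------------------------------------------------------------------
# consensus polishing
# ---------------------------------------------------------------------------

@dataclass
class PolishStudyResult:
    planted: int
    corrected: int
    false_edits: int
    second_round_edits: int


def polish_study(seed: int = 0, length: int = 5000, n_substitutions: int = 3,
                 coverage: int = 40, error_rate: float = 0.01
                 ) -> PolishStudyResult:
    """Plant substitutions, polish at the given coverage, score the result."""
    rng = np.random.default_rng(seed)
    truth = _random_seq(rng, length)
    positions = rng.choice(np.arange(200, length - 200), size=n_substitutions,
                           replace=False)
    ref = list(truth)
    for p in positions:
        ref[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[p]]
    ref = "".join(ref)
    n_pairs = length * coverage // 200
    lib, _ = simulate_matepairs(truth, n_pairs=n_pairs, mu_insert=3000,
                                sigma_insert=300, read_len=100,
                                error_rate=error_rate, seed=seed)
    polished, _ = polish_consensus(ref, lib)
    corrected = sum(polished[p] == truth[p] for p in positions)
    false_edits = sum(a != b for a, b in zip(polished, truth))
    _, edits2 = polish_consensus(polished, lib)
    return PolishStudyResult(planted=n_substitutions, corrected=corrected,
                             false_edits=false_edits,
                             second_round_edits=edits2[0])


# ---------------------------------------------------------------------------
# pairwise ML omega recovery
# ---------------------------------------------------------------------------

def ml_omega_recovery(true_omega: float = 0.5, n_codons: int = 1000,
                      kappa: float = 2.0, t_per_lineage: float = 0.25,
                      seed: int = 0, n_replicates: int = 5) -> float:
    """Mean ML omega estimate over replicate two-taxon simulations.

    A single 1,000-codon replicate has an omega SE of ~0.05, so the
    recovery check averages a few replicates to measure the estimator's
    accuracy rather than one draw's luck.
    """
    estimates = []
    for s in _child_seeds(seed, n_replicates):
        cfg = EvolSimConfig(tree=f"(A:{t_per_lineage},B:{t_per_lineage});",
                            n_codons=n_codons, kappa=kappa,
                            site_classes=[(1.0, true_omega)], seed=s)
        aln, _ = simulate_codon_alignment(cfg)
        estimates.append(ml_pairwise_dnds(aln, seed=s).omega)
    return float(np.mean(estimates))


# ---------------------------------------------------------------------------
# M1a vs M2a LRT calibration and NEB classification
# ---------------------------------------------------------------------------

@dataclass
class LRTStudyResult:
    n_replicates: int
    n_rejected: int

    @property
    def type1_error_pct(self) -> float:
        return 100.0 * self.n_rejected / self.n_replicates


def lrt_type1_study(n_replicates: int = 200, seed: int = 0,
                    n_codons: int = 150, alpha: float = 0.05
                    ) -> LRTStudyResult:
    """Type-I error of the M1a-vs-M2a LRT on data simulated under M1a.

    Replicates are deliberately small (three taxa, 150 codons) so 200 of
    them fit a desk-scale run; the chi-square(2) reference makes the test
    conservative when the M2a positive class collapses on null data.
    """
    from scipy.stats import chi2
    tree = "(A:0.3,B:0.3,C:0.3);"
    seeds = _child_seeds(seed, n_replicates)
    n_rejected = 0
    for s in seeds:
        cfg = EvolSimConfig(tree=tree, n_codons=n_codons, kappa=2.0,
                            site_classes=[(0.6, 0.2), (0.4, 1.0)], seed=s)
        aln, _ = simulate_codon_alignment(cfg)
        f1 = fit_site_model(aln, tree, model="M1a", n_restarts=1, seed=s)
        f2 = fit_site_model(aln, tree, model="M2a", n_restarts=1, seed=s)
        stat = max(0.0, 2.0 * (f2.lnl - f1.lnl))
        n_rejected += chi2.sf(stat, 2) < alpha
    return LRTStudyResult(n_replicates=n_replicates, n_rejected=n_rejected)


def neb_classification_study(seed: int = 0, n_codons: int = 500) -> float:
    """Fraction of true purifying-class sites classified negative by NEB."""
    tree = "((A:0.3,B:0.3):0.15,C:0.3,D:0.45);"
    cfg = EvolSimConfig(tree=tree, n_codons=n_codons, kappa=2.0,
                        site_classes=[(0.7, 0.1), (0.3, 1.0)], seed=seed)
    aln, labels = simulate_codon_alignment(cfg)
    fit = fit_site_model(aln, tree, model="M1a", n_restarts=2, seed=seed)
    return float((fit.site_classes[labels == 0] == 0).mean())


# ---------------------------------------------------------------------------
# TM percentile calibration
# ---------------------------------------------------------------------------

def percentile_calibration_study(n_queries: int = 200, n_reps: int = 1000,
                                 gc: float = 0.31, seed: int = 0) -> float:
    """Mean percentile of null-drawn queries; ~50 when calibrated."""
    seeds = _child_seeds(seed, n_queries + 1)
    qrng = np.random.default_rng(seeds[-1])
    spec = RandomOrfSpec(gc=gc)
    vals = []
    for s in seeds[:-1]:
        query = random_orf(spec, qrng)
        if not query:
            continue
        vals.append(percentile_test(query, gc, n_reps=n_reps, seed=s))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# planted IR recovery
# ---------------------------------------------------------------------------

def ir_recovery_study(seed: int = 0, total: int = 50_000, ir: int = 5_000,
                      ssc: int = 8_000) -> int:
    """Max absolute boundary error (bp) of quadripartite detection; 0 = exact."""
    rec, truth = simulate_plastome(PlastomeSimConfig(
        total_length=total, ir_length=ir, ssc_length=ssc, seed=seed))
    layout = detect_quadripartite(rec)
    if layout is None:
        return ir  # complete miss
    return max(abs(layout.ira[0] - truth["ira"][0]),
               abs(layout.ira[1] - truth["ira"][1]),
               abs(layout.irb[0] - truth["irb"][0]),
               abs(layout.irb[1] - truth["irb"][1]))
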