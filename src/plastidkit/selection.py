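"""Molecular-evolution statistics on codon alignments.

Implements the selection analyses used to judge whether unusual plastid
ORFs are functional genes: pairwise dN/dS both by the Nei-Gojobori (1986)
counting method and by maximum likelihood under GY94, likelihood-ratio
tests against neutrality (omega = 1), the M1a ("nearly neutral") and M2a
("positive selection") site-class models with naive empirical-Bayes
classification of codons, a free-ratio branch model, and Tajima's
outgroup relative-rate test with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonmodel import (CODON_INDEX, SENSE_CODONS, STOP_CODONS,
                         build_rate_matrix, dn_ds_from_fit, f3x4_frequencies,
                         is_transition, spectral_model, translate_codon)

logger = logging.getLogger(__name__)

LNL_TOL = 1e-4  # numerical slack when comparing nested-model likelihoods


class AlignmentError(ValueError):
    pass


class SaturationError(RuntimeError):
    pass


class UnidentifiableError(RuntimeError):
    pass


class InconsistentFitError(RuntimeError):
    pass


@dataclass
class CodonAlignment:
    """Gap-aware aligned coding sequences on a shared codon grid."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa/rows length mismatch")
        if len(self.taxa) < 2:
            raise AlignmentError("need at least two sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        if lengths.pop() % 3 != 0:
            raise AlignmentError("alignment length not a multiple of 3")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon_columns(self):
        for i in range(0, len(self.rows[0]), 3):
            yield [r[i:i + 3] for r in self.rows]


def clean_alignment(aln: CodonAlignment) -> tuple[CodonAlignment, int]:
    """Drop every codon column with a gap or ambiguity in any row.

    Mirrors the usual strict treatment of missing data in codon-model
    fitting.  Returns (cleaned alignment, number of removed codon columns).
    Raises if nothing is left or an internal stop codon survives cleaning.
    """
    kept = [[] for _ in aln.rows]
    removed = 0
    for col in aln.codon_columns():
        if any(set(c) - set("ACGT") for c in col):
            removed += 1
            continue
        for row, codon in zip(kept, col):
            row.append(codon)
    if not kept[0]:
        raise AlignmentError("no gap-free codon columns remain")
    rows = ["".join(r) for r in kept]
    n = len(rows[0]) // 3
    for taxon, row in zip(aln.taxa, rows):
        for i in range(n - 1):  # a terminal stop is tolerated and trimmed below
            if row[3 * i:3 * i + 3] in STOP_CODONS:
                raise AlignmentError(f"{taxon}: internal stop codon at codon {i + 1}")
    if any(row[-3:] in STOP_CODONS for row in rows):
        rows = [row[:-3] for row in rows]
    return CodonAlignment(list(aln.taxa), rows), removed


def _codon_indices(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) sense-codon index matrix; raises on non-sense codons."""
    out = np.empty((len(aln.rows), aln.n_codons), dtype=np.int64)
    for r, row in enumerate(aln.rows):
        for s in range(aln.n_codons):
            codon = row[3 * s:3 * s + 3]
            try:
                out[r, s] = CODON_INDEX[codon]
            except KeyError:
                raise AlignmentError(
                    f"{aln.taxa[r]}: codon {codon!r} at position {s + 1}; "
                    "clean the alignment first") from None
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori counting
# ---------------------------------------------------------------------------

def _ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each of the nine single-nucleotide changes contributes 1/3 site;
    changes creating a stop codon count as nonsynonymous, so S + N = 3
    per codon (the original counting convention).
    """
    syn = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if translate_codon(alt) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) step counts over minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if every pathway
    is blocked, all are used (the standard fallback).
    """
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(nxt) == "*":
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        results.append((syn, nonsyn, blocked))
    open_paths = [(s, n) for s, n, b in results if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in results]
    syn = sum(s for s, _ in use) / len(use)
    nonsyn = sum(n for _, n in use) / len(use)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 0.75; distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


@dataclass
class PairwiseDNDS:
    dn: float
    ds: float
    omega: float
    se_omega: float | None = None
    lnl_free: float | None = None
    lnl_fixed: float | None = None
    lrt_p: float | None = None
    t: float | None = None
    kappa: float | None = None
    # counting-method intermediates
    syn_sites: float | None = None
    nonsyn_sites: float | None = None


def ng86_dnds(aln: CodonAlignment) -> PairwiseDNDS:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction."""
    if len(aln.rows) != 2:
        raise AlignmentError("counting dN/dS is a pairwise statistic")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for c1, c2 in aln.codon_columns():
        s1, ns1 = _ng86_sites(c1)
        s2, ns2 = _ng86_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (ns1 + ns2) / 2
        sd, nd = _pathway_changes(c1, c2)
        s_diff += sd
        n_diff += nd
    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = dn / ds if ds > 0 else math.inf if dn > 0 else math.nan
    return PairwiseDNDS(dn=dn, ds=ds, omega=omega,
                        syn_sites=s_sites, nonsyn_sites=n_sites)


# ---------------------------------------------------------------------------
# ML pairwise dN/dS
# ---------------------------------------------------------------------------

@dataclass
class CodonModelConfig:
    kappa_init: float = 2.0
    pi: np.ndarray | None = None


def _pair_counts(aln: CodonAlignment) -> np.ndarray:
    idx = _codon_indices(aln)
    counts = np.zeros((len(SENSE_CODONS), len(SENSE_CODONS)))
    np.add.at(counts, (idx[0], idx[1]), 1.0)
    return counts


def _pair_loglik(counts: np.ndarray, t: float, kappa: float, omega: float,
                 pi: np.ndarray) -> float:
    model = spectral_model(kappa, omega, pi)
    p = model.transition_matrix(t)
    joint = pi[:, None] * p
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(joint, 1e-300))
    return float((counts * lp).sum())


def ml_pairwise_dnds(aln: CodonAlignment,
                     config: CodonModelConfig | None = None,
                     n_restarts: int = 3, seed: int = 0) -> PairwiseDNDS:
    """GY94 maximum-likelihood pairwise dN/dS with an LRT against omega=1.

    Optimises (t, kappa, omega) in log space; the null refit fixes
    omega = 1; the LRT has one degree of freedom.  The omega standard
    error comes from the observed information (numeric Hessian).
    """
    if len(aln.rows) != 2:
        raise AlignmentError("pairwise dN/dS requires exactly two sequences")
    if aln.rows[0] == aln.rows[1]:
        raise UnidentifiableError("sequences are identical; omega unidentifiable")
    config = config or CodonModelConfig()
    pi = config.pi if config.pi is not None else f3x4_frequencies(aln.rows)
    counts = _pair_counts(aln)
    rng = np.random.default_rng(seed)

    def nll(x, fixed_omega=None):
        t, kappa = math.exp(x[0]), math.exp(x[1])
        omega = fixed_omega if fixed_omega is not None else math.exp(x[2])
        if t > 50 or kappa > 500 or omega > 500:
            return 1e10
        return -_pair_loglik(counts, t, kappa, omega, pi)

    def optimise(fixed_omega=None):
        best = None
        inits = [[math.log(0.3), math.log(config.kappa_init), math.log(0.5)]]
        for _ in range(max(n_restarts - 1, 0)):
            inits.append([math.log(0.3) + rng.normal(0, 1),
                          math.log(config.kappa_init) + rng.normal(0, 0.5),
                          rng.normal(0, 1)])
        ndim = 2 if fixed_omega is not None else 3
        for x0 in inits:
            res = minimize(nll, x0[:ndim], args=(fixed_omega,),
                           method="L-BFGS-B",
                           bounds=[(-9, 4)] * ndim,
                           options={"maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        return best

    free = optimise()
    fixed = optimise(fixed_omega=1.0)
    if not np.isfinite(free.fun):
        raise RuntimeError(f"pairwise optimiser failed: {free.message}")
    t, kappa, omega = (math.exp(v) for v in free.x)
    lnl_free, lnl_fixed = -free.fun, -fixed.fun
    p = lrt(lnl_fixed, lnl_free, df=1)
    dn, ds = dn_ds_from_fit(t, kappa, omega, pi)
    se = _omega_se(counts, t, kappa, omega, pi)
    return PairwiseDNDS(dn=dn, ds=ds, omega=omega, se_omega=se,
                        lnl_free=lnl_free, lnl_fixed=lnl_fixed, lrt_p=p,
                        t=t, kappa=kappa)


def _omega_se(counts, t, kappa, omega, pi) -> float | None:
    """SE of omega from the observed information of (t, kappa, omega)."""
    theta = np.array([t, kappa, omega])
    h = np.maximum(1e-4, 1e-3 * theta)

    def ll(v):
        return _pair_loglik(counts, v[0], v[1], v[2], pi)

    hess = np.zeros((3, 3))
    f0 = ll(theta)
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3); ei[i] = h[i]
            ej = np.zeros(3); ej[j] = h[j]
            if i == j:
                hess[i, i] = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-hess)
        var = cov[2, 2]
        return math.sqrt(var) if var > 0 else None
    except np.linalg.LinAlgError:
        return None


def lrt(lnl0: float, lnl1: float, df: int) -> float:
    """Upper-tail chi-square p-value of 2(lnl1 - lnl0)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -LNL_TOL * max(1.0, abs(lnl0)):
        raise InconsistentFitError(
            f"alternative lnL {lnl1} below null lnL {lnl0}")
    return float(chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class _Tree:
    """Postorder-indexed tree for pruning; leaves first, root last."""

    def __init__(self, newick: str, taxa: list[str]):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.resolve_polytomies()
        leaves = {leaf.taxon.label.replace(" ", "_") for leaf in t.leaf_node_iter()}
        wanted = {x.replace(" ", "_") for x in taxa}
        if leaves != wanted:
            raise AlignmentError(
                f"tree leaves {sorted(leaves)} != alignment taxa {sorted(wanted)}")
        nodes = list(t.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.branch_init: list[float] = [0.1] * self.n_nodes
        self.leaf_taxon: dict[int, int] = {}
        index = {id(nd): i for i, nd in enumerate(nodes)}
        taxon_pos = {x.replace(" ", "_"): i for i, x in enumerate(taxa)}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.children[index[id(nd.parent_node)]].append(i)
                if nd.edge.length is not None and nd.edge.length >= 0:
                    self.branch_init[i] = max(float(nd.edge.length), 1e-4)
            if nd.is_leaf():
                self.leaf_taxon[i] = taxon_pos[nd.taxon.label.replace(" ", "_")]
        self.root = self.n_nodes - 1
        # branches = every non-root node's edge
        self.branch_nodes = [i for i in range(self.n_nodes) if i != self.root]


def _mixture_models(kappa: float, omegas, proportions, pi):
    """Per-class spectral models plus the mixture rate normaliser."""
    models = [spectral_model(kappa, w, pi) for w in omegas]
    # spectral_model normalises each class to rate 1; recover raw rates to
    # scale branch lengths by the mixture-average rate instead
    raw_rates = []
    for w in omegas:
        q, _, _ = build_rate_matrix(kappa, w, pi, normalize=False)
        raw_rates.append(-(pi * np.diag(q)).sum())
    raw_rates = np.asarray(raw_rates)
    mean_rate = float(np.dot(proportions, raw_rates))
    # class k advances at raw_rates[k]/mean_rate relative to the branch length
    rel = raw_rates / mean_rate
    return models, rel


def _pattern_compress(idx: np.ndarray):
    cols = [tuple(idx[:, s]) for s in range(idx.shape[1])]
    uniq: dict[tuple, int] = {}
    site_to_pattern = np.empty(len(cols), dtype=np.int64)
    weights = []
    patterns = []
    for s, c in enumerate(cols):
        if c not in uniq:
            uniq[c] = len(patterns)
            patterns.append(c)
            weights.append(0)
        site_to_pattern[s] = uniq[c]
        weights[uniq[c]] += 1
    return np.array(patterns).T, np.array(weights, float), site_to_pattern


def _class_site_likelihoods(tree: _Tree, patterns: np.ndarray,
                            branch_lengths: np.ndarray, model, rel_rate: float,
                            pi: np.ndarray) -> np.ndarray:
    """Per-pattern likelihood under one site class (pruning)."""
    n_pat = patterns.shape[1]
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in range(tree.n_nodes):
        if not tree.children[i]:
            part = np.zeros((n_pat, 61))
            part[np.arange(n_pat), patterns[tree.leaf_taxon[i]]] = 1.0
            partials[i] = part
        else:
            part = np.ones((n_pat, 61))
            for c in tree.children[i]:
                p = model.transition_matrix(branch_lengths[c] * rel_rate)
                part = part * (partials[c] @ p.T)
                partials[c] = None
            partials[i] = part
    return partials[tree.root] @ pi


@dataclass
class SiteModelFit:
    model: str
    p0: float
    p1: float
    p2: float
    omega0: float
    omega2: float | None
    kappa: float
    lnl: float
    posterior: np.ndarray          # site x class
    site_classes: np.ndarray       # argmax class per site (0 neg, 1 neu, 2 pos)
    branch_lengths: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def class_proportions(self) -> tuple[float, ...]:
        return (self.p0, self.p1, self.p2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_site_model(aln: CodonAlignment, tree_newick: str, model: str = "M1a",
                   n_restarts: int = 3, seed: int = 0,
                   kappa_init: float = 2.0,
                   pi: np.ndarray | None = None) -> SiteModelFit:
    """Fit the M1a or M2a site-class model by maximum likelihood.

    M1a mixes a purifying class (omega0 < 1, proportion p0) with a neutral
    class (omega = 1); M2a adds a positive-selection class (omega2 > 1).
    Branch lengths, kappa, proportions and omegas are jointly optimised
    (multiple seeded restarts); per-site class posteriors are naive
    empirical Bayes at the MLEs.
    """
    if model not in ("M1a", "M2a"):
        raise ValueError("model must be 'M1a' or 'M2a'")
    if len(aln.taxa) < 3:
        raise AlignmentError("site models need at least three sequences")
    idx = _codon_indices(aln)
    if pi is None:
        pi = f3x4_frequencies(aln.rows)
    tree = _Tree(tree_newick, aln.taxa)
    patterns, weights, site_to_pattern = _pattern_compress(idx)
    n_br = tree.n_nodes  # branch length per node edge (root entry unused)
    rng = np.random.default_rng(seed)

    def unpack(x):
        bl = np.exp(x[:n_br])
        kappa = math.exp(x[n_br])
        if model == "M1a":
            p0 = float(_sigmoid(x[n_br + 1]))
            props = np.array([p0, 1 - p0])
            omegas = [float(_sigmoid(x[n_br + 2])), 1.0]
        else:
            p0 = float(_sigmoid(x[n_br + 1]))
            p1 = float((1 - p0) * _sigmoid(x[n_br + 2]))
            props = np.array([p0, p1, 1 - p0 - p1])
            omegas = [float(_sigmoid(x[n_br + 3])), 1.0,
                      1.0 + math.exp(x[n_br + 4])]
        return bl, kappa, props, omegas

    def pattern_class_liks(bl, kappa, props, omegas):
        models, rel = _mixture_models(kappa, omegas, props, pi)
        return np.stack([
            _class_site_likelihoods(tree, patterns, bl, m, r, pi)
            for m, r in zip(models, rel)], axis=1)

    def nll(x):
        try:
            bl, kappa, props, omegas = unpack(x)
            if kappa > 500 or np.any(bl > 50):
                return 1e10
            liks = pattern_class_liks(bl, kappa, props, omegas)
            site_lik = liks @ props
            if np.any(site_lik <= 0):
                return 1e10
            return -float(weights @ np.log(site_lik))
        except (ValueError, np.linalg.LinAlgError):
            return 1e10

    n_extra = 3 if model == "M1a" else 5
    base = np.concatenate([
        np.log(np.maximum(tree.branch_init, 1e-3)),
        [math.log(kappa_init)],
        np.zeros(n_extra - 1)])
    if model == "M1a":
        base[n_br + 1:] = [0.0, -1.0]           # p0 = 0.5, omega0 ~ 0.27
    else:
        base[n_br + 1:] = [0.0, 0.5, -1.0, 0.0]  # p2 small-ish, omega2 = 2

    best = None
    attempts = []
    for r in range(max(n_restarts, 1)):
        x0 = base if r == 0 else base + rng.normal(0, 0.7, size=base.shape)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-9.5, 4)] * len(base),
                       options={"maxiter": 800})
        attempts.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(f"site-model optimiser failed; per-restart -lnL: {attempts}")
    bl, kappa, props, omegas = unpack(best.x)
    liks = pattern_class_liks(bl, kappa, props, omegas)
    post_pat = liks * props[None, :]
    post_pat /= post_pat.sum(axis=1, keepdims=True)
    posterior = post_pat[site_to_pattern]
    if model == "M1a":
        p0, p1, p2 = props[0], props[1], 0.0
        omega2 = None
        posterior3 = np.column_stack([posterior, np.zeros(len(posterior))])
    else:
        p0, p1, p2 = props
        omega2 = omegas[2]
        posterior3 = posterior
    if min(p0, p1) < 1e-6 or (model == "M2a" and p2 < 1e-6):
        logger.warning("degenerate site class (proportion ~ 0): %s", props)
    site_classes = posterior3.argmax(axis=1)
    branch_lengths = bl.copy()
    branch_lengths[tree.root] = 0.0
    return SiteModelFit(model=model, p0=float(p0), p1=float(p1), p2=float(p2),
                        omega0=omegas[0], omega2=omega2, kappa=kappa,
                        lnl=-float(best.fun), posterior=posterior3,
                        site_classes=site_classes,
                        branch_lengths=branch_lengths)


# ---------------------------------------------------------------------------
# free-ratio branch model
# ---------------------------------------------------------------------------

@dataclass
class BranchResult:
    branch_id: int
    taxa_below: tuple[str, ...]
    t: float
    omega: float
    dn: float
    ds: float
    unstable: bool


def branch_dnds(aln: CodonAlignment, tree_newick: str,
                n_restarts: int = 2, seed: int = 0,
                kappa_init: float = 2.0,
                min_expected_syn: float = 5.0) -> tuple[list[BranchResult], float, float]:
    """Free-ratio GY94 fit: one omega per branch, shared kappa.

    Branch lengths are expected substitutions per codon under each
    branch's own omega.  Branches whose expected number of synonymous
    substitutions falls below ``min_expected_syn`` are flagged unstable
    (their omega is dominated by noise), mirroring the usual caveat about
    very short branches.

    Returns (per-branch results, kappa, lnL).
    """
    idx = _codon_indices(aln)
    pi = f3x4_frequencies(aln.rows)
    tree = _Tree(tree_newick, aln.taxa)
    patterns, weights, _ = _pattern_compress(idx)
    branches = tree.branch_nodes
    nb = len(branches)
    rng = np.random.default_rng(seed)

    def likelihood(bl_map, omega_map, kappa):
        n_pat = patterns.shape[1]
        partials: list[np.ndarray | None] = [None] * tree.n_nodes
        for i in range(tree.n_nodes):
            if not tree.children[i]:
                part = np.zeros((n_pat, 61))
                part[np.arange(n_pat), patterns[tree.leaf_taxon[i]]] = 1.0
                partials[i] = part
            else:
                part = np.ones((n_pat, 61))
                for c in tree.children[i]:
                    m = spectral_model(kappa, omega_map[c], pi)
                    p = m.transition_matrix(bl_map[c])
                    part = part * (partials[c] @ p.T)
                    partials[c] = None
                partials[i] = part
        site_lik = partials[tree.root] @ pi
        if np.any(site_lik <= 0):
            return -1e10
        return float(weights @ np.log(site_lik))

    def unpack(x):
        bl_map = {}
        omega_map = {}
        for j, b in enumerate(branches):
            bl_map[b] = math.exp(x[j])
            omega_map[b] = math.exp(x[nb + j])
        kappa = math.exp(x[2 * nb])
        return bl_map, omega_map, kappa

    def nll(x):
        bl_map, omega_map, kappa = unpack(x)
        if kappa > 500 or any(v > 50 for v in bl_map.values()) \
                or any(v > 500 for v in omega_map.values()):
            return 1e10
        return -likelihood(bl_map, omega_map, kappa)

    base = np.concatenate([
        np.log([max(tree.branch_init[b], 1e-3) for b in branches]),
        np.full(nb, math.log(0.3)),
        [math.log(kappa_init)]])
    best = None
    for r in range(max(n_restarts, 1)):
        x0 = base if r == 0 else base + rng.normal(0, 0.5, size=base.shape)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-9.5, 4)] * len(base),
                       options={"maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    bl_map, omega_map, kappa = unpack(best.x)

    # taxa below each branch, for reporting
    below: list[set[str]] = [set() for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        if not tree.children[i]:
            below[i] = {aln.taxa[tree.leaf_taxon[i]]}
        else:
            for c in tree.children[i]:
                below[i] |= below[c]

    results = []
    n_codons = aln.n_codons
    for b in branches:
        t, w = bl_map[b], omega_map[b]
        dn, ds = dn_ds_from_fit(t, kappa, w, pi)
        _, syn_flux, _ = build_rate_matrix(kappa, w, pi)
        expected_syn = t * syn_flux * n_codons
        unstable = expected_syn < min_expected_syn
        if unstable:
            logger.warning(
                "branch to %s: ~%.1f expected synonymous substitutions; "
                "omega estimate unstable", sorted(below[b]), expected_syn)
        results.append(BranchResult(branch_id=b,
                                    taxa_below=tuple(sorted(below[b])),
                                    t=t, omega=w, dn=dn, ds=ds,
                                    unstable=unstable))
    return results, kappa, -float(best.fun)


# ---------------------------------------------------------------------------
# Tajima relative rate test
# ---------------------------------------------------------------------------

@dataclass
class RelativeRateResult:
    m1: int
    m2: int
    chi2_stat: float
    p_raw: float
    p_adjusted: float | None = None
    undefined: bool = False


def tajima_relative_rate(seq_a: str, seq_b: str, outgroup: str
                         ) -> RelativeRateResult:
    """Tajima's (1993) 1D relative rate test on an aligned triplet.

    m1 counts sites where only sequence A differs (B agrees with the
    outgroup), m2 the converse; chi2 = (m1-m2)^2/(m1+m2) with 1 df.
    Columns with gaps or ambiguity are ignored.
    """
    if not (len(seq_a) == len(seq_b) == len(outgroup)):
        raise AlignmentError("the three aligned sequences differ in length")
    m1 = m2 = 0
    for a, b, o in zip(seq_a.upper(), seq_b.upper(), outgroup.upper()):
        if any(c not in "ACGT" for c in (a, b, o)):
            continue
        if a != b and b == o:
            m1 += 1
        elif a != b and a == o:
            m2 += 1
    if m1 + m2 == 0:
        return RelativeRateResult(m1=0, m2=0, chi2_stat=0.0, p_raw=1.0,
                                  undefined=True)
    stat = (m1 - m2) ** 2 / (m1 + m2)
    return RelativeRateResult(m1=m1, m2=m2, chi2_stat=stat,
                              p_raw=float(chi2.sf(stat, 1)))


def bonferroni(results: list[RelativeRateResult], n_tests: int | None = None
               ) -> list[RelativeRateResult]:
    """Multiply raw p-values by the number of tests, capped at 1."""
    n = n_tests if n_tests is not None else len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_raw * n)
    return results
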