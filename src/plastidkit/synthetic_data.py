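"""Synthetic inputs with machine-readable ground truth.

Every input class the pipeline consumes can be generated here with known
truth: circular quadripartite plastomes with planted inverted repeats,
AT-rich tandem arrays and gene cassettes; junction-processed mate-pair
libraries with Gaussian insert sizes and per-base error; and codon
alignments evolved on a fixed tree under the same GY94 site-class
generator the likelihood code uses (deliberate coupling: a mismatch
between simulation and inference indicates a bug, not modelling drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codonmodel import SENSE_CODONS, uniform_frequencies
from .repeat_resolver import MatePairLibrary
from .selection import CodonAlignment, _mixture_models
from .seqio import Feature, GenomeRecord, reverse_complement

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# plastome simulation
# ---------------------------------------------------------------------------

@dataclass
class TandemArraySpec:
    unit_length: int
    copy_number: int
    divergence: float = 0.0    # per-base mismatch rate between copies
    at_enrichment: float = 0.5  # AT fraction of the unit (0.5 = unbiased)


@dataclass
class GeneCassetteSpec:
    name: str
    length: int
    strand: str = "+"
    kind: str = "gene"
    pseudo: bool = False


@dataclass
class PlastomeSimConfig:
    total_length: int = 50_000
    ir_length: int = 5_000          # 0 = no inverted repeat
    ssc_length: int = 8_000
    tandem_arrays: list[TandemArraySpec] = field(default_factory=list)
    gene_cassettes: list[GeneCassetteSpec] = field(default_factory=list)
    gc: float = 0.37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ir_length < 0:
            raise ValueError("ir_length must be >= 0")
        if self.ir_length and 2 * self.ir_length + self.ssc_length >= self.total_length:
            raise ValueError("IRs plus SSC do not fit in the genome")


def simulate_plastome(config: PlastomeSimConfig) -> tuple[GenomeRecord, dict]:
    """Circular genome with planted quadripartite layout and arrays.

    Layout is LSC | IRa | SSC | IRb with IRb the exact reverse complement
    of IRa.  Tandem arrays and gene cassettes are planted inside the LSC
    at evenly spaced offsets; the truth record lists every planted
    interval, copy number and boundary.
    """
    rng = np.random.default_rng(config.seed)
    ir = config.ir_length
    ssc = config.ssc_length if ir else 0
    lsc = config.total_length - 2 * ir - ssc
    if lsc <= 0:
        raise ValueError("non-positive LSC; layout infeasible")

    lsc_seq = list(_random_seq(rng, lsc, config.gc))
    truth: dict = {"arrays": [], "genes": [], "ir_length": ir}
    features: list[Feature] = []

    # space arrays and cassettes along the LSC, 1 kb margin, no overlap
    cursor = 1000
    for spec in config.tandem_arrays:
        unit = _random_seq(rng, spec.unit_length, gc=1.0 - spec.at_enrichment)
        copies = [unit] + [_mutate(rng, unit, spec.divergence)
                           for _ in range(spec.copy_number - 1)]
        arr = "".join(copies)
        if cursor + len(arr) + 1000 > lsc:
            raise ValueError("tandem arrays do not fit in the LSC")
        lsc_seq[cursor:cursor + len(arr)] = list(arr)
        truth["arrays"].append({
            "start": cursor, "end": cursor + len(arr),
            "unit_length": spec.unit_length, "copy_number": spec.copy_number,
            "unit": unit})
        cursor += len(arr) + 1000
    for spec in config.gene_cassettes:
        if cursor + spec.length + 200 > lsc:
            raise ValueError("gene cassettes do not fit in the LSC")
        features.append(Feature(name=spec.name, kind=spec.kind,
                                strand=spec.strand,
                                intervals=[(cursor, cursor + spec.length)],
                                pseudo=spec.pseudo))
        truth["genes"].append({"name": spec.name, "start": cursor,
                               "end": cursor + spec.length})
        cursor += spec.length + 200

    if ir:
        ira = _random_seq(rng, ir, config.gc)
        ssc_seq = list(_random_seq(rng, ssc, config.gc))
        # guard the IR boundaries: the planted pair must be the *maximal*
        # reverse-complement match, so the flanking bases on either side of
        # each IR copy must not complement each other by chance
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if ssc_seq[-1] == comp[ssc_seq[0]]:
            ssc_seq[-1] = ssc_seq[0]
        if lsc_seq[-1] == comp[lsc_seq[0]]:
            lsc_seq[-1] = lsc_seq[0]
        genome = "".join(lsc_seq) + ira + "".join(ssc_seq) + reverse_complement(ira)
        truth.update({
            "lsc": (0, lsc),
            "ira": (lsc, lsc + ir),
            "ssc": (lsc + ir, lsc + ir + ssc),
            "irb": (lsc + ir + ssc, lsc + 2 * ir + ssc),
        })
    else:
        genome = "".join(lsc_seq)
        truth.update({"lsc": (0, lsc), "ira": None, "ssc": None, "irb": None})
    record = GenomeRecord(id=f"synthetic_plastome_seed{config.seed}",
                          sequence=genome, circular=True, features=features)
    return record, truth


# ---------------------------------------------------------------------------
# mate-pair simulation
# ---------------------------------------------------------------------------

def simulate_matepairs(sequence: str, n_pairs: int, mu_insert: float,
                       sigma_insert: float, read_len: int,
                       error_rate: float = 0.0, seed: int = 0,
                       circular: bool = False) -> tuple[MatePairLibrary, dict]:
    """Forward-reverse mate pairs with truncated-Gaussian insert sizes.

    Fragment left ends are uniform over the template; inserts are drawn
    from Normal(mu, sigma) truncated at [2*read_len, template length];
    substitution errors hit each base independently.  Truth stores each
    pair's true left end and insert.
    """
    if mu_insert <= 2 * read_len:
        raise ValueError("insert mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    template = sequence + sequence[:int(mu_insert + 6 * sigma_insert) + read_len] \
        if circular else sequence
    pairs = []
    truth_rows = []
    max_insert = n if circular else len(template)
    for _ in range(n_pairs):
        while True:
            insert = int(round(rng.normal(mu_insert, sigma_insert))) \
                if sigma_insert > 0 else int(mu_insert)
            if 2 * read_len <= insert <= max_insert:
                break
        start = int(rng.integers(0, n if circular else len(template) - insert + 1))
        frag = template[start:start + insert]
        r1 = frag[:read_len]
        r2 = reverse_complement(frag[-read_len:])
        if error_rate > 0:
            r1 = _mutate(rng, r1, error_rate)
            r2 = _mutate(rng, r2, error_rate)
        pairs.append((r1, r2))
        truth_rows.append({"start": start, "insert": insert})
    lib = MatePairLibrary(pairs=pairs, mu_insert=mu_insert,
                          sigma_insert=sigma_insert, read_len=read_len)
    return lib, {"pairs": truth_rows}


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class EvolSimConfig:
    tree: str                               # newick with branch lengths
    n_codons: int = 500
    kappa: float = 2.0
    site_classes: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 1.0)])  # (proportion, omega)
    pi: np.ndarray | None = None            # uniform over sense codons if None
    seed: int = 0

    def __post_init__(self) -> None:
        props = [p for p, _ in self.site_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(w < 0 for _, w in self.site_classes):
            raise ValueError("omega must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def simulate_codon_alignment(config: EvolSimConfig
                             ) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons on a fixed tree under a GY94 site-class mixture.

    Root codons are drawn from pi; each site gets a class by the
    proportion vector; per-branch transition matrices come from the same
    spectral machinery the likelihood uses, with branch lengths measured
    in expected substitutions per codon averaged over classes (so a
    simulated branch length is directly comparable to a fitted one).
    Returns the gap-free alignment and the true per-site class labels.
    """
    rng = np.random.default_rng(config.seed)
    pi = config.pi if config.pi is not None else uniform_frequencies()
    props = np.array([p for p, _ in config.site_classes])
    omegas = [w for _, w in config.site_classes]
    models, rel = _mixture_models(config.kappa, omegas, props, pi)

    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")

    n = config.n_codons
    labels = rng.choice(len(props), size=n, p=props)
    root_state = rng.choice(61, size=n, p=pi)

    states: dict[int, np.ndarray] = {}
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_state
            continue
        t = float(node.edge.length or 0.0)
        parent = states[id(node.parent_node)]
        child = parent.copy()
        if t > 0:
            mats = [m.transition_matrix(t * r) for m, r in zip(models, rel)]
            for k in range(len(props)):
                sites_k = np.nonzero(labels == k)[0]
                if len(sites_k) == 0:
                    continue
                p_cum = mats[k].cumsum(axis=1)
                u = rng.random(len(sites_k))
                child[sites_k] = np.array([
                    np.searchsorted(p_cum[parent[s]], uu)
                    for s, uu in zip(sites_k, u)])
                np.minimum(child[sites_k], 60, out=child[sites_k])
        states[id(node)] = child
        if node.is_leaf():
            seqs[node.taxon.label.replace(" ", "_")] = child

    taxa = sorted(seqs)
    rows = ["".join(SENSE_CODONS[i] for i in seqs[t]) for t in taxa]
    return CodonAlignment(taxa=taxa, rows=rows), labels
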