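"""Composition, codon-usage, ORF, repeat and quadripartite-structure statistics.

These are the building blocks of a comparative plastome summary: GC content
(total and by codon position), relative synonymous codon usage, open-reading-
frame discovery with the extended plastid start-codon set, self-similarity
(repeat) detection, and detection of the canonical quadripartite layout
(two inverted-repeat copies separating large and small single-copy regions).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .codonmodel import CODON_AA, SENSE_CODONS, STOP_CODONS, translate_codon
from .seqio import Feature, GenomeRecord, reverse_complement

logger = logging.getLogger(__name__)

# extended start-codon set used by plastid ORF annotation
PLASTID_START_CODONS = frozenset(
    {"ATG", "TTG", "GTG", "CTG", "ATA", "ATT", "ATC"})


class UndefinedValueError(ValueError):
    """A statistic is undefined for this input (e.g. all-N sequence)."""


class FrameError(ValueError):
    """A coding sequence whose length is not a multiple of three."""


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N and other symbols excluded from the denominator."""
    if not seq:
        raise UndefinedValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise UndefinedValueError("no unambiguous bases")
    return gc / denom


@dataclass
class GCProfile:
    gc_total: float
    gc1: float
    gc2: float
    gc3: float


def codon_position_gc(cds_set: list[str], names: list[str] | None = None
                      ) -> GCProfile:
    """GC at codon positions 1-3 over the concatenation of in-frame CDS."""
    pos_seqs = ["", "", ""]
    for idx, cds in enumerate(cds_set):
        if len(cds) % 3 != 0:
            name = names[idx] if names else f"CDS #{idx}"
            raise FrameError(f"{name}: length {len(cds)} not a multiple of 3")
        for k in range(3):
            pos_seqs[k] += cds[k::3]
    concat = "".join(cds_set)
    return GCProfile(gc_total=gc_content(concat),
                     gc1=gc_content(pos_seqs[0]),
                     gc2=gc_content(pos_seqs[1]),
                     gc3=gc_content(pos_seqs[2]))


def rscu(cds_set: list[str]) -> dict[str, float | None]:
    """Relative synonymous codon usage over in-frame CDS.

    RSCU(c) = count(c) / mean count over c's synonymous family.  Codons of
    amino acids never observed get ``None`` (undefined), not zero.  Stop
    codons are excluded.
    """
    counts: dict[str, int] = defaultdict(int)
    for cds in cds_set:
        if len(cds) % 3 != 0:
            raise FrameError(f"CDS length {len(cds)} not a multiple of 3")
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if codon in SENSE_CODONS:
                counts[codon] += 1
    families: dict[str, list[str]] = defaultdict(list)
    for codon, aa in zip(SENSE_CODONS, CODON_AA):
        families[aa].append(codon)
    out: dict[str, float | None] = {}
    for aa, codons in families.items():
        total = sum(counts[c] for c in codons)
        if total == 0:
            for c in codons:
                out[c] = None
        else:
            mean = total / len(codons)
            for c in codons:
                out[c] = counts[c] / mean
    return out


def percent_identity(a: str, b: str) -> float:
    """Identical non-gap columns over columns where both rows are non-gap."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    ident = comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            ident += 1
    if comparable == 0:
        raise UndefinedValueError("no comparable columns")
    return ident / comparable


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------

@dataclass
class OrfCall:
    """One open reading frame; coordinates on the forward strand.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    scanned record; for ORFs crossing the origin of a circular record,
    ``end`` exceeds the genome length and wraps (end mod length).
    """

    start: int
    end: int
    strand: str
    length: int
    frame: int
    sequence: str

    def validate(self, start_codons=PLASTID_START_CODONS) -> None:
        assert self.length % 3 == 0
        assert self.sequence[:3] in start_codons
        assert self.sequence[-3:] in STOP_CODONS
        for i in range(3, len(self.sequence) - 3, 3):
            assert self.sequence[i:i + 3] not in STOP_CODONS


def _scan_strand(seq: str, limit: int, min_len: int, start_codons,
                 all_starts: bool) -> list[tuple[int, int]]:
    """Stop-anchored ORFs as (start, end) on ``seq``; end-exclusive.

    ``limit``: cap on ORF length (genome length for circular doubled scans).
    For each stop-anchored segment the maximal ORF (earliest qualifying
    start since the previous in-frame stop) is reported; with
    ``all_starts`` every qualifying start is reported.
    N-containing codons break segments (they can hide stops).
    """
    out = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                starts = []
                continue
            if codon in STOP_CODONS:
                for s in starts:
                    length = i + 3 - s
                    if length >= min_len and length <= limit:
                        out.append((s, i + 3))
                    if not all_starts:
                        break
                starts = []
            elif codon in start_codons:
                if all_starts or not starts:
                    starts.append(i)
    return out


def find_orfs(record: GenomeRecord,
              start_codons=PLASTID_START_CODONS,
              min_len_bp: int = 90,
              all_starts: bool = False) -> list[OrfCall]:
    """Scan both strands (and across the origin when circular) for ORFs.

    An ORF starts with one of ``start_codons``, ends with a stop codon, has
    no internal stop, and its length (stop included) is >= ``min_len_bp``.
    Results are deduplicated and sorted by length descending.
    """
    if min_len_bp < 3:
        raise ValueError("min_len_bp must be >= 3")
    n = len(record)
    calls: dict[tuple, OrfCall] = {}
    for strand in "+-":
        seq = record.sequence if strand == "+" else reverse_complement(record.sequence)
        scan_seq = seq + seq if record.circular else seq
        for s, e in _scan_strand(scan_seq, n, min_len_bp, start_codons, all_starts):
            if record.circular and s >= n:
                continue  # duplicate of the first copy
            orf_seq = scan_seq[s:e]
            if strand == "+":
                g_start, g_end = s, e
            else:
                # map from reverse-complement coordinates back to forward
                g_start = (n - e) % n
                g_end = g_start + (e - s)
            key = (strand, g_start % n, e - s)
            if key not in calls:
                calls[key] = OrfCall(start=g_start % n, end=g_end if strand == "-" else e,
                                     strand=strand, length=e - s, frame=s % 3,
                                     sequence=orf_seq)
    out = sorted(calls.values(), key=lambda o: (-o.length, o.start, o.strand))
    return out


# ---------------------------------------------------------------------------
# repeat detection
# ---------------------------------------------------------------------------

@dataclass
class RepeatHit:
    pos_a: int
    pos_b: int
    length: int
    identity: float
    orientation: str  # 'direct' | 'inverted'


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" not in w:
            idx[w].append(i)
    return idx


def _chain_and_extend(seq_a: str, seq_b: str, pairs: list[tuple[int, int]],
                      k: int, min_len: int, min_identity: float,
                      max_seed_gap: int = 40):
    """Chain co-diagonal seeds and extend; returns (a, b, length, identity).

    ``pairs`` are seed coordinates with constant offset b - a (both
    sequences read left to right).  Extension is greedy with a mismatch
    budget: grow while overall identity stays above ``min_identity``.
    """
    by_diag: dict[int, list[int]] = defaultdict(list)
    for a, b in pairs:
        by_diag[b - a].append(a)
    hits = []
    na, nb = len(seq_a), len(seq_b)
    for diag, a_list in by_diag.items():
        a_list.sort()
        chains: list[list[int]] = [[a_list[0]]]
        for a in a_list[1:]:
            if a - (chains[-1][-1] + k) <= max_seed_gap:
                chains[-1].append(a)
            else:
                chains.append([a])
        for chain in chains:
            lo, hi = chain[0], chain[-1] + k  # [lo, hi) on seq_a
            # extend right then left, tolerating mismatches while identity holds
            def mismatches(l, h):
                return sum(1 for x in range(l, h) if seq_a[x] != seq_b[x + diag])

            mm = mismatches(lo, hi)
            budget_ok = True
            while budget_ok:
                budget_ok = False
                if hi < na and hi + diag < nb:
                    new_mm = mm + (seq_a[hi] != seq_b[hi + diag])
                    if (hi + 1 - lo - new_mm) / (hi + 1 - lo) >= min_identity:
                        hi += 1
                        mm = new_mm
                        budget_ok = True
                if lo > 0 and lo + diag > 0:
                    new_mm = mm + (seq_a[lo - 1] != seq_b[lo - 1 + diag])
                    if (hi - lo + 1 - new_mm) / (hi - lo + 1) >= min_identity:
                        lo -= 1
                        mm = new_mm
                        budget_ok = True
            # trim to the maximum-scoring subsegment (match +1, mismatch -3)
            # so chance extension into flanking sequence is shed
            best_score = score = 0.0
            seg_lo = cur_lo = lo
            seg_hi = lo
            for x in range(lo, hi):
                step = 1.0 if seq_a[x] == seq_b[x + diag] else -3.0
                if score <= 0:
                    score = step
                    cur_lo = x
                else:
                    score += step
                if score > best_score:
                    best_score = score
                    seg_lo, seg_hi = cur_lo, x + 1
            length = seg_hi - seg_lo
            if length >= min_len:
                ident = (length - mismatches(seg_lo, seg_hi)) / length
                if ident >= min_identity:
                    hits.append((seg_lo, seg_lo + diag, length, ident))
    return hits


def find_repeats(record: GenomeRecord, min_len: int = 20,
                 min_identity: float = 0.95, word: int = 9) -> list[RepeatHit]:
    """Self-alignment repeat scan: word-seeded, both orientations.

    Direct hits are canonicalised with ``pos_a < pos_b``; the trivial self
    diagonal is excluded; no low-complexity masking is applied.  Overlapping
    hits on the same diagonal keep the longer, then higher-identity, then
    left-most one.
    """
    seq = record.sequence
    if len(seq) < min_len:
        raise ValueError("record shorter than min_len")
    idx = _kmer_index(seq, word)

    direct_pairs = []
    for w, positions in idx.items():
        if len(positions) > 1:
            for i, a in enumerate(positions):
                for b in positions[i + 1:]:
                    direct_pairs.append((a, b))
    raw = _chain_and_extend(seq, seq, direct_pairs, word, min_len, min_identity)
    hits = [RepeatHit(a, b, ln, ident, "direct")
            for a, b, ln, ident in raw if a < b]

    # inverted: compare seq against its reverse complement, then map back
    rc = reverse_complement(seq)
    n = len(seq)
    rc_pairs = []
    rc_idx = _kmer_index(rc, word)
    for w, positions in idx.items():
        for a in positions:
            for b in rc_idx.get(w, ()):
                rc_pairs.append((a, b))
    raw = _chain_and_extend(seq, rc, rc_pairs, word, min_len, min_identity)
    for a, b_rc, ln, ident in raw:
        b = n - (b_rc + ln)  # forward-strand start of the inverted copy
        if a == b and ln > 0:
            continue  # a perfect palindrome maps onto itself
        pos_a, pos_b = min(a, b), max(a, b)
        hits.append(RepeatHit(pos_a, pos_b, ln, ident, "inverted"))

    # deduplicate: group by (orientation, rough diagonal), keep best
    def sort_key(h: RepeatHit):
        return (-h.length, -h.identity, h.pos_a)

    kept: list[RepeatHit] = []
    for h in sorted(hits, key=sort_key):
        dominated = False
        for g in kept:
            if g.orientation != h.orientation:
                continue
            overlap_a = min(g.pos_a + g.length, h.pos_a + h.length) - max(g.pos_a, h.pos_a)
            overlap_b = min(g.pos_b + g.length, h.pos_b + h.length) - max(g.pos_b, h.pos_b)
            if overlap_a > 0.5 * h.length and overlap_b > 0.5 * h.length:
                dominated = True
                break
        if not dominated:
            kept.append(h)
    return sorted(kept, key=sort_key)


# ---------------------------------------------------------------------------
# quadripartite structure
# ---------------------------------------------------------------------------

@dataclass
class QuadripartiteLayout:
    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ir_length: int
    identity: float


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def detect_quadripartite(record: GenomeRecord, min_ir_len: int = 1000,
                         min_identity: float = 0.99, k: int = 25
                         ) -> QuadripartiteLayout | None:
    """Find the maximal disjoint pair of reverse-complementary arcs.

    Seeds are k-mers matching the reverse complement elsewhere in the
    genome; matched position pairs (x, y) with x + y constant are chained
    per anti-diagonal, the longest chain is extended outward base by base,
    and the two arcs plus the single-copy gaps between them are returned.
    Returns ``None`` when no pair passes the length/identity floors.
    """
    if not record.circular:
        raise ValueError("quadripartite detection requires a circular record")
    seq = record.sequence
    n = len(seq)
    idx = _kmer_index(seq, k)
    # group seed matches by anti-diagonal s = x + y where position x pairs
    # with position y = s - x under reverse complementation
    by_s: dict[int, list[int]] = defaultdict(list)
    for w, positions in idx.items():
        rc_w = reverse_complement(w)
        for i in positions:
            for j in idx.get(rc_w, ()):
                if j > i + k:  # keep one of the two symmetric encodings
                    by_s[i + j + k - 1].append(i)

    best = None
    for s, starts in by_s.items():
        starts = sorted(set(starts))
        chains: list[list[int]] = [[starts[0]]]
        for i in starts[1:]:
            if i - (chains[-1][-1] + k) <= 100:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            p, q = chain[0], chain[-1] + k  # arc A = [p, q)
            # extend outward exactly: A grows left as B grows right & v.v.
            while p > 0 and s - p + 1 < n and seq[p - 1] == _COMP[seq[s - p + 1]] \
                    and (s - p + 1) >= q:
                p -= 1
            while s - q >= q and seq[q] == _COMP[seq[s - q]]:
                q += 1
            length = q - p
            b_lo, b_hi = s - q + 1, s - p + 1
            if b_lo < q:  # arcs overlap; not a proper IR pair
                continue
            mm = sum(1 for x in range(p, q) if seq[x] != _COMP[seq[s - x]])
            ident = (length - mm) / length if length else 0.0
            if length >= min_ir_len and ident >= min_identity:
                if best is None or length > best[0]:
                    best = (length, p, q, b_lo, b_hi, ident)
    if best is None:
        return None
    length, p, q, b_lo, b_hi, ident = best
    gap1 = (q, b_lo)                     # between IRa end and IRb start
    gap2_len = (p - b_hi) % n            # wraps the origin
    gap2 = (b_hi, b_hi + gap2_len)
    if (gap1[1] - gap1[0]) >= gap2_len:
        lsc, ssc = gap1, gap2
    else:
        lsc, ssc = gap2, gap1
    return QuadripartiteLayout(ira=(p, q), irb=(b_lo, b_hi),
                               lsc=lsc, ssc=ssc, ir_length=length,
                               identity=ident)


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

#: gene symbols that differ only by annotation convention
NAME_SYNONYMS = {
    "trnfm-cau": "trnfM-CAU",
    "trnm-cau": "trnM-CAU",
}


def normalize_gene_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Canonicalise a gene symbol (case, tRNA anticodon form)."""
    syn = dict(NAME_SYNONYMS)
    if synonyms:
        syn.update({k.lower(): v for k, v in synonyms.items()})
    raw = name.strip()
    if raw.lower() in syn:
        return syn[raw.lower()]
    if raw.lower().startswith("trn") and "-" in raw:
        stem, anticodon = raw.split("-", 1)
        aa = stem[3:]
        aa = aa if aa in ("fM",) else aa.upper()
        return f"trn{aa}-{anticodon.upper().replace('T', 'U')}"
    return raw


def _gene_kind(record: GenomeRecord, name: str) -> str:
    kinds = {f.kind for f in record.features
             if normalize_gene_name(f.name) == name and f.kind != "gene"}
    for kind in ("CDS", "tRNA", "rRNA"):
        if kind in kinds:
            return kind
    return "CDS" if not name.startswith(("trn", "rrn")) else \
        ("tRNA" if name.startswith("trn") else "rRNA")


def gene_content_table(records: list[GenomeRecord],
                       synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    """Gene x species matrix with values 'intact' / 'pseudo' / 'absent'.

    Duplicated genes (IR copies) collapse to one entry; a gene with both an
    intact and a pseudogenised copy counts as intact.
    """
    status: dict[str, dict[str, str]] = defaultdict(dict)
    for rec in records:
        for feat in rec.features:
            if feat.kind not in ("gene", "CDS", "tRNA", "rRNA"):
                logger.info("%s: skipping feature kind %s (%s)",
                            rec.id, feat.kind, feat.name)
                continue
            name = normalize_gene_name(feat.name, synonyms)
            prev = status[name].get(rec.id)
            new = "pseudo" if feat.pseudo else "intact"
            if prev != "intact":
                status[name][rec.id] = new
    genes = sorted(status)
    data = {rec.id: [status[g].get(rec.id, "absent") for g in genes]
            for rec in records}
    return pd.DataFrame(data, index=genes)


def gene_counts(record: GenomeRecord,
                synonyms: dict[str, str] | None = None) -> dict[str, int]:
    """Counting convention: duplicates once, pseudogenes not counted."""
    table = gene_content_table([record], synonyms)
    intact = [g for g in table.index if table.loc[g, record.id] == "intact"]
    by_kind = {"protein": 0, "rRNA": 0, "tRNA": 0}
    for g in intact:
        kind = _gene_kind(record, g)
        if kind == "CDS":
            by_kind["protein"] += 1
        elif kind in ("rRNA", "tRNA"):
            by_kind[kind] += 1
    return {"total": sum(by_kind.values()), **by_kind}
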