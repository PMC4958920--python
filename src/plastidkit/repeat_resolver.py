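"""Assembly-refinement computations driven by mate-pair insert sizes.

Collapsed or inflated tandem-repeat arrays in a draft assembly shift the
apparent insert size of read pairs that flank the array: if the assembly
has too few copies of the unit, flanking pairs appear shorter than the
library mean, and vice versa.  Iteratively adding or removing one unit
copy until the flanking-pair insert mean matches the genome-wide mean
recovers the true copy number.  A consensus-polishing loop and a
"coverage by inserts" verification profile complete the procedure.

The built-in read mapper is deliberately minimal — exact k-mer seeds plus
ungapped scoring — sized for plastome-scale references; externally mapped
reads can be supplied as SAM instead.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .seqio import reverse_complement

logger = logging.getLogger(__name__)


class InsufficientDataError(RuntimeError):
    pass


class UnresolvableRegionError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MatePairLibrary:
    """Junction-processed forward-reverse mate pairs with an insert model."""

    pairs: list[tuple[str, str]]
    mu_insert: float
    sigma_insert: float
    read_len: int

    def __post_init__(self) -> None:
        if self.mu_insert <= 2 * self.read_len:
            raise ValueError("nominal insert must exceed twice the read length")
        if self.sigma_insert < 0:
            raise ValueError("insert SD must be >= 0")


@dataclass
class MappedPair:
    pos1: int       # leftmost ref coordinate of the left mate
    pos2: int       # leftmost ref coordinate of the right mate
    strand1: str
    strand2: str
    insert: int     # outer distance: rightmost base of right mate - pos1 + 1
    passes_filter: bool = True
    ambiguous: bool = False


@dataclass
class TandemRegion:
    start: int
    end: int
    unit_length: int
    copy_number: int = 1


# ---------------------------------------------------------------------------
# minimal mapper
# ---------------------------------------------------------------------------

class ReferenceIndex:
    def __init__(self, reference: str, k: int = 21):
        self.reference = reference
        self.k = k
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(reference) - k + 1):
            w = reference[i:i + k]
            if "N" not in w:
                self.index[w].append(i)

    def place_read(self, read: str, min_cov_frac: float, min_identity: float):
        """All best-scoring placements of ``read`` (either orientation).

        Returns (placements, best_matches) where each placement is
        (ref_pos, strand).  A placement must cover >= min_cov_frac of the
        read within the reference at >= min_identity over the covered part.
        """
        ref, k, n = self.reference, self.k, len(self.reference)
        L = len(read)
        best: list[tuple[int, str]] = []
        best_matches = -1
        for strand, r in (("+", read), ("-", reverse_complement(read))):
            candidates = set()
            for off in range(0, max(L - k, 0) + 1, k):
                for pos in self.index.get(r[off:off + k], ()):
                    candidates.add(pos - off)
            for start in candidates:
                lo = max(start, 0)
                hi = min(start + L, n)
                covered = hi - lo
                if covered < min_cov_frac * L:
                    continue
                seg_read = r[lo - start:hi - start]
                seg_ref = ref[lo:hi]
                matches = sum(a == b for a, b in zip(seg_read, seg_ref))
                if matches < min_identity * covered or covered - matches > (1 - min_identity) * covered:
                    continue
                if matches > best_matches:
                    best_matches = matches
                    best = [(start, strand)]
                elif matches == best_matches:
                    best.append((start, strand))
        return best, best_matches


def map_reads(library: MatePairLibrary, reference: str,
              min_cov_frac: float = 0.8, min_identity: float = 0.99,
              k: int = 21) -> list[MappedPair]:
    """Map mate pairs with the built-in seeded ungapped mapper.

    Pairs in which either mate fails the coverage/identity filter are
    dropped; pairs in which either mate has multiple equally good
    placements are returned flagged ``ambiguous`` (and are excluded from
    all insert statistics downstream).
    """
    if not library.pairs:
        raise ValueError("empty library")
    if len(reference) < library.read_len:
        raise ValueError("reference shorter than the read length")
    idx = ReferenceIndex(reference, k=k)
    out: list[MappedPair] = []
    for r1, r2 in library.pairs:
        p1, _ = idx.place_read(r1, min_cov_frac, min_identity)
        p2, _ = idx.place_read(r2, min_cov_frac, min_identity)
        if not p1 or not p2:
            continue
        ambiguous = len(p1) > 1 or len(p2) > 1
        (pos1, s1), (pos2, s2) = p1[0], p2[0]
        if pos1 > pos2:
            (pos1, s1), (pos2, s2) = (pos2, s2), (pos1, s1)
        insert = pos2 + library.read_len - pos1
        out.append(MappedPair(pos1=pos1, pos2=pos2, strand1=s1, strand2=s2,
                              insert=insert, ambiguous=ambiguous))
    return out


def read_sam_pairs(path: str, read_len: int | None = None) -> list[MappedPair]:
    """Build MappedPairs from a (text) SAM file of paired reads."""
    import pysam

    by_name: dict[str, list] = defaultdict(list)
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            by_name[aln.query_name].append(aln)
    out = []
    for name, alns in by_name.items():
        if len(alns) != 2:
            continue
        a, b = sorted(alns, key=lambda x: x.reference_start)
        rl = read_len or b.query_length or b.infer_query_length() or 0
        insert = b.reference_start + rl - a.reference_start
        out.append(MappedPair(
            pos1=a.reference_start, pos2=b.reference_start,
            strand1="-" if a.is_reverse else "+",
            strand2="-" if b.is_reverse else "+",
            insert=insert))
    return out


# ---------------------------------------------------------------------------
# insert statistics
# ---------------------------------------------------------------------------

def _usable(mapped: list[MappedPair]) -> list[MappedPair]:
    return [m for m in mapped if m.passes_filter and not m.ambiguous]


def spanning_pairs(mapped: list[MappedPair], region: tuple[int, int],
                   read_len: int) -> list[MappedPair]:
    """Pairs whose left mate ends before the region and right mate starts after."""
    start, end = region
    return [m for m in _usable(mapped)
            if m.pos1 + read_len <= start and m.pos2 >= end]


def insert_mean(mapped: list[MappedPair], region: tuple[int, int] | None,
                read_len: int, min_pairs: int = 20) -> float:
    """Mean outer distance, restricted to region-flanking pairs if given."""
    if region is not None:
        use = spanning_pairs(mapped, region, read_len)
    else:
        use = _usable(mapped)
    if len(use) < min_pairs:
        raise InsufficientDataError(
            f"only {len(use)} usable pairs (need >= {min_pairs})")
    return float(np.mean([m.insert for m in use]))


def control_window_mean(mapped: list[MappedPair], region: tuple[int, int],
                        reference_length: int, read_len: int,
                        min_pairs: int = 20) -> tuple[float, float, int]:
    """Insert mean of pairs flanking a same-length repeat-free window.

    A pair flanks an interval with probability proportional to how much
    its insert exceeds the interval, so flanking-pair insert means are
    length-biased upward by ~sigma^2/(mu - interval).  Comparing the
    repeat region against a *matched-length* control window elsewhere in
    the reference cancels this bias exactly; comparing against the
    unconditioned library mean would not.

    Returns (mean, SE, n_pairs) for the best-populated control placement.
    """
    length = region[1] - region[0]
    margin = 200
    usable_inserts = [m.insert for m in _usable(mapped)]
    if not usable_inserts:
        raise InsufficientDataError("no usable pairs for a control window")
    # two geometric hazards deflate a naive control mean: (1) near a
    # template edge, long inserts lose placements; (2) near the repeat
    # region, control-flanking pairs also span the region and inherit its
    # length distortion.  Keep the window a full insert away from both
    # whenever the reference allows it, and always drop region-spanning
    # pairs from the control statistics.
    i_hi = int(np.quantile(usable_inserts, 0.999))
    reach = i_hi - read_len
    candidates = []
    for side, (lo, hi) in (("left", (margin, region[0] - margin - length)),
                           ("right", (region[1] + margin,
                                      reference_length - margin - length))):
        if hi < lo:
            continue
        safe_lo = max(lo, reach - length)          # template left edge
        safe_hi = min(hi, reference_length - i_hi + read_len)  # right edge
        if side == "left":
            safe_hi = min(safe_hi, region[0] - reach - length)
        else:
            safe_lo = max(safe_lo, region[1] + reach)
        if safe_hi >= safe_lo:
            start = (safe_lo + safe_hi) // 2
        else:
            start = (lo + hi) // 2  # residual bias unavoidable; best effort
        candidates.append((start, start + length))
    best = None
    for cand in candidates:
        spans = [m for m in spanning_pairs(mapped, cand, read_len)
                 if not (m.pos1 + read_len <= region[0] and m.pos2 >= region[1])]
        if best is None or len(spans) > len(best):
            best = spans
    if best is None:
        raise InsufficientDataError(
            f"no room for a {length} bp control window in a "
            f"{reference_length} bp reference")
    if len(best) < min_pairs:
        raise InsufficientDataError(
            f"only {len(best)} control-window pairs (need >= {min_pairs})")
    inserts = np.array([m.insert for m in best], float)
    se = float(inserts.std(ddof=1)) / math.sqrt(len(inserts))
    return float(inserts.mean()), se, len(best)


# ---------------------------------------------------------------------------
# copy-number iteration
# ---------------------------------------------------------------------------

def _edit_array(reference: str, region: TandemRegion, delta: int) -> tuple[str, TandemRegion]:
    """Insert (+1) or delete (-1) one unit copy at the end of the array."""
    u = region.unit_length
    if delta == +1:
        new_ref = reference[:region.end] + reference[region.end - u:region.end] \
            + reference[region.end:]
        new_region = TandemRegion(region.start, region.end + u, u,
                                  region.copy_number + 1)
    elif delta == -1:
        if region.end - region.start <= u:
            raise UnresolvableRegionError("cannot delete below one unit copy")
        new_ref = reference[:region.end - u] + reference[region.end:]
        new_region = TandemRegion(region.start, region.end - u, u,
                                  region.copy_number - 1)
    else:
        raise ValueError("delta must be +1 or -1")
    return new_ref, new_region


def estimate_copy_number(reference: str, region: TandemRegion,
                         library: MatePairLibrary,
                         min_cov_frac: float = 0.8, min_identity: float = 0.99,
                         min_pairs: int = 20, max_iter: int = 50,
                         tau: float | None = None):
    """Iterate map -> compare insert means -> add/remove one unit copy.

    Converges when the insert mean of pairs flanking the repeat region
    matches that of pairs flanking a matched-length control window in
    repeat-free sequence, within tau = max(unit/2, 2 SE of the
    difference); half a unit is the decision boundary between adjacent
    copy numbers.  The matched-length control cancels the length bias of
    flanking-pair sampling (longer inserts flank an interval more often),
    which would otherwise systematically delete copies of short units.
    When the add/remove sequence starts oscillating, the visited state
    with the smallest discrepancy is returned.

    Returns (corrected_reference, copy_number, trajectory).
    """
    ref, reg = reference, region
    visited: dict[int, tuple[float, str, TandemRegion]] = {}
    trajectory: list[tuple[int, float, float]] = []
    for it in range(max_iter):
        mapped = map_reads(library, ref, min_cov_frac, min_identity)
        span = spanning_pairs(mapped, (reg.start, reg.end), library.read_len)
        if not span:
            raise UnresolvableRegionError(
                f"no pairs flank the region at iteration {it}; "
                f"trajectory so far: {trajectory}")
        if len(span) < min_pairs:
            raise InsufficientDataError(
                f"only {len(span)} flanking pairs at iteration {it} "
                f"(need >= {min_pairs})")
        m_r = float(np.mean([m.insert for m in span]))
        try:
            m_g, se_g, _ = control_window_mean(mapped, (reg.start, reg.end),
                                               len(ref), library.read_len,
                                               min_pairs)
        except InsufficientDataError:
            # region comparable to the insert size: few pairs can span a
            # matched-length control, but the copy-number signal is then
            # much larger than the residual length bias of the crude mean
            logger.info("control window starved at %d copies; falling back "
                        "to the all-pairs insert mean", reg.copy_number)
            all_ins = np.array([m.insert for m in _usable(mapped)], float)
            m_g = float(all_ins.mean())
            se_g = float(all_ins.std(ddof=1)) / math.sqrt(len(all_ins))
        se_r = float(np.std([m.insert for m in span], ddof=1)) / math.sqrt(len(span))
        se = math.sqrt(se_r ** 2 + se_g ** 2)
        tol = tau if tau is not None else max(reg.unit_length / 2.0, 2.0 * se)
        diff = m_r - m_g
        trajectory.append((reg.copy_number, m_r, m_g))
        visited[reg.copy_number] = (abs(diff), ref, reg)
        if abs(diff) <= tol:
            return ref, reg.copy_number, trajectory
        delta = +1 if diff < 0 else -1
        next_copies = reg.copy_number + delta
        at_floor = delta == -1 and reg.end - reg.start <= reg.unit_length
        if next_copies in visited or at_floor:
            # oscillation (or the one-copy floor): keep the visited state
            # with the smallest discrepancy
            best = min(visited.items(), key=lambda kv: kv[1][0])
            _, best_ref, best_reg = best[1]
            return best_ref, best_reg.copy_number, trajectory
        ref, reg = _edit_array(ref, reg, delta)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations; trajectory: {trajectory}")


# ---------------------------------------------------------------------------
# consensus polishing
# ---------------------------------------------------------------------------

def polish_consensus(reference: str, library: MatePairLibrary,
                     min_identity: float = 0.98, min_cov_frac: float = 0.8,
                     max_rounds: int = 20) -> tuple[str, list[int]]:
    """Majority-vote consensus polishing, iterated to a fixed point.

    Each round maps both mates of every pair independently, tallies
    per-position base counts from unambiguous ungapped placements, and
    replaces reference bases where a strict majority disagrees (ties keep
    the reference).  Stops when a round makes zero edits.

    Returns (polished_reference, edits_per_round).
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    ref = reference
    edit_counts: list[int] = []
    for rnd in range(max_rounds):
        idx = ReferenceIndex(ref)
        counts = np.zeros((len(ref), 4), dtype=np.int32)
        for r1, r2 in library.pairs:
            for read in (r1, r2):
                placements, _ = idx.place_read(read, min_cov_frac, min_identity)
                if len(placements) != 1:
                    continue
                pos, strand = placements[0]
                r = read if strand == "+" else reverse_complement(read)
                for j, b in enumerate(r):
                    p = pos + j
                    if 0 <= p < len(ref) and b in base_idx:
                        counts[p, base_idx[b]] += 1
        new = list(ref)
        edits = 0
        for p in range(len(ref)):
            total = counts[p].sum()
            if total == 0:
                continue
            best = int(counts[p].argmax())
            best_base = "ACGT"[best]
            ref_base = ref[p]
            ref_count = counts[p, base_idx[ref_base]] if ref_base in base_idx else -1
            if best_base != ref_base and counts[p, best] > ref_count:
                new[p] = best_base
                edits += 1
        edit_counts.append(edits)
        logger.info("polish round %d: %d edits", rnd + 1, edits)
        ref = "".join(new)
        if edits == 0:
            return ref, edit_counts
    raise ConvergenceError(
        f"polishing did not converge in {max_rounds} rounds "
        f"(edits per round: {edit_counts})")


# ---------------------------------------------------------------------------
# coverage by inserts
# ---------------------------------------------------------------------------

@dataclass
class InsertProfile:
    coverage: np.ndarray      # per-position count of spanning inserts
    mean_insert: np.ndarray   # per-position mean span of those inserts
    low_positions: np.ndarray = field(default_factory=lambda: np.array([], int))


def insert_coverage_profile(mapped: list[MappedPair], reference_length: int,
                            low_fraction: float = 0.2) -> InsertProfile:
    """Per-position count and mean size of mate-pair inserts spanning it.

    Positions whose insert coverage falls below ``low_fraction`` of the
    median are flagged — the sharp declines that indicate a bad join.
    """
    n = reference_length
    cov_diff = np.zeros(n + 1)
    sum_diff = np.zeros(n + 1)
    for m in _usable(mapped):
        lo = max(m.pos1, 0)
        hi = min(m.pos1 + m.insert, n)
        if hi <= lo:
            continue
        cov_diff[lo] += 1
        cov_diff[hi] -= 1
        sum_diff[lo] += m.insert
        sum_diff[hi] -= m.insert
    cov = np.cumsum(cov_diff[:-1])
    tot = np.cumsum(sum_diff[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cov > 0, tot / np.maximum(cov, 1), 0.0)
    median = np.median(cov)
    low = np.nonzero(cov < low_fraction * median)[0] if median > 0 else np.arange(n)
    return InsertProfile(coverage=cov, mean_insert=mean, low_positions=low)
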