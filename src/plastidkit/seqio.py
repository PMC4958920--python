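"""Sequence and annotation I/O with a single coordinate convention.

All coordinates inside the package are 0-based half-open on the forward
strand; GenBank's 1-based inclusive intervals exist only at the parsing
boundary.  Features that wrap the origin of a circular genome are stored as
two ascending intervals plus a ``wraps`` flag, so ``start < end`` holds for
every stored interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "repeat_region", "misc")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Malformed input record."""


class CoordinateError(ValueError):
    """Feature coordinates incompatible with the sequence they annotate."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_sequence(seq: str, context: str = "") -> str:
    """Uppercase ``seq`` and map non-ACGTN ambiguity codes to N."""
    s = seq.upper()
    bad = set(s) - VALID_ALPHABET
    if bad:
        logger.warning("mapping ambiguity codes %s to N%s",
                       sorted(bad), f" in {context}" if context else "")
        s = "".join(c if c in VALID_ALPHABET else "N" for c in s)
    return s


@dataclass
class Feature:
    """A typed annotation: one gene/CDS/tRNA/rRNA/repeat on a genome."""

    name: str
    kind: str
    strand: str  # '+' or '-'
    intervals: list[tuple[int, int]]  # 0-based half-open, ascending
    pseudo: bool = False
    wraps: bool = False  # spans the origin of a circular genome

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            self.kind = "misc"
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if not 0 <= s < e:
                raise CoordinateError(
                    f"feature {self.name!r}: bad interval [{s}, {e})")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass
class GenomeRecord:
    """A plastome (or any nucleotide) sequence plus typed features."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = sanitize_sequence(self.sequence, context=self.id)
        for f in self.features:
            if f.end > len(self.sequence):
                raise CoordinateError(
                    f"feature {f.name!r} extends to {f.end} beyond "
                    f"sequence length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _location_intervals(loc) -> tuple[list[tuple[int, int]], str]:
    """Flatten a Biopython location to ascending 0-based half-open parts."""
    parts = [(int(p.start), int(p.end)) for p in loc.parts]
    strand = "-" if (loc.strand or 1) < 0 else "+"
    parts.sort()
    return parts, strand


def read_genbank(path: str | Path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    The circular flag comes from the LOCUS line topology; gene, CDS, tRNA,
    rRNA and repeat_region features are kept, with ``/pseudo`` and
    ``/pseudogene`` qualifiers honoured.  Compound (join/complement)
    locations become ascending interval lists.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise SeqFormatError(f"{path}: not a readable GenBank record: {exc}") from exc
    circular = (rec.annotations.get("topology", "linear") == "circular")
    features: list[Feature] = []
    n = len(rec.seq)
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA", "repeat_region"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag")
                or quals.get("label") or [feat.type])[0]
        intervals, strand = _location_intervals(feat.location)
        for s, e in intervals:
            if e > n:
                raise CoordinateError(
                    f"{path}: feature {name!r} interval [{s},{e}) outside "
                    f"sequence of length {n}")
        wraps = circular and len(intervals) == 2 and \
            intervals[0][0] == 0 and intervals[1][1] == n
        pseudo = "pseudo" in quals or "pseudogene" in quals
        features.append(Feature(name=name, kind=feat.type, strand=strand,
                                intervals=intervals, pseudo=pseudo,
                                wraps=wraps))
    return GenomeRecord(id=rec.id or path.stem, sequence=str(rec.seq),
                        circular=circular, features=features)


def extract_feature_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Concatenate a feature's intervals; reverse-complement on '-'.

    For wrap-around features on circular records the two stored intervals
    are joined in genome order starting at the 3'-most piece (the piece
    ending at the origin first), which reconstructs the biological sequence.
    """
    n = len(record)
    for s, e in feature.intervals:
        if e > n:
            raise CoordinateError(
                f"interval [{s},{e}) exceeds record length {n}")
    ivals = feature.intervals
    if feature.wraps:
        if not record.circular:
            raise CoordinateError("wrap-around feature on a linear record")
        # genome-order join across the origin: [x, n) then [0, y)
        ivals = [feature.intervals[1], feature.intervals[0]]
    seq = "".join(record.sequence[s:e] for s, e in ivals)
    return reverse_complement(seq) if feature.strand == "-" else seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) tuples; ids stop at first whitespace.

    Sequences are uppercased; ambiguity codes other than N map to N.
    """
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq), context=rec.id)
        if not seq:
            raise SeqFormatError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (id, sequence) tuples as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            if not seq:
                raise ValueError(f"record {rid!r} has an empty sequence")
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA without nucleotide sanitisation (for protein queries)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def translate(seq: str, to_stop: bool = False) -> str:
    """Standard-code translation of an in-frame nucleotide string."""
    return str(Seq(seq).translate(to_stop=to_stop))
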