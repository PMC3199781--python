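"""Raw-read processing: primer selection, barcode demultiplexing, tag mapping.

Gene-trap proviral junctions are amplified by linker-mediated PCR and
pyrosequenced; each read carries sequencing primer A, a 4-bp sample barcode
encoding the vector type and silencing phenotype, a viral LTR remnant, a
stretch of genomic DNA, and primer B context.  Reads whose primers are not
exact are discarded; the 20 bases adjacent to primer B serve as the genomic
tag, which is mapped to the genome tolerating at most 2 mismatches.

Coordinate convention
---------------------
A mapped site's ``position`` is the forward-strand coordinate of the *first*
base of the tag window, 0-based.  ``strand`` is the provirus orientation:
``+`` when the tag matches the forward strand as read, ``-`` when it matches
the reverse complement.  Reverse-complementing the genome therefore mirrors
positions but leaves the (position, strand)-pair semantics intact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

# Barcode classes: L/M = lentiviral / MLV-based vector, I/R = irrepressible
# (non-repressing) / repressible integrant.
DEFAULT_BARCODES: dict[str, tuple[str, ...]] = {
    "LI": ("TGAC", "AGTC"),
    "LR": ("CTGA",),
    "MI": ("TCGA", "AGCT"),
    "MR": ("GTAC",),
}

# 454 pyrosequencing adaptor primers (defaults; configurable per run).
DEFAULT_PRIMER_A = "GCCTCCCTCGCGCCATCAG"
DEFAULT_PRIMER_B = "GCCTTGCCAGCCCGCTCAG"

# Terminal LTR remnants left on the genomic side of the junction after
# trimming; one per vector backbone.
DEFAULT_LTR = {"LV": "AGTGTGGAAAATCTCTAGCA", "MLV": "AATGAAAGACCCC"}

CLASS_TO_VECTOR = {"LI": "LV", "LR": "LV", "MI": "MLV", "MR": "MLV"}
CLASS_TO_PHENOTYPE = {"LI": "NREP", "LR": "REP", "MI": "NREP", "MR": "REP"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeScheme:
    """Demultiplexing layout: primers, barcodes, LTR remnants, tag policy."""

    barcodes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BARCODES)
    )
    primer_a: str = DEFAULT_PRIMER_A
    primer_b: str = DEFAULT_PRIMER_B
    ltr: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LTR))
    tag_length: int = 20
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        all_codes = [b for codes in self.barcodes.values() for b in codes]
        if not all_codes:
            raise ValueError("barcode scheme is empty")
        lengths = {len(b) for b in all_codes}
        if len(lengths) != 1:
            raise ValueError("barcodes must be equal length")
        if len(set(all_codes)) != len(all_codes):
            raise ValueError("barcodes must be distinct across classes")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(next(iter(self.barcodes.values())))))

    def classify_barcode(self, barcode: str) -> str | None:
        for cls, codes in self.barcodes.items():
            if barcode in codes:
                return cls
        return None

    def barcode_for(self, vector: str, phenotype: str) -> tuple[str, tuple[str, ...]]:
        """Return (class, barcodes) for a (vector, phenotype) pair."""
        for cls in self.barcodes:
            if CLASS_TO_VECTOR[cls] == vector and CLASS_TO_PHENOTYPE[cls] == phenotype:
                return cls, self.barcodes[cls]
        raise KeyError(f"no barcode class for {vector}/{phenotype}")


@dataclass
class SiteRecord:
    """One read's fate: class labels plus mapping outcome.

    status is one of mapped / unmapped / ambiguous / too_short / discarded;
    reason refines non-mapped outcomes (primer_mismatch, no_barcode,
    ltr_mismatch, ambiguous_base, ...).
    """

    read_id: str
    vector: str | None = None
    phenotype: str | None = None
    barcode_class: str | None = None
    chrom: str | None = None
    position: int = -1
    strand: str | None = None
    mismatches: int = -1
    status: str = "discarded"
    reason: str = ""


SITE_COLUMNS = [f.name for f in dataclasses.fields(SiteRecord)]


def read_fasta(path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Iterable[tuple[str, str]], scheme: BarcodeScheme
) -> tuple[dict[str, list[tuple[str, str]]], list[SiteRecord]]:
    """Exact-primer selection and barcode classification.

    A read is kept iff it begins with primer A and ends with primer B with no
    mismatches, carries a known barcode immediately after primer A, and the
    expected vector LTR remnant follows the barcode.  Kept reads are trimmed
    to genomic sequence only.  Returns ``(per_class, discards)`` where
    ``per_class`` maps barcode class to ``[(read_id, genomic_seq), ...]``;
    kept + discarded equals the input count.
    """
    per_class: dict[str, list[tuple[str, str]]] = {c: [] for c in scheme.barcodes}
    discards: list[SiteRecord] = []
    bl = scheme.barcode_length
    pa, pb = scheme.primer_a, scheme.primer_b
    for read_id, seq in reads:
        seq = seq.upper()
        if not (seq.startswith(pa) and seq.endswith(pb) and len(seq) > len(pa) + len(pb)):
            discards.append(SiteRecord(read_id, reason="primer_mismatch"))
            continue
        barcode = seq[len(pa) : len(pa) + bl]
        cls = scheme.classify_barcode(barcode)
        if cls is None:
            discards.append(SiteRecord(read_id, reason="no_barcode"))
            continue
        vector = CLASS_TO_VECTOR[cls]
        ltr = scheme.ltr[vector]
        body = seq[len(pa) + bl : len(seq) - len(pb)]
        if not body.startswith(ltr):
            discards.append(
                SiteRecord(read_id, vector=vector, barcode_class=cls, reason="ltr_mismatch")
            )
            continue
        per_class[cls].append((read_id, body[len(ltr):]))
    return per_class, discards


def extract_tag(trimmed_read: str, scheme: BarcodeScheme) -> str | None:
    """The ``tag_length`` bases adjacent to primer B (the read's 3' end).

    Returns None when the trimmed read is too short to yield a full tag.
    The tag is in read orientation; mapping resolves genome strand.
    """
    if len(trimmed_read) < scheme.tag_length:
        return None
    return trimmed_read[-scheme.tag_length :]


# ---------------------------------------------------------------------------
# Tag mapping: pigeonhole exact-seed search + Hamming verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapResult:
    chrom: str | None
    position: int
    strand: str | None
    mismatches: int
    status: str  # mapped | unmapped | ambiguous
    reason: str = ""


def _split_segments(tag: str, n_parts: int) -> list[tuple[int, str]]:
    """Split into n_parts near-equal segments; any window within Hamming
    distance < n_parts of the tag must contain at least one segment exactly."""
    k = len(tag)
    base, extra = divmod(k, n_parts)
    segs, off = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        segs.append((off, tag[off : off + size]))
        off += size
    return segs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _candidate_positions(tag: str, seq: str, n_parts: int) -> set[int]:
    cands: set[int] = set()
    k = len(tag)
    n = len(seq)
    for off, seg in _split_segments(tag, n_parts):
        start = seq.find(seg)
        while start != -1:
            pos = start - off
            if 0 <= pos <= n - k:
                cands.add(pos)
            start = seq.find(seg, start + 1)
    return cands


def map_tag(tag: str, genome: dict[str, str], scheme: BarcodeScheme) -> MapResult:
    """Locate a tag on either strand of the genome, tolerating up to
    ``max_mismatches`` substitutions.

    Returns the unique minimum-Hamming-distance hit; two or more hits tying
    at the minimum give status "ambiguous", no hit within tolerance gives
    "unmapped".  Equivalent to an exhaustive scan of every window on both
    strands (the seed split guarantees no hit within tolerance is missed).
    """
    if not genome:
        raise ValueError("empty genome")
    tag = tag.upper()
    if set(tag) - set("ACGT"):
        return MapResult(None, -1, None, -1, "unmapped", "ambiguous_base")
    n_parts = scheme.max_mismatches + 1
    queries = {"+": tag, "-": revcomp(tag)}
    best: list[tuple[str, int, str]] = []
    best_d = scheme.max_mismatches + 1
    for chrom, seq in genome.items():
        if len(seq) < len(tag):
            continue
        for strand, query in queries.items():
            for pos in _candidate_positions(query, seq, n_parts):
                d = _hamming(query, seq[pos : pos + len(tag)])
                if d < best_d:
                    best_d = d
                    best = [(chrom, pos, strand)]
                elif d == best_d:
                    hit = (chrom, pos, strand)
                    if hit not in best:
                        best.append(hit)
    if best_d > scheme.max_mismatches:
        return MapResult(None, -1, None, -1, "unmapped", "no_hit")
    if len(best) > 1:
        return MapResult(None, -1, None, best_d, "ambiguous", "multi_hit")
    chrom, pos, strand = best[0]
    return MapResult(chrom, pos, strand, best_d, "mapped")


# ---------------------------------------------------------------------------
# End-to-end read processing
# ---------------------------------------------------------------------------

def process_reads(
    reads: Iterable[tuple[str, str]],
    genome: dict[str, str],
    scheme: BarcodeScheme | None = None,
) -> pd.DataFrame:
    """Demultiplex, extract tags, and map: one SiteRecord row per input read.

    Every read ends in exactly one status of {mapped, unmapped, ambiguous,
    too_short, discarded}.
    """
    scheme = scheme or BarcodeScheme()
    per_class, discards = demultiplex(reads, scheme)
    records: list[SiteRecord] = list(discards)
    for cls, kept in per_class.items():
        vector = CLASS_TO_VECTOR[cls]
        phenotype = CLASS_TO_PHENOTYPE[cls]
        for read_id, trimmed in kept:
            tag = extract_tag(trimmed, scheme)
            if tag is None:
                records.append(
                    SiteRecord(read_id, vector, phenotype, cls, status="too_short",
                               reason="short_genomic")
                )
                continue
            m = map_tag(tag, genome, scheme)
            records.append(
                SiteRecord(read_id, vector, phenotype, cls, m.chrom, m.position,
                           m.strand, m.mismatches, m.status, m.reason)
            )
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=SITE_COLUMNS)
    return df


def write_sites_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"position": int, "mismatches": int})
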