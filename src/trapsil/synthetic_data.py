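"""Synthetic genomes, annotations, feature tracks, integrants and raw reads.

The generator emulates every input of the analysis with planted statistical
structure so the whole pipeline is exercisable without downloads:

* a random genome of ``n_chromosomes`` chromosomes (``chrS1..chrSn``, named
  to avoid collision with real assemblies) with configurable GC content;
* transcripts placed without inter-gene overlap, a fraction of which come in
  same-strand overlapping pairs to exercise the aggressive clustering (some
  pairs share their 5' end and keep a single TSS, some do not);
* CpG-island and DNase interval tracks concentrated at the TSSs of a random
  "active" half of the genes, ChIP-style SGA count tracks for two active
  (H3K4me3, H3K27ac) and two repressive (H3K9me3, H4K20me3) marks, and an
  expression table correlated with the active tracks by construction;
* integration sites whose vector targeting follows the field's observation
  that MLV integrates near active TSSs while LV lands inside gene bodies,
  and whose silencing phenotype (REP / NREP) is drawn from a logistic model
  in distance-to-TSS and local feature density;
* barcoded LM-PCR-style reads around each junction, with opt-in primer
  corruption and per-base errors (error-free by default).

Phenotype model: with d the signed distance to the target gene's TSS and f
the local feature density (the configured density track — DNase intervals by
default — quantified in a +/-1 kb window),

    logit P(REP) = logit(baseline_p_rep)
                 + distance_effect * exp(-|d| / distance_decay_bp)
                 + feature_effect * f

``distance_decay_bp = 0`` disables the distance term.  Effect sizes are
configuration, not constants: the observed data state only directions of
enrichment, so the knobs let tests plant effects of known size.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotation, features, readproc
from .annotation import GeneCluster, Transcript
from .readproc import BarcodeScheme

_STAGE_GENOME, _STAGE_SITES, _STAGE_READS = 11, 13, 17


@dataclass
class SynthConfig:
    genome_length: int = 1_000_000      # bp per chromosome
    n_chromosomes: int = 2
    n_genes: int = 60
    gene_size_range: tuple[int, int] = (5_000, 50_000)
    gc: float = 0.5
    n_sites: int = 500
    controls_per_site: int = 10
    # phenotype model
    baseline_p_rep: float = 0.35
    distance_effect: float = 2.0        # log-odds at the TSS
    distance_decay_bp: float = 10_000.0  # e-folding scale; 0 disables
    feature_effect: float = 0.0         # log-odds per feature-density unit
    density_track: str = "DNase_HS"     # track quantified as "local density"
    density_half_width: int = 1_000     # bp half-window for the density term
    # read generation
    read_error_rate: float = 0.0
    corrupt_fraction: float = 0.0
    mlv_fraction: float = 0.5
    mlv_tss_sd: float = 1_000.0
    sense_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_chromosomes, self.controls_per_site) < 1:
            raise ValueError("counts must be positive")
        if self.n_genes < 0 or self.n_sites < 0:
            raise ValueError("n_genes and n_sites must be >= 0")
        lo, hi = self.gene_size_range
        if not (1 <= lo <= hi):
            raise ValueError("gene_size_range min must be >= 1 and <= max")
        for p in (self.gc, self.baseline_p_rep, self.read_error_rate,
                  self.corrupt_fraction, self.mlv_fraction, self.sense_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_genes * hi > self.genome_length * self.n_chromosomes:
            raise ValueError("cannot place n_genes of max size in the genome")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gene_size_range" in raw:
            raw["gene_size_range"] = tuple(raw["gene_size_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gene_size_range"] = list(d["gene_size_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    transcripts: list[Transcript]
    tracks: dict[str, features.FeatureTrack]
    expression: dict[str, float]
    clusters: list[GeneCluster] = field(default_factory=list)
    active_cluster_ids: set[str] = field(default_factory=set)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def gen_genome(config: SynthConfig) -> GenomeBundle:
    """Genome, transcripts, feature tracks and expression for one run.

    Deterministic in ``config.seed``: identical configs give byte-identical
    bundles and on-disk files.
    """
    rng = np.random.default_rng([_STAGE_GENOME, config.seed])
    sequences = {
        f"chrS{i + 1}": _random_dna(rng, config.genome_length, config.gc)
        for i in range(config.n_chromosomes)
    }
    chroms = list(sequences)

    # --- transcript placement: non-overlapping gene slots per chromosome ---
    transcripts: list[Transcript] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    margin = 2_000  # keep genes clear of chromosome ends
    gene_idx = 0
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        sizes = rng.integers(config.gene_size_range[0], config.gene_size_range[1] + 1,
                             size=k)
        free = config.genome_length - 2 * margin - int(sizes.sum())
        if free < 0:
            raise ValueError(f"cannot place {k} genes on {chrom}")
        gaps = rng.multinomial(free, [1 / (k + 1)] * (k + 1))
        cursor = margin
        for gi in range(k):
            cursor += int(gaps[gi])
            start, end = cursor, cursor + int(sizes[gi])
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"tx{gene_idx:04d}"
            u = rng.random()
            transcripts.append(Transcript(name, chrom, strand, start, end))
            if u < 0.2 and end - start > 2_000:
                # overlapping same-strand isoform; half keep a shared 5' end
                # (single TSS), half shift it (two distinct TSSs)
                short = int((end - start) * 0.6)
                shift = 0 if u < 0.1 else int((end - start) * 0.2)
                if strand == "+":
                    transcripts.append(
                        Transcript(name + "b", chrom, strand, start + shift,
                                   start + shift + short))
                else:
                    transcripts.append(
                        Transcript(name + "b", chrom, strand, end - shift - short,
                                   end - shift))
            gene_idx += 1

    clusters = annotation.cluster_transcripts(transcripts)

    # --- tracks planted around a random "active" half of the genes ---
    order = rng.permutation(len(clusters))
    active = {clusters[i].cluster_id for i in order[: len(clusters) // 2]}
    cpg: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    dnase: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    marks: dict[str, dict[str, list[tuple[int, int]]]] = {
        m: {c: [] for c in chroms}
        for m in ("H3K4me3", "H3K27ac", "H3K9me3", "H4K20me3")
    }

    def _clip(chrom: str, lo: int, hi: int) -> tuple[int, int]:
        n = len(sequences[chrom])
        return max(0, lo), min(n, hi)

    for c in clusters:
        is_active = c.cluster_id in active
        if is_active:
            cpg[c.chrom].append(_clip(c.chrom, c.tss - 200, c.tss + 200))
            dnase[c.chrom].append(_clip(c.chrom, c.tss - 500, c.tss + 500))
            for mark, spread in (("H3K4me3", 1_000), ("H3K27ac", 2_000)):
                offs = rng.integers(-spread, spread + 1, size=8)
                for o in offs:
                    p = min(max(0, c.tss + int(o)), len(sequences[c.chrom]) - 1)
                    marks[mark][c.chrom].append((p, 1))
        else:
            for mark in ("H3K9me3", "H4K20me3"):
                ps = rng.integers(c.start, c.end, size=8)
                for p in ps:
                    marks[mark][c.chrom].append((int(p), 1))
    # background points for the repressive marks in intergenic space
    for mark in ("H3K9me3", "H4K20me3"):
        for chrom in chroms:
            ps = rng.integers(0, len(sequences[chrom]), size=50)
            for p in ps:
                marks[mark][chrom].append((int(p), 1))

    tracks: dict[str, features.FeatureTrack] = {
        "CpG_islands": features.interval_track("CpG_islands", cpg),
        "DNase_HS": features.interval_track("DNase_HS", dnase),
        "GC_content": features.sequence_track("GC_content", sequences, "sequence_gc"),
        "CpG_density": features.sequence_track("CpG_density", sequences, "sequence_cpg"),
        "gene_TSS": features.tss_track(
            "gene_TSS", {ch: [c.tss for c in clusters if c.chrom == ch] for ch in chroms}
        ),
    }
    for mark, pts in marks.items():
        tracks[mark] = features.point_track(mark, pts)

    # expression correlated with active-mark placement by construction
    expression = {}
    for c in clusters:
        base = 8.0 if c.cluster_id in active else 2.0
        expression[c.cluster_id] = float(base * rng.lognormal(0.0, 0.4))

    return GenomeBundle(sequences, transcripts, tracks, expression, clusters, active)


# ---------------------------------------------------------------------------
# Integrants
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    with np.errstate(divide="ignore"):
        return float(np.log(p) - np.log1p(-p))


def gen_integrants(
    config: SynthConfig, bundle: GenomeBundle, scheme: BarcodeScheme | None = None
) -> pd.DataFrame:
    """Integration sites with planted phenotype structure (the truth table).

    Returns a SiteRecord-shaped table (status "mapped", positions being the
    forward-strand tag starts) extended with truth columns: target cluster,
    signed distance to its TSS, local feature density, and P(REP).
    """
    if not bundle.clusters:
        raise ValueError("bundle has no genes; cannot place integrants")
    scheme = scheme or BarcodeScheme()
    rng = np.random.default_rng([_STAGE_SITES, config.seed])
    density_track = bundle.tracks[config.density_track]
    eta0 = _logit(config.baseline_p_rep)
    rows = []
    for i in range(config.n_sites):
        c = bundle.clusters[int(rng.integers(len(bundle.clusters)))]
        vector = "MLV" if rng.random() < config.mlv_fraction else "LV"
        if vector == "MLV":
            offset = int(round(rng.normal(0.0, config.mlv_tss_sd)))
            pos = c.tss + offset if c.strand == "+" else c.tss - offset
        else:
            pos = int(rng.integers(c.start, c.end))
        n = bundle.chrom_length(c.chrom)
        pos = min(max(pos, 0), n - scheme.tag_length)
        strand = c.strand if rng.random() < config.sense_fraction else (
            "-" if c.strand == "+" else "+")
        d = c.dist_to_tss(pos)
        density = features.quantify(density_track, c.chrom, pos,
                                    config.density_half_width, chrom_length=n)
        eta = eta0
        if config.distance_decay_bp > 0:
            eta += config.distance_effect * math.exp(-abs(d) / config.distance_decay_bp)
        eta += config.feature_effect * density
        p_rep = 1.0 / (1.0 + math.exp(-eta)) if math.isfinite(eta) else (
            1.0 if eta > 0 else 0.0)
        phenotype = "REP" if rng.random() < p_rep else "NREP"
        rows.append(dict(
            read_id=f"site{i:05d}", vector=vector, phenotype=phenotype,
            barcode_class={"LV": {"REP": "LR", "NREP": "LI"},
                           "MLV": {"REP": "MR", "NREP": "MI"}}[vector][phenotype],
            chrom=c.chrom, position=pos, strand=strand, mismatches=0,
            status="mapped", reason="",
            true_cluster=c.cluster_id, true_dist_to_tss=d,
            feature_density=density, p_rep=p_rep,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def gen_reads(
    sites: pd.DataFrame,
    bundle: GenomeBundle,
    config: SynthConfig,
    scheme: BarcodeScheme | None = None,
) -> list[tuple[str, str]]:
    """LM-PCR-style reads, one per site: primer A + barcode + vector LTR +
    20-bp genomic tag + primer B.

    The tag equals genome[pos:pos+tag_length] for plus-strand proviruses and
    its reverse complement for minus-strand ones, so downstream demultiplex
    + mapping recovers (chrom, position, strand) exactly when noise is off.
    A ``corrupt_fraction`` of reads get a one-base primer-A substitution
    (discarded downstream); per-base substitutions at ``read_error_rate``
    hit the genomic tag only.  Sites whose tag window leaves the chromosome
    are skipped with a warning.
    """
    scheme = scheme or BarcodeScheme()
    rng = np.random.default_rng([_STAGE_READS, config.seed])
    reads = []
    for _, s in sites.iterrows():
        chrom, pos = s["chrom"], int(s["position"])
        seq = bundle.sequences[chrom]
        if pos < 0 or pos + scheme.tag_length > len(seq):
            warnings.warn(f"site {s['read_id']} too close to {chrom} end; skipped")
            continue
        tag = seq[pos : pos + scheme.tag_length]
        if s["strand"] == "-":
            tag = readproc.revcomp(tag)
        if config.read_error_rate > 0:
            tag = _mutate(tag, rng, config.read_error_rate)
        cls, codes = scheme.barcode_for(s["vector"], s["phenotype"])
        barcode = codes[int(rng.integers(len(codes)))]
        primer_a = scheme.primer_a
        if config.corrupt_fraction > 0 and rng.random() < config.corrupt_fraction:
            primer_a = _substitute_one(primer_a, rng)
        ltr = scheme.ltr[s["vector"]]
        reads.append((s["read_id"], primer_a + barcode + ltr + tag + scheme.primer_b))
    return reads


def _substitute_one(seq: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(seq)))
    alt = [b for b in "ACGT" if b != seq[i]]
    return seq[:i] + alt[int(rng.integers(3))] + seq[i + 1 :]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alt = [b for b in "ACGT" if b != out[i]]
            out[i] = alt[int(rng.integers(3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(bundle: GenomeBundle, outdir) -> None:
    """Write genome.fasta, transcripts.refflat.tsv, expression.tsv and all
    tracks (BED for intervals, SGA for counted points)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sorted(bundle.sequences.items()), outdir / "genome.fasta")
    annotation.write_refflat(bundle.transcripts, outdir / "transcripts.refflat.tsv")
    features.write_expression(bundle.expression, outdir / "expression.tsv")
    for name, track in bundle.tracks.items():
        if track.kind == "interval":
            features.write_bed(track, outdir / f"{name}.bed")
        elif track.kind == "point_count":
            features.write_sga(track, outdir / f"{name}.sga")


def write_truth(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)
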