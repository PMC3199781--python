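"""Non-redundant gene model and integrant-to-gene assignment.

Transcript annotations (refFlat-like: name, chrom, strand, txStart, txEnd;
0-based half-open) are collapsed into a non-redundant gene list by an
aggressive clustering strategy: all transcripts that directly or indirectly
overlap on the same strand of the same chromosome form one cluster, recorded
with the 5'-most start and 3'-most end.  Integrants are intragenic when they
fall inside a cluster's span and are assigned to ("mapped relative to") a
gene only when the provirus orientation matches the gene's strand.

All coordinates are 0-based half-open internally.  A cluster's TSS is its
first transcribed base: ``start`` on the plus strand, ``end - 1`` on the
minus strand; dist_to_tss is measured 5'->3' along the gene and is >= 0 for
intragenic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd


class Transcript(NamedTuple):
    name: str
    chrom: str
    strand: str
    start: int  # txStart, 0-based
    end: int    # txEnd, half-open

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"transcript {self.name}: invalid span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.name}: bad strand {self.strand!r}")


@dataclass
class GeneCluster:
    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    n_distinct_tss: int = 1

    @property
    def tss(self) -> int:
        """First transcribed base (5'-most position along the gene)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def size(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def dist_to_tss(self, position: int) -> int:
        return position - self.start if self.strand == "+" else self.end - 1 - position


def cluster_transcripts(transcripts: Iterable[Transcript]) -> list[GeneCluster]:
    """Connected components of the same-strand interval-overlap graph.

    Overlap means nonempty intersection of half-open spans; transcripts that
    merely touch ([0,10) and [10,20)) do not cluster.  Cluster bounds are the
    minimum start and maximum end of the members; n_distinct_tss counts the
    distinct transcription starts (txStart on +, txEnd on -) among members.
    Output is sorted by (chrom, tss).
    """
    by_key: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        t.validate()
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    clusters: list[GeneCluster] = []
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda t: (t.start, t.end, t.name))
        cur: list[Transcript] = []
        cur_end = -1
        for t in group:
            if cur and t.start < cur_end:
                cur.append(t)
                cur_end = max(cur_end, t.end)
            else:
                if cur:
                    clusters.append(_make_cluster(chrom, strand, cur))
                cur = [t]
                cur_end = t.end
        if cur:
            clusters.append(_make_cluster(chrom, strand, cur))
    clusters.sort(key=lambda c: (c.chrom, c.tss, c.strand))
    for i, c in enumerate(clusters):
        c.cluster_id = f"CL{i:05d}"
    return clusters


def _make_cluster(chrom: str, strand: str, members: list[Transcript]) -> GeneCluster:
    starts = {t.start for t in members} if strand == "+" else {t.end for t in members}
    return GeneCluster(
        cluster_id="",
        chrom=chrom,
        strand=strand,
        start=min(t.start for t in members),
        end=max(t.end for t in members),
        members=[t.name for t in members],
        n_distinct_tss=len(starts),
    )


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class GeneAssignment:
    site_id: str
    cluster_id: str | None
    intragenic: bool
    sense: bool
    assigned: bool        # intragenic AND sense
    dist_to_tss: int      # valid when intragenic
    multi: bool = False   # site falls in clusters on both strands


class ClusterIndex:
    """Per-(chrom, strand) sorted-array lookup; same-strand clusters are
    disjoint by construction so containment is a single bisection."""

    def __init__(self, clusters: list[GeneCluster]):
        self.clusters = clusters
        self._by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[GeneCluster]]] = {}
        grouped: dict[tuple[str, str], list[GeneCluster]] = {}
        for c in clusters:
            grouped.setdefault((c.chrom, c.strand), []).append(c)
        for key, group in grouped.items():
            group.sort(key=lambda c: c.start)
            starts = np.array([c.start for c in group], dtype=np.int64)
            ends = np.array([c.end for c in group], dtype=np.int64)
            self._by_key[key] = (starts, ends, group)

    def containing(self, chrom: str, position: int) -> list[GeneCluster]:
        hits = []
        for strand in "+-":
            entry = self._by_key.get((chrom, strand))
            if entry is None:
                continue
            starts, ends, group = entry
            i = int(np.searchsorted(starts, position, side="right")) - 1
            if i >= 0 and position < ends[i]:
                hits.append(group[i])
        return hits


def assign_site(
    site_id: str, chrom: str, position: int, strand: str, index: ClusterIndex
) -> list[GeneAssignment]:
    """All cluster assignments for one mapped site.

    A site inside overlapping opposite-strand clusters yields one assignment
    per cluster, flagged multi.  A site in no cluster yields a single
    intergenic record with cluster_id None.
    """
    hits = index.containing(chrom, position)
    if not hits:
        return [GeneAssignment(site_id, None, False, False, False, -1)]
    multi = len(hits) > 1
    out = []
    for c in hits:
        sense = strand == c.strand
        out.append(
            GeneAssignment(site_id, c.cluster_id, True, sense, sense,
                           c.dist_to_tss(position), multi)
        )
    return out


def assign_sites(sites: pd.DataFrame, clusters: list[GeneCluster]) -> pd.DataFrame:
    """Assignment table for every mapped site in a SiteRecord table."""
    index = ClusterIndex(clusters)
    rows = []
    mapped = sites[sites["status"] == "mapped"]
    for _, s in mapped.iterrows():
        for a in assign_site(s["read_id"], s["chrom"], int(s["position"]), s["strand"], index):
            rows.append(
                dict(site_id=a.site_id, cluster_id=a.cluster_id, intragenic=a.intragenic,
                     sense=a.sense, assigned=a.assigned, dist_to_tss=a.dist_to_tss,
                     multi=a.multi, vector=s["vector"], phenotype=s["phenotype"])
            )
    cols = ["site_id", "cluster_id", "intragenic", "sense", "assigned",
            "dist_to_tss", "multi", "vector", "phenotype"]
    return pd.DataFrame(rows, columns=cols)


POOLS = ["LVtotal", "MLVtotal", "LV-REP", "LV-NREP", "MLV-REP", "MLV-NREP"]


def intragenic_fraction(assignments: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-pool intragenic accounting over mapped sites.

    Pools follow the vector x phenotype breakdown (LVtotal, MLVtotal and the
    four REP/NREP subsets).  ``frac_assigned`` counts sense-oriented
    intragenic sites ("mapped relative to" a gene); ``frac_intragenic_any``
    counts intragenic sites regardless of orientation.  Pools with zero
    mapped sites report NA.
    """
    mapped = sites[sites["status"] == "mapped"]
    per_site = assignments.groupby("site_id").agg(
        intragenic=("intragenic", "any"), assigned=("assigned", "any")
    )
    rows = []
    for pool in POOLS:
        if pool.endswith("total"):
            sel = mapped[mapped["vector"] == pool[:-5]]
        else:
            vec, phen = pool.split("-")
            sel = mapped[(mapped["vector"] == vec) & (mapped["phenotype"] == phen)]
        n = len(sel)
        if n == 0:
            rows.append(dict(pool=pool, n_mapped=0, n_intragenic=0, n_assigned=0,
                             frac_intragenic_any=np.nan, frac_assigned=np.nan))
            continue
        flags = per_site.reindex(sel["read_id"]).fillna(False)
        n_intra = int(flags["intragenic"].sum())
        n_assigned = int(flags["assigned"].sum())
        rows.append(dict(pool=pool, n_mapped=n, n_intragenic=n_intra,
                         n_assigned=n_assigned,
                         frac_intragenic_any=n_intra / n,
                         frac_assigned=n_assigned / n))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_refflat(path) -> list[Transcript]:
    """Read a refFlat-like TSV: name, chrom, strand, txStart, txEnd
    (0-based half-open, UCSC convention).  A header line is tolerated."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            if lineno == 1 and parts[0] == "name":
                continue
            t = Transcript(parts[0], parts[1], parts[2], int(parts[3]), int(parts[4]))
            t.validate()
            out.append(t)
    return out


def write_refflat(transcripts: Iterable[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstrand\ttxStart\ttxEnd\n")
        for t in transcripts:
            fh.write(f"{t.name}\t{t.chrom}\t{t.strand}\t{t.start}\t{t.end}\n")


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(cluster_id=c.cluster_id, chrom=c.chrom, strand=c.strand, start=c.start,
              end=c.end, tss=c.tss, size=c.size, n_distinct_tss=c.n_distinct_tss,
              members=",".join(c.members)) for c in clusters]
    )


def write_clusters_tsv(clusters: list[GeneCluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def clusters_to_bed(clusters: list[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t0\t{c.strand}\n")
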