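"""Phenotype pools and silencing-response gene groups.

Integrants split into repressing (REP) and non-repressing (NREP) pools per
vector.  Genes that are at least 20 kb long, have a single known TSS, and
were hit at least three times are classified by where their repressing and
non-repressing integrants sit relative to the promoter:

* group 1 ("long-range repression") — mostly repressing integrants across
  the first 20 kb, with repression reaching beyond 10 kb;
* group 2 ("limited repression") — repression confined to the first 10 kb,
  with non-repressing integrants dominating between 10 and 20 kb;
* group 3 ("absence of repression") — mostly non-repressing integrants.

"Mostly" is operationalized as a configurable majority fraction (default
2/3), reported in output headers so calls are auditable.  When a gene
satisfies more than one rule the precedence is group 1, then group 3, then
group 2 (a gene with a strong overall REP majority is long-range even if its
distal window happens to be NREP-tilted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import GeneCluster


@dataclass(frozen=True)
class GroupConfig:
    min_gene_size: int = 20_000
    min_hits: int = 3
    require_single_tss: bool = True
    window_full: int = 20_000
    window_proximal: int = 10_000
    majority_fraction: float = 2 / 3

    def __post_init__(self) -> None:
        if not self.window_proximal < self.window_full:
            raise ValueError("window_proximal must be < window_full")
        if not 0.5 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0.5, 1]")
        if self.min_hits < 1 or self.min_gene_size < 1:
            raise ValueError("min_hits and min_gene_size must be positive")


@dataclass
class GeneGroupCall:
    cluster_id: str
    group: str  # "1" | "2" | "3" | "unclassified"
    n_rep: int
    n_nrep: int
    rep_positions: list[int] = field(default_factory=list)
    nrep_positions: list[int] = field(default_factory=list)
    reason: str = ""


def pool_split(sites: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Partition labelled sites by (vector, phenotype); counts conserved.

    All four pools are present even when empty; an unknown label raises.
    """
    pools = {(v, p): sites.iloc[0:0] for v in ("LV", "MLV") for p in ("REP", "NREP")}
    labelled = sites[sites["vector"].notna() & (sites["vector"] != "")]
    for (v, p), df in labelled.groupby(["vector", "phenotype"]):
        if (v, p) not in pools:
            raise ValueError(f"unknown class label {(v, p)}")
        pools[(v, p)] = df
    return pools


def select_candidates(
    assignments: pd.DataFrame, clusters: list[GeneCluster], cfg: GroupConfig
) -> dict[str, pd.DataFrame]:
    """Genes eligible for phenotype-group classification.

    Keeps clusters spanning >= min_gene_size, with a single distinct TSS when
    required, and hit at least min_hits times by sense-oriented integrants
    within window_full of the TSS.  Returns cluster_id -> its qualifying
    assignment rows.
    """
    by_id = {c.cluster_id: c for c in clusters}
    hits = assignments[
        assignments["assigned"] & (assignments["dist_to_tss"] <= cfg.window_full)
    ]
    out: dict[str, pd.DataFrame] = {}
    for cid, rows in hits.groupby("cluster_id"):
        c = by_id[cid]
        if c.size < cfg.min_gene_size:
            continue
        if cfg.require_single_tss and c.n_distinct_tss != 1:
            continue
        if len(rows) < cfg.min_hits:
            continue
        out[cid] = rows
    return out


def classify_gene(
    cluster_id: str,
    rep_positions: list[int],
    nrep_positions: list[int],
    cfg: GroupConfig,
) -> GeneGroupCall:
    """Assign one candidate gene to group 1/2/3 or leave it unclassified.

    Positions are distances to the TSS, already restricted to
    [0, window_full].  The group-2 rule requires occupancy of both the
    proximal and the distal window; a gene with hits only below 10 kb cannot
    be told apart from group 1 and stays unclassified.
    """
    rep = sorted(rep_positions)
    nrep = sorted(nrep_positions)
    n_rep, n_nrep = len(rep), len(nrep)
    total = n_rep + n_nrep
    call = GeneGroupCall(cluster_id, "unclassified", n_rep, n_nrep, rep, nrep)
    if total == 0:
        call.reason = "no_hits"
        return call
    maj = cfg.majority_fraction
    frac_rep = n_rep / total
    has_distal_rep = any(cfg.window_proximal < p <= cfg.window_full for p in rep)
    if frac_rep >= maj and has_distal_rep:
        call.group = "1"
        return call
    if (1 - frac_rep) >= maj:
        call.group = "3"
        return call
    prox = [(p, "R") for p in rep if p <= cfg.window_proximal] + [
        (p, "N") for p in nrep if p <= cfg.window_proximal
    ]
    dist = [(p, "R") for p in rep if p > cfg.window_proximal] + [
        (p, "N") for p in nrep if p > cfg.window_proximal
    ]
    if prox and dist:
        fr_prox = sum(1 for _, k in prox if k == "R") / len(prox)
        fn_dist = sum(1 for _, k in dist if k == "N") / len(dist)
        if fr_prox >= maj and fn_dist >= maj:
            call.group = "2"
            return call
    call.reason = "no_rule_matched"
    return call


def classify_genes(
    candidates: dict[str, pd.DataFrame], cfg: GroupConfig
) -> list[GeneGroupCall]:
    calls = []
    for cid in sorted(candidates):
        rows = candidates[cid]
        rep = rows.loc[rows["phenotype"] == "REP", "dist_to_tss"].astype(int).tolist()
        nrep = rows.loc[rows["phenotype"] == "NREP", "dist_to_tss"].astype(int).tolist()
        calls.append(classify_gene(cid, rep, nrep, cfg))
    return calls


def calls_to_frame(calls: list[GeneGroupCall], cfg: GroupConfig) -> pd.DataFrame:
    df = pd.DataFrame(
        [dict(cluster_id=c.cluster_id, group=c.group, n_rep=c.n_rep, n_nrep=c.n_nrep,
              rep_positions=",".join(map(str, c.rep_positions)),
              nrep_positions=",".join(map(str, c.nrep_positions)),
              reason=c.reason) for c in calls]
    )
    df.attrs["majority_fraction"] = cfg.majority_fraction
    return df


def write_groups_tsv(calls: list[GeneGroupCall], cfg: GroupConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# majority_fraction={cfg.majority_fraction:.4f} "
                 f"window_full={cfg.window_full} window_proximal={cfg.window_proximal} "
                 f"min_gene_size={cfg.min_gene_size} min_hits={cfg.min_hits}\n")
        calls_to_frame(calls, cfg).to_csv(fh, sep="\t", index=False)
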