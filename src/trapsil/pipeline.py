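"""End-to-end driver: reads -> sites -> genes -> groups -> enrichment scan.

``run_all`` executes the full chain (demultiplex, tag mapping, gene-model
construction, assignment, phenotype pools, gene-group calls, matched-control
ROC heatmap with REP-vs-NREP contrasts) and writes a versioned manifest
mirroring the per-stage accounting of the read-processing funnel: total
reads, kept/discarded by reason, mapping outcomes, per-pool intragenic
counts, and genes per silencing group.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, features, grouping, readproc, roc
from .grouping import GroupConfig
from .readproc import BarcodeScheme


@dataclass
class RunConfig:
    reads: str
    genome: str
    transcripts: str
    outdir: str
    tracks: dict[str, str] = field(default_factory=dict)  # name -> .bed/.sga path
    expression: str | None = None
    seed: int = 0
    n_controls: int = 10
    control_mode: str = "uniform"
    scales: tuple[int, ...] = features.REDUCED_SCALES
    scheme: BarcodeScheme = field(default_factory=BarcodeScheme)
    group_config: GroupConfig = field(default_factory=GroupConfig)
    add_sequence_tracks: bool = True  # derive GC / CpG-density from the genome

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "group_config" in raw:
            raw["group_config"] = GroupConfig(**raw["group_config"])
        if "scheme" in raw:
            sch = raw["scheme"]
            if "barcodes" in sch:
                sch["barcodes"] = {k: tuple(v) for k, v in sch["barcodes"].items()}
            raw["scheme"] = BarcodeScheme(**sch)
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_tracks(cfg: RunConfig, sequences: dict[str, str]) -> dict[str, features.FeatureTrack]:
    tracks: dict[str, features.FeatureTrack] = {}
    for name, path in cfg.tracks.items():
        if str(path).endswith(".bed"):
            tracks[name] = features.read_bed(path, name)
        elif str(path).endswith(".sga"):
            tracks[name] = features.read_sga(path, name)
        else:
            raise ValueError(f"track {name}: unknown format {path} (need .bed or .sga)")
    if cfg.add_sequence_tracks:
        tracks.setdefault("GC_content",
                          features.sequence_track("GC_content", sequences, "sequence_gc"))
        tracks.setdefault("CpG_density",
                          features.sequence_track("CpG_density", sequences, "sequence_cpg"))
    return tracks


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {"reads": cfg.reads, "genome": cfg.genome, "transcripts": cfg.transcripts}
    inputs.update({f"track:{k}": v for k, v in cfg.tracks.items()})
    if cfg.expression:
        inputs["expression"] = cfg.expression

    genome = dict(readproc.read_fasta(cfg.genome))
    reads = list(readproc.read_fasta(cfg.reads))

    # demultiplex + map
    sites = readproc.process_reads(reads, genome, cfg.scheme)
    readproc.write_sites_tsv(sites, out / "sites.tsv")

    # gene model + assignment
    transcripts = annotation.read_refflat(cfg.transcripts)
    clusters = annotation.cluster_transcripts(transcripts)
    annotation.write_clusters_tsv(clusters, out / "clusters.tsv")
    assignments = annotation.assign_sites(sites, clusters)
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    intragenic = annotation.intragenic_fraction(assignments, sites)
    intragenic.to_csv(out / "intragenic.tsv", sep="\t", index=False)

    # pools + gene groups
    mapped = sites[sites["status"] == "mapped"]
    pools = grouping.pool_split(mapped)
    candidates = grouping.select_candidates(assignments, clusters, cfg.group_config)
    calls = grouping.classify_genes(candidates, cfg.group_config)
    grouping.write_groups_tsv(calls, cfg.group_config, out / "groups.tsv")

    # matched-control ROC heatmap + REP-vs-NREP contrasts
    tracks = _load_tracks(cfg, genome)
    controls = roc.matched_controls(
        mapped, genome, n_controls=cfg.n_controls, mode=cfg.control_mode, seed=cfg.seed
    )
    site_groups = {f"{v}-{p}": df for (v, p), df in pools.items() if len(df)}
    heat = roc.heatmap_matrix(site_groups, tracks, cfg.scales, controls,
                              sequences=genome)
    heat = _add_contrasts(heat, site_groups, tracks, cfg, controls, genome)
    heat.to_csv(out / "heatmap.tsv", sep="\t", index=False)

    manifest = {
        "config": _config_dict(cfg),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "counts": {
            "total_reads": len(reads),
            "kept": int((sites["status"] != "discarded").sum()),
            "discarded": int((sites["status"] == "discarded").sum()),
            "discard_reasons": sites.loc[sites["status"] == "discarded", "reason"]
                                    .value_counts().to_dict(),
            "by_status": sites["status"].value_counts().to_dict(),
            "per_class": sites.loc[sites["status"] != "discarded", "barcode_class"]
                              .value_counts().to_dict(),
            "pool_sizes": {f"{v}-{p}": int(len(df)) for (v, p), df in pools.items()},
            "intragenic": intragenic.to_dict(orient="records"),
            "n_clusters": len(clusters),
            "n_candidate_genes": len(candidates),
            "genes_per_group": pd.Series([c.group for c in calls])
                                 .value_counts().to_dict(),
        },
        "outputs": {p.name: str(p) for p in sorted(out.glob("*.tsv"))},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["scheme"]["barcodes"] = {k: list(v) for k, v in d["scheme"]["barcodes"].items()}
    d["scales"] = list(d["scales"])
    return d


def _add_contrasts(heat, site_groups, tracks, cfg, controls, genome):
    """REP vs NREP comparison per vector for every (feature, scale) cell."""
    chrom_len = {c: len(s) for c, s in genome.items()}

    def values_for(df, track, hw):
        case, ctrl = [], []
        for _, s in df.iterrows():
            case.append(features.quantify(track, s["chrom"], int(s["position"]), hw,
                                          chrom_length=chrom_len.get(s["chrom"])))
            ctrl.append([features.quantify(track, cc, int(cp), hw,
                                           chrom_length=chrom_len.get(cc))
                         for cc, cp, _ in controls[s["read_id"]].controls])
        return case, ctrl

    heat = heat.copy()
    for col in ("p_chi2", "p_perm", "stars"):
        heat[col] = "" if col == "stars" else float("nan")
    for vec in ("LV", "MLV"):
        a, b = f"{vec}-REP", f"{vec}-NREP"
        if a not in site_groups or b not in site_groups:
            continue
        for fname, track in tracks.items():
            for hw in cfg.scales:
                label = features.IntervalScale(int(hw)).label
                ca, xa = values_for(site_groups[a], track, int(hw))
                cb, xb = values_for(site_groups[b], track, int(hw))
                try:
                    res = roc.compare_groups(ca, xa, cb, xb, seed=cfg.seed)
                except ValueError:
                    continue
                sel = (heat["group"] == a) & (heat["feature"] == fname) \
                    & (heat["scale"] == label)
                heat.loc[sel, "p_chi2"] = res["p_chi2"]
                heat.loc[sel, "p_perm"] = res["p_perm"]
                heat.loc[sel, "stars"] = roc.significance_stars(res["p_chi2"])
    raw = pd.to_numeric(heat["p_chi2"], errors="coerce")
    mask = raw.notna()
    heat["q_bh"] = float("nan")
    if mask.any():
        heat.loc[mask, "q_bh"] = roc.benjamini_hochberg(raw[mask].to_numpy())
    return heat


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def report(manifest: dict) -> str:
    """Human-readable run summary: the read-accounting funnel, per-pool
    intragenic table, and gene-group tallies; every number comes straight
    from a manifest field."""
    c = manifest.get("counts", {})
    lines = ["# trapsil run report", ""]
    lines += ["## Read accounting",
              f"total reads      {c.get('total_reads', 0)}",
              f"kept             {c.get('kept', 0)}",
              f"discarded        {c.get('discarded', 0)}"]
    for reason, n in sorted(c.get("discard_reasons", {}).items()):
        lines.append(f"  - {reason:<18} {n}")
    lines += ["", "## Mapping outcomes"]
    for status, n in sorted(c.get("by_status", {}).items()):
        lines.append(f"{status:<12} {n}")
    lines += ["", "## Pools x intragenic (sites isolated / mapped / intragenic-sense)"]
    for row in c.get("intragenic", []):
        frac = row["frac_assigned"]
        frac_s = "NA" if frac != frac else f"{100 * frac:.1f}%"
        lines.append(f"{row['pool']:<10} mapped={row['n_mapped']:<6} "
                     f"intragenic={row['n_assigned']:<6} ({frac_s})")
    lines += ["", "## Gene groups"]
    for grp in ("1", "2", "3", "unclassified"):
        lines.append(f"group {grp:<13} {c.get('genes_per_group', {}).get(grp, 0)}")
    if "outputs" in manifest:
        lines += ["", "## Output tables"]
        lines += [f"  {name}" for name in sorted(manifest["outputs"])]
    return "\n".join(lines) + "\n"
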