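"""Stage orchestration: run each analysis stage on configured inputs and
write its TSV outputs, plus the collated summary report.

This sits between the analysis modules and the command-line interface; every
stage is a plain function taking a :class:`RunConfig` and an output directory,
so the stages are equally usable from Python. All output tables are sorted by
their primary key so re-running a stage on unchanged inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import genome_position, go_profile, library_stats, orf_pseudo, similarity, snp, ssr
from .formats import (
    FormatError,
    SeqRecord,
    read_clusters,
    read_fasta,
    read_gff,
    read_go,
    read_hits,
    read_msa,
    read_slim_map,
    read_taxmap,
)


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run. Paths are resolved relative
    to the config file's directory when loaded from YAML."""

    unique_fasta: Optional[str] = None
    clusters: Optional[str] = None
    alignments: Optional[str] = None
    genome_fasta: Optional[str] = None
    gff: Optional[str] = None
    hits_nr: Optional[str] = None
    hits_genome: Optional[str] = None
    hits_pseudo: Optional[str] = None
    proteome_hits: dict = field(default_factory=dict)
    candidate_missing_db: Optional[str] = None
    taxmap: Optional[str] = None
    go_annotations: Optional[str] = None
    go_slim_map: Optional[str] = None
    categories: list = field(default_factory=list)
    evalue_protein: float = 1e-5
    evalue_genome: float = 1e-8
    utr_max: int = genome_position.DEFAULT_UTR_MAX
    orf_min_len: int = orf_pseudo.DEFAULT_MIN_ORF_NT
    ssr_thresholds: dict = field(default_factory=lambda: dict(ssr.DEFAULT_THRESHOLDS))
    ssr_max_gap: int = ssr.DEFAULT_MAX_COMPOUND_GAP
    snp_min_depth: int = snp.DEFAULT_MIN_DEPTH
    snp_min_maf: float = snp.DEFAULT_MIN_MAF
    snp_min_occurrence: int = snp.DEFAULT_MIN_OCCURRENCE
    alpha: float = 0.05
    correction: str = "bonferroni"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        import dataclasses as _dc

        known = {f.name for f in _dc.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        base = path.parent
        for key in ("unique_fasta", "clusters", "alignments", "genome_fasta",
                    "gff", "hits_nr", "hits_genome", "hits_pseudo", "taxmap",
                    "go_annotations", "go_slim_map"):
            val = getattr(cfg, key)
            if val is not None:
                setattr(cfg, key, str((base / val).resolve()))
        cfg.proteome_hits = {
            db: str((base / p).resolve()) for db, p in cfg.proteome_hits.items()
        }
        if cfg.ssr_thresholds:
            cfg.ssr_thresholds = {int(k): int(v) for k, v in cfg.ssr_thresholds.items()}
        return cfg

    def category_rules(self) -> list[tuple[str, object]]:
        rules = []
        for entry in self.categories:
            taxa = entry["taxa"]
            rules.append((entry["label"], taxa if taxa == "*" else set(taxa)))
        return rules

    def require(self, *keys: str) -> None:
        missing = [k for k in keys if not getattr(self, k)]
        if missing:
            raise FileNotFoundError(
                "missing required inputs: " + ", ".join(f"--{k}" for k in missing)
            )
        for k in keys:
            val = getattr(self, k)
            if isinstance(val, str) and not Path(val).exists():
                raise FileNotFoundError(f"input for --{k} not found: {val}")


def _write_tsv(df: pd.DataFrame, path, float_format="%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# stages

def stage_stats(cfg: RunConfig, outdir: Path) -> Path:
    cfg.require("clusters", "unique_fasta")
    clusters = read_clusters(cfg.clusters)
    seqs = read_fasta(cfg.unique_fasta)
    summary = library_stats.assembly_summary(clusters, seqs)
    gc = library_stats.gc_content(seqs)
    contig_seqs = [s for s in seqs if s.id in clusters.contig_members]
    rows = [
        ("n_ests", summary.n_ests),
        ("n_contigs", summary.n_contigs),
        ("n_singletons", summary.n_singletons),
        ("n_unique", summary.n_unique),
        ("mean_per_contig", round(summary.mean_per_contig, 2)),
        ("max_per_contig", summary.max_per_contig),
        ("contig_len_mean", round(summary.contig_len_mean, 2)),
        ("contig_len_max", summary.contig_len_max),
        ("gc_percent", round(gc * 100, 2)),
    ]
    if contig_seqs:
        ls = library_stats.length_stats(contig_seqs)
        rows.append(("contig_len_mean_check", round(ls["mean"], 2)))
    out = outdir / "assembly_stats.tsv"
    _write_tsv(pd.DataFrame(rows, columns=["statistic", "value"]), out)
    return out


def stage_annotate(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("hits_nr", "taxmap", "unique_fasta")
    seqs = read_fasta(cfg.unique_fasta)
    hits = read_hits(cfg.hits_nr)
    best = similarity.best_hits(hits, cfg.evalue_protein, source_db="nr")
    taxmap = read_taxmap(cfg.taxmap)
    tally = similarity.taxon_tally(best, taxmap, cfg.category_rules(), len(seqs))
    df = pd.DataFrame(
        [(lab, n) for lab, n in tally.counts.items()] + [("No hits", tally.no_hits)],
        columns=["category", "count"],
    )
    out1 = outdir / "taxon_tally.tsv"
    _write_tsv(df, out1)
    red = similarity.redundancy_estimate(best, len(seqs))
    out2 = outdir / "redundancy.tsv"
    _write_tsv(pd.DataFrame([red]), out2)
    outs = [out1, out2]
    if cfg.proteome_hits:
        tables = {db: read_hits(p) for db, p in sorted(cfg.proteome_hits.items())}
        matrix = similarity.cross_proteome(tables, cfg.evalue_protein)
        df = matrix.presence.reset_index().rename(columns={"index": "qseqid"})
        out3 = outdir / "cross_proteome.tsv"
        _write_tsv(df.sort_values("qseqid"), out3)
        outs.append(out3)
        if cfg.candidate_missing_db:
            cands = matrix.candidates(cfg.candidate_missing_db)
            out4 = outdir / "candidates.tsv"
            _write_tsv(pd.DataFrame({"qseqid": cands}), out4)
            outs.append(out4)
    return outs


def stage_go_profile(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("go_annotations", "go_slim_map")
    annots = go_profile.filter_annotations(read_go(cfg.go_annotations))
    slim_map = read_slim_map(cfg.go_slim_map)
    tallies = go_profile.slim_tally(annots, slim_map)
    rows = []
    for t in tallies:
        for term, count in t.counts.items():
            rows.append((t.namespace, term, count, round(t.percents[term], 1)))
    out = outdir / "go_slim_tally.tsv"
    _write_tsv(
        pd.DataFrame(rows, columns=["namespace", "slim_term", "count", "percent"]), out
    )
    return [out]


def stage_classify(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("hits_genome", "gff")
    hits = read_hits(cfg.hits_genome)
    best = similarity.best_hits(hits, cfg.evalue_genome, source_db="genome")
    best_ids = {b.qseqid for b in best}
    # keep the single best row per query (best_hits gives the winners)
    chosen: dict[str, object] = {}
    for h in hits:
        if h.qseqid not in best_ids or h.evalue > cfg.evalue_genome:
            continue
        b = chosen.get(h.qseqid)
        if b is None or (h.evalue, -h.bitscore, h.sseqid) < (
            b.evalue, -b.bitscore, b.sseqid
        ):
            chosen[h.qseqid] = h
    features = read_gff(cfg.gff)
    cls, summary = genome_position.classify_all(
        sorted(chosen.values(), key=lambda h: h.qseqid), features, cfg.utr_max
    )
    df = pd.DataFrame(
        [
            (c.qseqid, c.seqid, c.start, c.end, c.cls,
             "" if c.distance_to_nearest_cds is None else c.distance_to_nearest_cds,
             c.nearest_feature_id or "")
            for c in cls
        ],
        columns=["qseqid", "seqid", "start", "end", "class", "distance", "nearest_cds"],
    )
    out1 = outdir / "hit_classes.tsv"
    _write_tsv(df, out1)
    out2 = outdir / "class_summary.tsv"
    _write_tsv(
        pd.DataFrame(sorted(summary.items()), columns=["class", "count"]), out2
    )
    out3 = outdir / "seqid_distribution.tsv"
    _write_tsv(genome_position.seqid_distribution(cls, features), out3)
    return [out1, out2, out3]


def stage_orfs(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("unique_fasta")
    seqs = read_fasta(cfg.unique_fasta)
    all_orfs = []
    for rec in seqs:
        if len(rec) >= 3:
            all_orfs.extend(orf_pseudo.find_orfs(rec, min_len=cfg.orf_min_len))
    df = pd.DataFrame(
        [
            (o.seq_id, o.strand, o.frame, o.start, o.end, o.length_nt,
             int(o.incomplete_3prime))
            for o in all_orfs
        ],
        columns=["seq_id", "strand", "frame", "start", "end", "length_nt",
                 "incomplete_3prime"],
    ).sort_values(["seq_id", "start", "end"])
    out1 = outdir / "orfs.tsv"
    _write_tsv(df, out1)
    stats = orf_pseudo.orf_stats(all_orfs)
    out2 = outdir / "orf_stats.tsv"
    _write_tsv(pd.DataFrame([stats] if stats else []), out2)
    return [out1, out2]


def stage_stop_screen(cfg: RunConfig, outdir: Path) -> Path:
    cfg.require("genome_fasta", "hits_pseudo")
    genome = {r.id: r for r in read_fasta(cfg.genome_fasta)}
    hits = read_hits(cfg.hits_pseudo)
    rows = []
    for h in sorted(hits, key=lambda h: (h.qseqid, h.sseqid, h.sstart)):
        if h.frame is None:
            raise FormatError(f"hit {h.qseqid} lacks the frame column", cfg.hits_pseudo)
        lo, hi = h.subject_interval
        region = SeqRecord(id=h.sseqid, sequence=genome[h.sseqid].sequence[lo:hi])
        span = (0, (hi - lo) // 3)
        screen = orf_pseudo.premature_stop_screen(
            "", region, h.frame, span, query_id=h.qseqid
        )
        rows.append(
            (h.qseqid, h.sseqid, lo, hi, h.frame, screen.n_premature_stops,
             ";".join(map(str, screen.stop_positions)), screen.verdict)
        )
    out = outdir / "stop_screen.tsv"
    _write_tsv(
        pd.DataFrame(rows, columns=["query", "seqid", "start", "end", "frame",
                                    "n_premature_stops", "stop_positions", "verdict"]),
        out,
    )
    return out


def stage_ssr(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("unique_fasta")
    seqs = read_fasta(cfg.unique_fasta)
    records = []
    for rec in seqs:
        found = ssr.find_ssrs(rec, cfg.ssr_thresholds)
        records.extend(ssr.group_compound(found, cfg.ssr_max_gap))
    df = pd.DataFrame(
        [
            (r.seq_id, r.motif, r.canonical_motif, r.repeats, r.start + 1, r.end,
             r.compound_group or "")
            for r in records
        ],
        columns=["seq_id", "motif", "canonical_motif", "repeats", "start", "end",
                 "compound_group"],
    ).sort_values(["seq_id", "start"])
    out1 = outdir / "ssrs.tsv"
    _write_tsv(df, out1)
    summary = ssr.ssr_summary(records)
    rows = [
        (f"{p}-mer", c["count"], round(c["mean_repeats"], 2),
         c["min_repeats"], c["max_repeats"])
        for p, c in summary["classes"].items()
    ]
    rows.append(("total", summary["total"], "", "", ""))
    rows.append(("sequences_with_ssr", summary["n_sequences_with_ssr"], "", "", ""))
    rows.append(("in_compound", summary["n_records_in_compound"], "", "", ""))
    rows.append(("compound_groups", summary["n_compound_groups"], "", "", ""))
    out2 = outdir / "ssr_summary.tsv"
    _write_tsv(
        pd.DataFrame(rows, columns=["class", "count", "mean_repeats",
                                    "min_repeats", "max_repeats"]), out2
    )
    return [out1, out2]


def stage_snp(cfg: RunConfig, outdir: Path) -> list[Path]:
    cfg.require("alignments", "clusters")
    clusters = read_clusters(cfg.clusters)
    blocks = read_msa(cfg.alignments)
    elig = snp.eligible_contigs(clusters, blocks, cfg.snp_min_depth)
    eligible = set(elig["eligible"])
    records = []
    for block in sorted(blocks, key=lambda b: b.contig_id):
        if block.contig_id not in eligible:
            continue
        records.extend(
            snp.call_snps(block, cfg.snp_min_depth, cfg.snp_min_maf,
                          cfg.snp_min_occurrence)
        )
    df = pd.DataFrame(
        [
            (r.contig_id, r.column + 1, r.major_allele, r.minor_allele, r.depth,
             r.minor_count, round(r.maf, 4), int(r.multiallelic))
            for r in records
        ],
        columns=["contig_id", "column", "major", "minor", "depth", "minor_count",
                 "maf", "multiallelic"],
    )
    out1 = outdir / "snps.tsv"
    _write_tsv(df, out1)
    summary = snp.snp_summary(records)
    summary.update(
        n_eligible_contigs=len(elig["eligible"]),
        coverage_bases=elig["coverage_bases"],
        n_missing_alignments=len(elig["missing"]),
    )
    out2 = outdir / "snp_summary.tsv"
    _write_tsv(pd.DataFrame([summary]), out2)
    return [out1, out2]


STAGE_FUNCS = {
    "stats": stage_stats,
    "annotate": stage_annotate,
    "go-profile": stage_go_profile,
    "classify-hits": stage_classify,
    "orfs": stage_orfs,
    "stop-screen": stage_stop_screen,
    "ssr": stage_ssr,
    "snp": stage_snp,
}

REPORT_ORDER = [
    ("Assembly", "assembly_stats.tsv"),
    ("Taxonomic distribution of best hits", "taxon_tally.tsv"),
    ("Redundancy and unique-gene estimate", "redundancy.tsv"),
    ("GO-slim distribution", "go_slim_tally.tsv"),
    ("Genome hit classification", "class_summary.tsv"),
    ("Hits per genomic sequence", "seqid_distribution.tsv"),
    ("ORF statistics", "orf_stats.tsv"),
    ("Premature stop-codon screen", "stop_screen.tsv"),
    ("SSR markers", "ssr_summary.tsv"),
    ("SNP markers", "snp_summary.tsv"),
]


def run_all(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("stats", "annotate", "go-profile", "classify-hits", "orfs",
                 "stop-screen", "ssr", "snp"):
        STAGE_FUNCS[name](cfg, outdir)
    write_manifest(cfg, outdir)


def write_report(outdir: Path) -> Path:
    outdir = Path(outdir)
    missing = [f for _, f in REPORT_ORDER if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError("missing stage outputs: " + ", ".join(missing))
    out = outdir / "report.txt"
    with open(out, "w") as fh:
        fh.write("EST library characterization report\n")
        fh.write("=" * 36 + "\n")
        for title, fname in REPORT_ORDER:
            fh.write(f"\n## {title}\n")
            fh.write((outdir / fname).read_text())
    return out


def write_manifest(cfg: RunConfig, outdir: Path) -> Path:
    import dataclasses as _dc

    from . import __version__

    cfg_json = json.dumps(_dc.asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {},
    }
    for p in sorted(Path(outdir).glob("*.tsv")):
        with open(p) as fh:
            n_rows = max(0, sum(1 for _ in fh) - 1)
        manifest["outputs"][p.name] = n_rows
    out = Path(outdir) / "run_manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
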