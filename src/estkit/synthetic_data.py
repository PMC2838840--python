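"""Synthetic toy genome, transcriptome and EST library with known ground truth.

The generator emulates the data flow of a normalised 5'-read EST project:
a small multi-chromosome genome carrying UTR+CDS genes, transcripts read 5'
to 3' with slight start-offset jitter, clustering of reads by source
transcript into contigs and singletons, gap-padded per-contig alignments, and
oracle similarity-hit tables derived from known provenance (the pipeline
under test consumes hit tables; it does not run an aligner).

Planted features — microsatellites with guard bases, biallelic alignment
columns at a requested minor-allele frequency, pseudogenized gene copies with
in-frame premature stops, and genes deleted from individual reference
proteomes — are registered in a :class:`GroundTruth` object so every detector
can be scored exactly. Background sequence is actively scrubbed of chance
microsatellites (with stop-codon-aware substitutions inside coding frames) so
planted-marker precision is measurable, not just recall.

Everything is driven by one integer-seeded numpy generator; a fixed seed
yields byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import ssr as ssr_mod
from .formats import (
    ClusterTable,
    GenomeFeature,
    HitRecord,
    MsaBlock,
    SeqRecord,
    write_clusters,
    write_fasta,
    write_gff,
    write_hits,
    write_msa,
)
from .orf_pseudo import STOP_CODONS, _revcomp

BASES = "ACGT"

# species -> weight; ordered category rules group species into the taxonomic
# tally categories (genus rule before the family rule that contains it).
SPECIES_WEIGHTS = {
    "Apis mellifera": 0.45,
    "Apis cerana": 0.25,
    "Nasonia vitripennis": 0.12,
    "Bombus impatiens": 0.05,
    "Formica exsecta": 0.03,
    "Drosophila melanogaster": 0.04,
    "Tribolium castaneum": 0.03,
    "Homo sapiens": 0.03,
}
DEFAULT_CATEGORIES: list[tuple[str, object]] = [
    ("Apis spp.", ["Apis mellifera", "Apis cerana"]),
    ("Nasonia vitripennis", ["Nasonia vitripennis"]),
    ("Other Hymenoptera", ["Bombus impatiens", "Formica exsecta"]),
    ("Diptera", ["Drosophila melanogaster"]),
    ("Coleoptera", ["Tribolium castaneum"]),
    ("Other", "*"),
]

# small fixed GO vocabulary: go_id -> (slim term, namespace)
GO_VOCAB: dict[str, tuple[str, str]] = {
    "GO:0005524": ("binding", "molecular_function"),
    "GO:0003677": ("binding", "molecular_function"),
    "GO:0016301": ("catalytic activity", "molecular_function"),
    "GO:0016787": ("catalytic activity", "molecular_function"),
    "GO:0022857": ("transporter activity", "molecular_function"),
    "GO:0006096": ("metabolic process", "biological_process"),
    "GO:0019538": ("metabolic process", "biological_process"),
    "GO:0007165": ("cell communication", "biological_process"),
    "GO:0006810": ("transport", "biological_process"),
    "GO:0005886": ("membrane", "cellular_component"),
    "GO:0005737": ("intracellular", "cellular_component"),
    "GO:0005634": ("intracellular", "cellular_component"),
    "GO:0005615": ("extracellular", "cellular_component"),
}
EVIDENCE_WEIGHTS = {"TAS": 0.30, "IDA": 0.25, "IMP": 0.15, "IEA": 0.30}


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic genome and EST library.

    Distribution parameters are inclusive uniform bounds. Defaults are a
    desk-scale rendition of a normalised 5'-read EST study: mean ~4 reads
    per contig with a contig/singleton mix, 36% GC, Sanger-length reads,
    and planted marker/pseudogene/deletion features at realistic per-library
    counts.
    """

    seed: int = 0
    n_chromosomes: int = 3
    n_genes: int = 120
    cds_codons: tuple[int, int] = (60, 300)
    utr5_len: tuple[int, int] = (10, 80)
    utr3_len: tuple[int, int] = (20, 300)
    utr_max: int = 4375
    intergenic_len: tuple[int, int] = (1000, 3000)
    gc: float = 0.36
    n_ests: int = 480
    read_len: tuple[int, int] = (300, 600)
    max_read_offset: int = 10
    error_rate: float = 0.0
    expression_concentration: float = 5.0
    novel_frac: float = 0.4
    go_prob: float = 0.6
    proteome_dbs: tuple[str, ...] = ("amel", "nvit", "tcas", "dmel")
    # (motif, repeats, host) with host in {"utr", "intergenic"}
    planted_ssrs: list = field(
        default_factory=lambda: [
            ("AT", 8, "utr"),
            ("ACG", 6, "utr"),
            ("AAAT", 6, "utr"),
            ("AT", 7, "intergenic"),
            ("AGC", 5, "intergenic"),
        ]
    )
    # (gene index, n columns, target minor allele frequency)
    planted_snps: list = field(
        default_factory=lambda: [(0, 2, 0.2), (1, 2, 0.25), (2, 1, 0.3)]
    )
    snp_reserved_depth: int = 12
    # (gene index, n premature stops)
    planted_pseudogenes: list = field(default_factory=lambda: [(3, 1), (4, 2), (5, 3)])
    # db -> list of gene indices absent from that proteome
    deleted_from_proteome: dict = field(default_factory=lambda: {"amel": [6, 7]})
    n_distal_fragments: int = 3
    fragment_len: int = 400

    def __post_init__(self):
        if self.n_genes < 12:
            raise ValueError("n_genes must be >= 12 to host the planted features")
        for lo, hi in (self.cds_codons, self.utr5_len, self.utr3_len,
                       self.intergenic_len, self.read_len):
            if not (0 < lo <= hi):
                raise ValueError("distribution bounds must satisfy 0 < lo <= hi")
        if self.utr3_len[1] > self.utr_max or self.utr5_len[1] > self.utr_max:
            raise ValueError("UTR lengths must stay within utr_max")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be a fraction in (0,1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for motif, reps, host in self.planted_ssrs:
            p = len(motif)
            if p not in ssr_mod.DEFAULT_THRESHOLDS:
                raise ValueError(f"planted SSR motif length {p} outside 2-6")
            if reps < ssr_mod.DEFAULT_THRESHOLDS[p]:
                raise ValueError(f"planted SSR {motif}x{reps} below threshold")
            if host not in ("utr", "intergenic"):
                raise ValueError(f"unknown SSR host {host!r}")
        for _, _, maf in self.planted_snps:
            if not 0.1 <= maf <= 0.5:
                raise ValueError("planted maf must lie in [0.1, 0.5]")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        # tuples -> lists for clean YAML
        data = json.loads(json.dumps(data))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cds_codons", "utr5_len", "utr3_len", "intergenic_len",
                    "read_len", "proteome_dbs"):
            if key in data:
                data[key] = tuple(data[key])
        if "planted_ssrs" in data:
            data["planted_ssrs"] = [tuple(x) for x in data["planted_ssrs"]]
        if "planted_snps" in data:
            data["planted_snps"] = [tuple(x) for x in data["planted_snps"]]
        if "planted_pseudogenes" in data:
            data["planted_pseudogenes"] = [tuple(x) for x in data["planted_pseudogenes"]]
        return cls(**data)


@dataclass
class GroundTruth:
    """Registry of everything the simulator planted or can book-keep exactly."""

    est_provenance: dict = field(default_factory=dict)  # est -> (gene, offset, len)
    contigs: dict = field(default_factory=dict)  # contig_id -> gene_id
    singletons: dict = field(default_factory=dict)  # est_id -> gene_id
    unique_of_gene: dict = field(default_factory=dict)  # gene_id -> unique seq id
    contig_lengths: dict = field(default_factory=dict)
    ssr_registry: list = field(default_factory=list)
    snp_registry: list = field(default_factory=list)
    pseudogenes: list = field(default_factory=list)
    deleted: dict = field(default_factory=dict)  # db -> [gene ids]
    expected_candidates: dict = field(default_factory=dict)  # db -> [unique ids]
    expected_tally: dict = field(default_factory=dict)  # category -> count
    expected_no_hits: int = 0
    expected_class: dict = field(default_factory=dict)  # qseqid -> class
    expected_go: dict = field(default_factory=dict)  # ns -> {slim: count}
    gene_taxon: dict = field(default_factory=dict)
    n_ests: int = 0

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tkey\tpayload\n")

            def row(kind, key, payload):
                fh.write(f"{kind}\t{key}\t{json.dumps(payload, sort_keys=True)}\n")

            for est, prov in self.est_provenance.items():
                row("est", est, list(prov))
            for cid, gene in self.contigs.items():
                row("contig", cid, gene)
            for sid, gene in self.singletons.items():
                row("singleton", sid, gene)
            for i, rec in enumerate(self.ssr_registry):
                row("ssr", str(i), rec)
            for i, rec in enumerate(self.snp_registry):
                row("snp", str(i), rec)
            for i, rec in enumerate(self.pseudogenes):
                row("pseudogene", str(i), rec)
            row("deleted", "all", self.deleted)
            row("candidates", "all", self.expected_candidates)
            row("tally", "all", self.expected_tally)
            row("no_hits", "all", self.expected_no_hits)
            row("class", "all", self.expected_class)
            row("go", "all", self.expected_go)


# ---------------------------------------------------------------------------
# low-level sequence helpers

def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=p)) if n else ""


def _sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _rand_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


def _pick_base(rng: np.random.Generator, exclude: set[str]) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def plant_pseudogene(
    cds: str, n_stops: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """A genomic copy of `cds` with `n_stops` interior sense codons replaced
    by stop codons. Returns the copy and the 0-based codon indices of the
    planted stops. The first (start) and last (terminator) codons are never
    touched; asking for more stops than there are interior codons is an error.
    """
    if len(cds) % 3 or len(cds) < 9:
        raise ValueError("CDS must be a codon multiple of >= 3 codons")
    n_codons = len(cds) // 3
    interior = n_codons - 2
    if n_stops < 0 or n_stops > interior:
        raise ValueError(f"{n_stops} stops do not fit in {interior} interior codons")
    idx = sorted(rng.choice(np.arange(1, n_codons - 1), size=n_stops, replace=False))
    stops = sorted(STOP_CODONS)
    codons = [cds[i * 3 : i * 3 + 3] for i in range(n_codons)]
    for i in idx:
        codons[i] = stops[int(rng.integers(len(stops)))]
    return "".join(codons), [int(i) for i in idx]


def plant_snp_columns(
    rows: list[str],
    columns: Sequence[int],
    maf: float,
    rng: np.random.Generator,
    min_occurrence: int = 2,
    min_maf: float = 0.1,
) -> tuple[list[str], list[dict]]:
    """Edit alignment rows so each chosen column is biallelic at the minor
    count nearest the requested MAF. Columns must be gap-free and currently
    monomorphic. Returns the edited rows and per-column registry entries with
    the realised counts. An unachievable MAF (minor count below the occurrence
    floor, or below the MAF contract) is an error.
    """
    depth = len(rows)
    # nearest achievable count, capped so the planted allele stays the minor
    minor_n = min(round(maf * depth), (depth - 1) // 2)
    if minor_n < min_occurrence or minor_n / depth < min_maf:
        raise ValueError(
            f"maf {maf} unachievable at depth {depth} "
            f"(minor count {minor_n} violates the calling contract)"
        )
    rows = list(rows)
    registry = []
    for col in columns:
        chars = {r[col] for r in rows}
        if "-" in chars or len(chars) != 1:
            raise ValueError(f"column {col} is not a gap-free monomorphic column")
        major = rows[0][col]
        minor = _pick_base(rng, {major})
        which = rng.choice(depth, size=minor_n, replace=False)
        for r in which:
            rows[r] = rows[r][:col] + minor + rows[r][col + 1 :]
        realised = sum(1 for r in rows if r[col] == minor)
        registry.append(
            {"column": int(col), "major": major, "minor": minor,
             "minor_count": int(realised), "depth": depth}
        )
    return rows, registry


def _scrub_ssrs(
    seq: str,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
    frame_regions: Sequence[tuple[int, int]] = (),
    protected_codons: Sequence[int] = (),
    max_rounds: int = 60,
) -> str:
    """Break every chance microsatellite in `seq` that does not overlap a
    protected span, by substituting one base near the middle of the run.

    `frame_regions` are (start, end) coding spans read in-phase from start;
    substitutions there never create a stop codon, and positions inside
    `protected_codons` (absolute base positions) are avoided so planted
    premature stops survive.
    """
    s = list(seq)
    prot = list(protected)
    codon_block = set(protected_codons)

    def in_frame_region(pos):
        for a, b in frame_regions:
            if a <= pos < b:
                return a
        return None

    for _ in range(max_rounds):
        recs = ssr_mod.find_ssrs(SeqRecord(id="x", sequence="".join(s)))
        extra = [
            r for r in recs
            if not any(r.start < pe and ps < r.end for ps, pe in prot)
        ]
        if not extra:
            return "".join(s)
        for r in extra:
            # try positions spiralling out from the run's middle
            mid = (r.start + r.end) // 2
            order = sorted(range(r.start, r.end), key=lambda i: (abs(i - mid), i))
            done = False
            for pos in order:
                if pos in codon_block or any(ps <= pos < pe for ps, pe in prot):
                    continue
                fstart = in_frame_region(pos)
                cur = s[pos]
                for b in BASES:
                    if b == cur:
                        continue
                    if fstart is not None:
                        ci = (pos - fstart) // 3
                        cstart = fstart + ci * 3
                        codon = "".join(s[cstart : cstart + 3])
                        trial = list(codon)
                        trial[pos - cstart] = b
                        if "".join(trial) in STOP_CODONS or codon in STOP_CODONS:
                            continue
                    s[pos] = b
                    done = True
                    break
                if done:
                    break
            if not done:  # pragma: no cover - pathological
                raise RuntimeError("could not scrub a chance SSR")
    raise RuntimeError("SSR scrubbing did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# the generator

@dataclass
class _Gene:
    gene_id: str
    index: int
    chrom: str
    strand: str
    utr5: int
    cds_len: int
    utr3: int
    transcript: str = ""
    gstart: int = 0  # genomic start of the whole gene span

    @property
    def length(self) -> int:
        return self.utr5 + self.cds_len + self.utr3

    @property
    def cds(self) -> str:
        return self.transcript[self.utr5 : self.utr5 + self.cds_len]


def _loguniform_evalue(rng, lo=1e-50, hi=1e-6) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def simulate(config: SimConfig, outdir) -> tuple[GroundTruth, dict[str, Path]]:
    """Generate the full synthetic dataset under `outdir`.

    Writes genome+GFF, transcripts, ESTs, unique sequences, cluster table,
    per-contig alignments, oracle hit tables (nr-style, one per reference
    proteome, genome, pseudogene screen), GO annotation and slim-map TSVs,
    the taxon map, a ground-truth registry TSV, and a ready-to-run pipeline
    config. Returns the in-memory :class:`GroundTruth` and a name->path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    gt = GroundTruth()
    thresholds = ssr_mod.DEFAULT_THRESHOLDS

    # ----- assign planted roles to genes
    snp_hosts = {g: (ncols, maf) for g, ncols, maf in config.planted_snps}
    pseudo_specs = list(config.planted_pseudogenes)
    utr_ssrs = [(m, k) for m, k, host in config.planted_ssrs if host == "utr"]
    intergenic_ssrs = [(m, k) for m, k, host in config.planted_ssrs if host == "intergenic"]
    reserved_for = set(snp_hosts)
    # utr-SSR hosts: first genes not already carrying a planted role
    taken = set(snp_hosts) | {g for g, _ in pseudo_specs}
    for db_genes in config.deleted_from_proteome.values():
        taken |= set(db_genes)
    ssr_host_ids: list[int] = []
    g = 0
    while len(ssr_host_ids) < len(utr_ssrs):
        if g not in taken:
            ssr_host_ids.append(g)
            taken.add(g)
        g += 1
        if g >= config.n_genes:
            raise ValueError("not enough genes to host planted SSRs")
    ssr_host_of = dict(zip(ssr_host_ids, utr_ssrs))

    # ----- build genes and transcripts
    genes: list[_Gene] = []
    for i in range(config.n_genes):
        utr5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        utr3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        if i in ssr_host_of:
            motif, reps = ssr_host_of[i]
            utr3 = max(utr3, len(motif) * reps + 22)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            _Gene(
                gene_id=f"g{i:04d}", index=i,
                chrom=f"chr{i % config.n_chromosomes + 1}",
                strand=strand, utr5=utr5, cds_len=codons * 3, utr3=utr3,
            )
        )

    for gene in genes:
        utr5_seq = _rand_seq(rng, gene.utr5, config.gc)
        n_codons = gene.cds_len // 3
        cds = "ATG" + "".join(
            _sense_codon(rng, config.gc) for _ in range(n_codons - 2)
        ) + sorted(STOP_CODONS)[int(rng.integers(3))]
        utr3_seq = _rand_seq(rng, gene.utr3, config.gc)
        protected: list[tuple[int, int]] = []
        if gene.index in ssr_host_of:
            motif, reps = ssr_host_of[gene.index]
            p, span = len(motif), len(motif) * reps
            at = 10  # offset within the 3' UTR
            u3 = list(utr3_seq)
            u3[at : at + span] = motif * reps
            u3[at - 1] = _pick_base(rng, {motif[-1]})  # guard: no left extension
            u3[at + span] = _pick_base(rng, {motif[0]})  # guard: no right extension
            utr3_seq = "".join(u3)
            t_start = gene.utr5 + gene.cds_len + at
            # protect the guard bases too, so scrubbing cannot re-enable
            # extension of the planted run
            protected.append((t_start - 1, t_start + span + 1))
            gt.ssr_registry.append(
                {"seq_id": f"t_{gene.gene_id}", "motif": motif, "repeats": reps,
                 "start": t_start, "end": t_start + span, "host": "utr"}
            )
        transcript = utr5_seq + cds + utr3_seq
        cds_span = (gene.utr5, gene.utr5 + gene.cds_len)
        # never mutate the start or terminator codon while scrubbing
        transcript = _scrub_ssrs(
            transcript, rng,
            protected=protected + [(cds_span[0], cds_span[0] + 3),
                                   (cds_span[1] - 3, cds_span[1])],
            frame_regions=[cds_span],
        )
        gene.transcript = transcript

    # ----- pseudogene copies (from the scrubbed CDS)
    pseudo_segments: list[tuple[str, list[int], str]] = []  # seq, stop codons, gene_id
    for gidx, n_stops in pseudo_specs:
        gene = genes[gidx]
        copy, stop_idx = plant_pseudogene(gene.cds, n_stops, rng)
        pseudo_segments.append((copy, stop_idx, gene.gene_id))

    # ----- assemble chromosomes
    chrom_parts: dict[str, list[str]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    chrom_len: dict[str, int] = {k: 0 for k in chrom_parts}
    features: list[GenomeFeature] = []
    for gene in genes:
        spacer = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        chrom_parts[gene.chrom].append(_rand_seq(rng, spacer, config.gc))
        chrom_len[gene.chrom] += spacer
        gene.gstart = chrom_len[gene.chrom]
        segment = gene.transcript if gene.strand == "+" else _revcomp(gene.transcript)
        chrom_parts[gene.chrom].append(segment)
        chrom_len[gene.chrom] += gene.length
        gend = gene.gstart + gene.length
        if gene.strand == "+":
            cstart = gene.gstart + gene.utr5
            cend = cstart + gene.cds_len
        else:
            cend = gend - gene.utr5
            cstart = cend - gene.cds_len
        features.append(GenomeFeature(gene.chrom, gene.gstart, gend, gene.strand,
                                      "gene", gene.gene_id))
        features.append(GenomeFeature(gene.chrom, cstart, cend, gene.strand,
                                      "CDS", f"{gene.gene_id}.cds"))

    # desert chromosome: planted intergenic SSRs, distal-fragment zone,
    # pseudogene copies; carries no annotation at all
    d_parts: list[str] = [_rand_seq(rng, 800, config.gc)]
    d_len = 800
    d_protected: list[tuple[int, int]] = []
    d_frames: list[tuple[int, int]] = []
    d_stop_positions: list[int] = []
    for motif, reps in intergenic_ssrs:
        p, span = len(motif), len(motif) * reps
        pad = _rand_seq(rng, 120, config.gc)
        left = pad[:-1] + _pick_base(rng, {motif[-1]})
        start = d_len + len(left)
        d_parts.append(left + motif * reps + _pick_base(rng, {motif[0]}))
        d_len = start + span + 1
        d_protected.append((start - 1, start + span + 1))  # guards included
        gt.ssr_registry.append(
            {"seq_id": "chrD", "motif": motif, "repeats": reps,
             "start": start, "end": start + span, "host": "intergenic"}
        )
    frag_zone_start = d_len + 400
    d_parts.append(_rand_seq(rng, 400, config.gc))
    frag_zone_len = max(3000, config.fragment_len * (config.n_distal_fragments + 1))
    d_parts.append(_rand_seq(rng, frag_zone_len, config.gc))
    d_len = frag_zone_start + frag_zone_len
    pseudo_registry_stage: list[dict] = []
    for copy, stop_idx, gene_id in pseudo_segments:
        d_parts.append(_rand_seq(rng, 300, config.gc))
        d_len += 300
        start = d_len
        d_parts.append(copy)
        d_len += len(copy)
        d_frames.append((start, start + len(copy)))
        for ci in stop_idx:
            d_stop_positions.extend(range(start + ci * 3, start + ci * 3 + 3))
        # protect the terminator codon of the copy as well
        d_stop_positions.extend(range(start + len(copy) - 3, start + len(copy)))
        pseudo_registry_stage.append(
            {"gene": gene_id, "seqid": "chrD", "start": start,
             "end": start + len(copy), "frame": 1, "n_stops": len(stop_idx),
             "stop_codons": stop_idx}
        )
    d_parts.append(_rand_seq(rng, 500, config.gc))
    chrD = _scrub_ssrs(
        "".join(d_parts), rng, protected=d_protected,
        frame_regions=d_frames, protected_codons=d_stop_positions,
    )
    for rec in pseudo_registry_stage:
        gene = genes[int(rec["gene"][1:])]
        rec["protein_id"] = f"{rec['gene']}_prot"
        rec["protein"] = _translate(gene.cds)[:-1]
        gt.pseudogenes.append(rec)

    chromosomes = [
        SeqRecord(id=name, sequence="".join(parts))
        for name, parts in chrom_parts.items()
    ] + [SeqRecord(id="chrD", sequence=chrD)]

    # ----- gene-level annotations: taxon, novelty, GO, proteome membership
    species = list(SPECIES_WEIGHTS)
    weights = np.array(list(SPECIES_WEIGHTS.values()))
    weights = weights / weights.sum()
    go_ids = sorted(GO_VOCAB)
    gene_novel: dict[str, bool] = {}
    gene_go: dict[str, list[tuple[str, str]]] = {}
    evid = list(EVIDENCE_WEIGHTS)
    evid_w = np.array(list(EVIDENCE_WEIGHTS.values()))
    evid_w = evid_w / evid_w.sum()
    for gene in genes:
        gt.gene_taxon[gene.gene_id] = species[int(rng.choice(len(species), p=weights))]
        gene_novel[gene.gene_id] = bool(rng.random() < config.novel_frac)
        if rng.random() < config.go_prob:
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(go_ids), size=k, replace=False)
            gene_go[gene.gene_id] = [
                (go_ids[int(c)], evid[int(rng.choice(len(evid), p=evid_w))])
                for c in sorted(chosen)
            ]
    deleted_ids = {
        db: [genes[i].gene_id for i in idxs]
        for db, idxs in config.deleted_from_proteome.items()
    }
    gt.deleted = deleted_ids

    # ----- EST sampling
    counts = np.zeros(config.n_genes, dtype=int)
    for gidx in sorted(reserved_for):
        counts[gidx] = config.snp_reserved_depth
    remaining = config.n_ests - int(counts.sum())
    if remaining < 0:
        raise ValueError("n_ests too small for the reserved SNP-host depth")
    w = rng.dirichlet([config.expression_concentration] * config.n_genes)
    counts += rng.multinomial(remaining, w)
    gt.n_ests = int(counts.sum())

    est_records: list[SeqRecord] = []
    reads_of_gene: dict[str, list[tuple[str, int, str]]] = {}  # (est, offset, seq)
    est_no = 0
    for gene, n_reads in zip(genes, counts):
        if n_reads == 0:
            continue
        lst = []
        for _ in range(int(n_reads)):
            est_no += 1
            est_id = f"est{est_no:05d}"
            off = int(rng.integers(0, config.max_read_offset + 1))
            off = min(off, gene.length - 30)
            rlen = int(rng.integers(config.read_len[0], config.read_len[1] + 1))
            rlen = min(rlen, gene.length - off)
            read = list(gene.transcript[off : off + rlen])
            if config.error_rate > 0:
                errs = np.flatnonzero(rng.random(rlen) < config.error_rate)
                for e in errs:
                    read[e] = _pick_base(rng, {read[e]})
            lst.append((est_id, off, "".join(read)))
            gt.est_provenance[est_id] = (gene.gene_id, off, rlen)
        reads_of_gene[gene.gene_id] = lst

    # ----- clustering, SNP planting, alignments, unique sequences
    contig_members: dict[str, list[str]] = {}
    singletons: list[str] = []
    msa_blocks: list[MsaBlock] = []
    unique_records: list[SeqRecord] = []
    contig_no = 0
    for gene in genes:
        lst = reads_of_gene.get(gene.gene_id)
        if not lst:
            continue
        if len(lst) == 1:
            est_id, off, read = lst[0]
            singletons.append(est_id)
            gt.singletons[est_id] = gene.gene_id
            gt.unique_of_gene[gene.gene_id] = est_id
            unique_records.append(SeqRecord(id=est_id, sequence=read))
            est_records.append(SeqRecord(id=est_id, sequence=read))
            continue
        contig_no += 1
        cid = f"CL{contig_no:04d}"
        min_off = min(off for _, off, _ in lst)
        max_end = max(off + len(r) for _, off, r in lst)
        width = max_end - min_off
        padded = [
            "-" * (off - min_off) + read + "-" * (max_end - off - len(read))
            for _, off, read in lst
        ]
        if gene.index in snp_hosts:
            n_cols, maf = snp_hosts[gene.index]
            lo = config.max_read_offset + 5 - min_off
            hi = min(150, min(off + len(r) for _, off, r in lst) - 5) - min_off
            cols = sorted(
                int(c) for c in rng.choice(np.arange(lo, hi), size=n_cols, replace=False)
            )
            padded, planted = plant_snp_columns(padded, cols, maf, rng)
            for entry in planted:
                entry.update({"contig_id": cid, "gene": gene.gene_id,
                              "transcript_pos": entry["column"] + min_off})
                gt.snp_registry.append(entry)
        rows = []
        for (est_id, off, _read), aligned in zip(lst, padded):
            read_back = aligned[off - min_off : off - min_off + len(_read)]
            rows.append((est_id, aligned))
            est_records.append(SeqRecord(id=est_id, sequence=read_back))
        contig_members[cid] = [est_id for est_id, _, _ in lst]
        gt.contigs[cid] = gene.gene_id
        gt.unique_of_gene[gene.gene_id] = cid
        block = MsaBlock(contig_id=cid, rows=rows)
        msa_blocks.append(block)
        consensus = _consensus(block)
        gt.contig_lengths[cid] = len(consensus)
        unique_records.append(SeqRecord(id=cid, sequence=consensus))

    clusters = ClusterTable(contig_members=contig_members, singletons=singletons)

    # ----- oracle hit tables
    hits_nr: list[HitRecord] = []
    taxmap: dict[str, str] = {}
    tally: dict[str, int] = {lab: 0 for lab, _ in DEFAULT_CATEGORIES}
    no_hits = 0
    for gene in genes:
        uid = gt.unique_of_gene.get(gene.gene_id)
        if uid is None:
            continue
        if gene_novel[gene.gene_id]:
            no_hits += 1
            continue
        taxon = gt.gene_taxon[gene.gene_id]
        subj = f"nr|{gene.gene_id}"
        taxmap[subj] = taxon
        qlen = len(_uid_seq(unique_records, uid))
        hits_nr.append(_mk_hit(rng, uid, subj, qlen))
        for lab, taxa in DEFAULT_CATEGORIES:
            if taxa == "*" or taxon in taxa:
                tally[lab] += 1
                break
    gt.expected_tally = tally
    gt.expected_no_hits = no_hits

    hits_db: dict[str, list[HitRecord]] = {db: [] for db in config.proteome_dbs}
    for db in config.proteome_dbs:
        gone = set(deleted_ids.get(db, []))
        for gene in genes:
            uid = gt.unique_of_gene.get(gene.gene_id)
            if uid is None or gene.gene_id in gone:
                continue
            subj = f"{db}|{gene.gene_id}"
            taxmap.setdefault(subj, db)
            qlen = len(_uid_seq(unique_records, uid))
            hits_db[db].append(_mk_hit(rng, uid, subj, qlen))
    gt.expected_candidates = {
        db: sorted(
            gt.unique_of_gene[gid] for gid in gone_ids
            if gid in gt.unique_of_gene
            and sum(gid in deleted_ids.get(d, []) for d in config.proteome_dbs) == 1
        )
        for db, gone_ids in deleted_ids.items()
    }

    # genome hits + expected positional classes
    hits_genome: list[HitRecord] = []
    for gene in genes:
        uid = gt.unique_of_gene.get(gene.gene_id)
        if uid is None:
            continue
        if uid in gt.contigs:
            lst = reads_of_gene[gene.gene_id]
            lo = min(off for _, off, _ in lst)
            hi = max(off + len(r) for _, off, r in lst)
        else:
            _gene_id, lo, rlen = gt.est_provenance[uid]
            hi = lo + rlen
        if gene.strand == "+":
            gs, ge = gene.gstart + lo, gene.gstart + hi
            sstart, send = gs + 1, ge
        else:
            gs, ge = gene.gstart + gene.length - hi, gene.gstart + gene.length - lo
            sstart, send = ge, gs + 1  # minus orientation
        qlen = hi - lo
        hits_genome.append(
            HitRecord(
                qseqid=uid, sseqid=gene.chrom, pident=99.0, length=qlen,
                mismatch=0, gapopen=0, qstart=1, qend=qlen,
                sstart=sstart, send=send,
                evalue=_loguniform_evalue(rng, 1e-50, 1e-9), bitscore=500.0,
            )
        )
        cs, ce = gene.utr5, gene.utr5 + gene.cds_len
        if lo >= cs and hi <= ce:
            cls = "inside"
        elif max(cs - hi, lo - ce, 0) == 0:
            cls = "spanning"
        elif max(cs - hi, lo - ce) <= config.utr_max:
            cls = "utr_range"
        else:  # pragma: no cover - impossible with bounded UTRs
            cls = "distal"
        gt.expected_class[uid] = cls
    for i in range(config.n_distal_fragments):
        fid = f"frag{i + 1:03d}"
        fstart = frag_zone_start + i * (config.fragment_len + 50)
        fend = fstart + config.fragment_len
        hits_genome.append(
            HitRecord(
                qseqid=fid, sseqid="chrD", pident=99.0, length=config.fragment_len,
                mismatch=0, gapopen=0, qstart=1, qend=config.fragment_len,
                sstart=fstart + 1, send=fend,
                evalue=_loguniform_evalue(rng, 1e-50, 1e-9), bitscore=400.0,
            )
        )
        gt.expected_class[fid] = "distal"

    # pseudogene screen hit table (13-column; frame in column 13)
    hits_pseudo: list[HitRecord] = []
    for rec in gt.pseudogenes:
        n_codons = (rec["end"] - rec["start"]) // 3
        hits_pseudo.append(
            HitRecord(
                qseqid=rec["protein_id"], sseqid=rec["seqid"], pident=95.0,
                length=n_codons, mismatch=0, gapopen=0, qstart=1, qend=n_codons - 1,
                sstart=rec["start"] + 1, send=rec["end"],
                evalue=_loguniform_evalue(rng, 1e-60, 1e-21), bitscore=800.0,
                frame=rec["frame"],
            )
        )

    # ----- GO annotations for unique sequences
    go_rows: list[tuple[str, str, str, str]] = []
    expected_go: dict[str, dict[str, int]] = {}
    for gene in genes:
        uid = gt.unique_of_gene.get(gene.gene_id)
        if uid is None or gene.gene_id not in gene_go:
            continue
        curated_slims = set()
        for go_id, evidence in gene_go[gene.gene_id]:
            slim, ns = GO_VOCAB[go_id]
            go_rows.append((uid, go_id, evidence, ns))
            if evidence != "IEA":
                curated_slims.add((ns, slim))
        for ns, slim in curated_slims:
            expected_go.setdefault(ns, {}).setdefault(slim, 0)
            expected_go[ns][slim] += 1
    gt.expected_go = expected_go

    # ----- write everything
    paths: dict[str, Path] = {}

    def P(name):
        paths[name] = outdir / name
        return paths[name]

    write_fasta(chromosomes, P("genome.fasta"))
    write_gff(features, P("annotation.gff3"))
    write_fasta(
        [SeqRecord(id=f"t_{g.gene_id}", sequence=g.transcript) for g in genes],
        P("transcripts.fasta"),
    )
    write_fasta(est_records, P("ests.fasta"))
    write_fasta(unique_records, P("unique.fasta"))
    write_clusters(clusters, P("clusters.txt"))
    write_msa(msa_blocks, P("alignments.afa"))
    write_hits(hits_nr, P("hits_nr.tsv"))
    for db in config.proteome_dbs:
        write_hits(hits_db[db], P(f"hits_{db}.tsv"))
    write_hits(hits_genome, P("hits_genome.tsv"))
    write_hits(hits_pseudo, P("hits_pseudo.tsv"))
    with open(P("taxmap.tsv"), "w") as fh:
        fh.write("sseqid\ttaxon\n")
        for subj in sorted(taxmap):
            fh.write(f"{subj}\t{taxmap[subj]}\n")
    with open(P("go_annotations.tsv"), "w") as fh:
        fh.write("seq_id\tgo_id\tevidence_code\tnamespace\n")
        for row in sorted(go_rows):
            fh.write("\t".join(row) + "\n")
    with open(P("go_slim_map.tsv"), "w") as fh:
        fh.write("go_id\tslim_term\tnamespace\n")
        for go_id in sorted(GO_VOCAB):
            slim, ns = GO_VOCAB[go_id]
            fh.write(f"{go_id}\t{slim}\t{ns}\n")
    gt.write_tsv(P("ground_truth.tsv"))
    config.to_yaml(P("sim_config.yaml"))

    run_cfg = {
        "unique_fasta": "unique.fasta",
        "clusters": "clusters.txt",
        "alignments": "alignments.afa",
        "genome_fasta": "genome.fasta",
        "gff": "annotation.gff3",
        "hits_nr": "hits_nr.tsv",
        "hits_genome": "hits_genome.tsv",
        "hits_pseudo": "hits_pseudo.tsv",
        "proteome_hits": {db: f"hits_{db}.tsv" for db in config.proteome_dbs},
        "candidate_missing_db": next(iter(config.deleted_from_proteome), None),
        "taxmap": "taxmap.tsv",
        "go_annotations": "go_annotations.tsv",
        "go_slim_map": "go_slim_map.tsv",
        "categories": [
            {"label": lab, "taxa": (taxa if taxa == "*" else list(taxa))}
            for lab, taxa in DEFAULT_CATEGORIES
        ],
        "evalue_protein": 1e-5,
        "evalue_genome": 1e-8,
        "utr_max": config.utr_max,
        "orf_min_len": 100,
        "alpha": 0.05,
        "correction": "bonferroni",
    }
    with open(P("run_config.yaml"), "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)

    return gt, paths


def _consensus(block: MsaBlock) -> str:
    """Per-column majority base (ties alphabetical), gap-only columns skipped."""
    cols = []
    for i in range(block.width):
        counts: dict[str, int] = {}
        for _id, row in block.rows:
            c = row[i]
            if c in "ACGTN" and c != "N":
                counts[c] = counts.get(c, 0) + 1
        if counts:
            cols.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(cols)


def _uid_seq(records: list[SeqRecord], uid: str) -> str:
    for r in records:
        if r.id == uid:
            return r.sequence
    raise KeyError(uid)


def _mk_hit(rng, qseqid, sseqid, qlen) -> HitRecord:
    alen = max(30, int(qlen * 0.8))
    return HitRecord(
        qseqid=qseqid, sseqid=sseqid, pident=float(np.round(rng.uniform(80, 99), 2)),
        length=alen, mismatch=int(rng.integers(0, 5)), gapopen=0,
        qstart=1, qend=min(qlen, alen), sstart=1, send=alen,
        evalue=_loguniform_evalue(rng), bitscore=float(np.round(rng.uniform(100, 900), 1)),
    )


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())
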