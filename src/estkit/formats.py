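"""Readers and writers for every external representation the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from the
1-based inclusive conventions of FASTA-adjacent tabular formats (hit tables,
GFF3) happens only here, at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"
GO_ID_RE = re.compile(r"^GO:\d{7}$")
NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


class FormatError(ValueError):
    """Malformed input; carries the file path and 1-based line number."""

    def __init__(self, message: str, path=None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (EST read, unique sequence, genome segment)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id must be a non-empty token: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of 12/13-column tabular similarity-search output.

    Query and subject coordinates are kept in their printed 1-based inclusive
    form; ``sstart > send`` means the match lies on the subject minus strand.
    ``frame`` (column 13, optional) is the translation frame in {-3..-1, 1..3}.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    frame: Optional[int] = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.qseqid}")
        if self.qstart > self.qend:
            raise ValueError(f"qstart > qend for {self.qseqid}")
        if self.length <= 0:
            raise ValueError(f"non-positive alignment length for {self.qseqid}")
        if self.frame is not None and self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"frame {self.frame} out of range for {self.qseqid}")

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Strand-normalised subject interval, 0-based half-open."""
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi

    @property
    def subject_minus(self) -> bool:
        return self.sstart > self.send


@dataclass(frozen=True)
class GenomeFeature:
    """An annotated stranded interval (gene or CDS) on a genomic sequence."""

    seqid: str
    start: int  # 0-based half-open
    end: int
    strand: str
    ftype: str
    feature_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start},{self.end}) for {self.feature_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.feature_id}")


@dataclass
class ClusterTable:
    """Cluster membership: contigs (>=2 member ESTs) and singleton ESTs."""

    contig_members: dict[str, list[str]]
    singletons: list[str]

    def __post_init__(self):
        seen: set[str] = set()
        for cid, members in self.contig_members.items():
            if len(members) < 2:
                raise ValueError(f"contig {cid} has fewer than 2 members")
            for m in members:
                if m in seen:
                    raise ValueError(f"EST id {m} appears twice")
                seen.add(m)
        for s in self.singletons:
            if s in seen:
                raise ValueError(f"EST id {s} appears twice")
            seen.add(s)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_members)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def n_ests(self) -> int:
        return self.n_singletons + sum(len(v) for v in self.contig_members.values())


@dataclass
class MsaBlock:
    """A gap-padded multiple alignment of the member ESTs of one contig."""

    contig_id: str
    rows: list[tuple[str, str]]  # (est_id, aligned sequence over ACGTN-)

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError(f"MSA block {self.contig_id} has fewer than 2 rows")
        widths = {len(r[1]) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged rows in MSA block {self.contig_id}")
        allowed = set("ACGTN-")
        for est_id, aligned in self.rows:
            bad = set(aligned) - allowed
            if bad:
                raise ValueError(
                    f"illegal characters {sorted(bad)} in MSA row {est_id}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def column(self, i: int) -> list[str]:
        return [aligned[i] for _, aligned in self.rows]


@dataclass(frozen=True)
class GoAnnotation:
    """A (sequence, GO term) assignment with its evidence code and namespace."""

    seq_id: str
    go_id: str
    evidence_code: str
    namespace: str

    def __post_init__(self):
        if not GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO id {self.go_id!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SeqRecord]:
    """Parse a multi-record FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased; ids must be unique; characters outside the IUPAC
    nucleotide alphabet raise :class:`FormatError` naming the offending line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: Optional[tuple[str, str, int]] = None  # id, description, line no
    chunks: list[str] = []

    def flush(lineno):
        nonlocal header, chunks
        if header is None:
            return
        sid, desc, hline = header
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {sid!r} has no sequence", path, hline)
        try:
            records.append(SeqRecord(id=sid, sequence=seq, description=desc))
        except ValueError as exc:
            raise FormatError(str(exc), path, hline) from exc
        header, chunks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                head = line[1:].strip()
                if not head:
                    raise FormatError("empty FASTA header", path, lineno)
                parts = head.split(None, 1)
                sid = parts[0]
                desc = parts[1] if len(parts) == 2 else ""
                if sid in seen:
                    raise FormatError(f"duplicate sequence id {sid!r}", path, lineno)
                seen.add(sid)
                header = (sid, desc, lineno)
            else:
                if header is None:
                    raise FormatError("sequence data before first header", path, lineno)
                frag = line.strip().upper()
                bad = set(frag) - IUPAC_NT
                if bad:
                    raise FormatError(
                        f"illegal sequence characters {sorted(bad)}", path, lineno
                    )
                chunks.append(frag)
        flush(lineno)
    if not records:
        raise FormatError("no FASTA records found", path)
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular hit files (12 or 13 columns)

def read_hits(path) -> list[HitRecord]:
    """Parse a tab-separated 12/13-column hit table (13th column = frame)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(
                    f"expected 12 or 13 columns, found {len(cols)}", path, lineno
                )
            try:
                hit = HitRecord(
                    qseqid=cols[0],
                    sseqid=cols[1],
                    pident=float(cols[2]),
                    length=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    frame=int(cols[12]) if len(cols) == 13 else None,
                )
            except ValueError as exc:
                raise FormatError(f"bad hit row: {exc}", path, lineno) from exc
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.qseqid, h.sseqid, f"{h.pident:.2f}", str(h.length),
                str(h.mismatch), str(h.gapopen), str(h.qstart), str(h.qend),
                str(h.sstart), str(h.send), f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]
            if h.frame is not None:
                cols.append(str(h.frame))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 subset (columns 1-9, ID= attribute)

def read_gff(path) -> list[GenomeFeature]:
    """Parse GFF3-style gene/CDS lines; printed 1-based inclusive coordinates
    become internal 0-based half-open ((1,10) -> [0,10))."""
    feats: list[GenomeFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"expected 9 columns, found {len(cols)}", path, lineno)
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"non-integer coordinates: {exc}", path, lineno)
            if end1 < start1:
                raise FormatError(f"end {end1} < start {start1}", path, lineno)
            if strand not in ("+", "-"):
                raise FormatError(f"unknown strand {strand!r}", path, lineno)
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            fid = m.group(1) if m else f"{ftype}:{seqid}:{start1}"
            try:
                feats.append(
                    GenomeFeature(
                        seqid=seqid, start=start1 - 1, end=end1,
                        strand=strand, ftype=ftype, feature_id=fid,
                    )
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
    return feats


def write_gff(features: Iterable[GenomeFeature], path, source: str = "estkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seqid, source, f.ftype, str(f.start + 1), str(f.end),
                        ".", f.strand, ".", f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Cluster table
#
# Dialect: one line per cluster, "contig_id: est1 est2 ..."; a bare id on a
# line of its own is a singleton EST.

def read_clusters(path) -> ClusterTable:
    contigs: dict[str, list[str]] = {}
    singletons: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                cid, rest = line.split(":", 1)
                cid = cid.strip()
                members = rest.split()
                if len(members) < 2:
                    raise FormatError(
                        f"contig {cid!r} lists {len(members)} member(s); "
                        "contigs need >= 2", path, lineno,
                    )
                if cid in contigs:
                    raise FormatError(f"duplicate contig id {cid!r}", path, lineno)
                contigs[cid] = members
            else:
                singletons.append(line.split()[0])
    try:
        return ClusterTable(contig_members=contigs, singletons=singletons)
    except ValueError as exc:
        raise FormatError(str(exc), path) from exc


def write_clusters(table: ClusterTable, path) -> None:
    with open(path, "w") as fh:
        for cid, members in table.contig_members.items():
            fh.write(f"{cid}: " + " ".join(members) + "\n")
        for s in table.singletons:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# Per-contig multiple alignments (aligned FASTA)
#
# Either one file per contig, or one file with blocks introduced by a
# "# contig: <id>" comment line. Both are accepted.

def read_msa(path, contig_id: Optional[str] = None) -> list[MsaBlock]:
    blocks: list[MsaBlock] = []
    cur_id: Optional[str] = contig_id
    cur_rows: list[tuple[str, str]] = []
    row_id: Optional[str] = None
    row_chunks: list[str] = []
    start_line = 1

    def flush_row():
        nonlocal row_id, row_chunks
        if row_id is not None:
            cur_rows.append((row_id, "".join(row_chunks).upper()))
        row_id, row_chunks = None, []

    def flush_block(lineno):
        nonlocal cur_rows
        flush_row()
        if cur_rows:
            bid = cur_id if cur_id is not None else Path(path).stem
            try:
                blocks.append(MsaBlock(contig_id=bid, rows=cur_rows))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
        cur_rows = []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = re.match(r"^#\s*contig:\s*(\S+)", line)
            if m:
                flush_block(start_line)
                cur_id = m.group(1)
                start_line = lineno
                continue
            if line.startswith("#"):
                continue
            if line.startswith(">"):
                flush_row()
                row_id = line[1:].split()[0]
            else:
                if row_id is None:
                    raise FormatError("alignment data before first header", path, lineno)
                row_chunks.append(line.strip())
        flush_block(lineno)
    if not blocks:
        raise FormatError("no alignment blocks found", path)
    return blocks


def write_msa(blocks: Iterable[MsaBlock], path) -> None:
    with open(path, "w") as fh:
        for block in blocks:
            fh.write(f"# contig: {block.contig_id}\n")
            for est_id, aligned in block.rows:
                fh.write(f">{est_id}\n{aligned}\n")


# ---------------------------------------------------------------------------
# GO annotation and slim-map TSVs

def read_go(path) -> list[GoAnnotation]:
    """Parse a GO annotation TSV: seq_id, go_id, evidence_code, namespace.

    A header row beginning with 'seq_id' is tolerated. Evidence filtering is
    deliberately NOT applied here (see go_profile.filter_annotations)."""
    annots: list[GoAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "seq_id":
                continue
            if len(cols) != 4:
                raise FormatError(f"expected 4 columns, found {len(cols)}", path, lineno)
            try:
                annots.append(GoAnnotation(*cols))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
    return annots


def read_slim_map(path) -> dict[str, tuple[str, str]]:
    """Parse a GO->GO-slim mapping TSV: go_id, slim_term, namespace."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "go_id":
                continue
            if len(cols) != 3:
                raise FormatError(f"expected 3 columns, found {len(cols)}", path, lineno)
            go_id, slim, ns = cols
            if not GO_ID_RE.match(go_id):
                raise FormatError(f"malformed GO id {go_id!r}", path, lineno)
            if ns not in NAMESPACES:
                raise FormatError(f"unknown namespace {ns!r}", path, lineno)
            mapping[go_id] = (slim, ns)
    return mapping


def read_taxmap(path) -> dict[str, str]:
    """Parse a subject-to-taxon TSV: sseqid, taxon label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "sseqid":
                continue
            if len(cols) != 2:
                raise FormatError(f"expected 2 columns, found {len(cols)}", path, lineno)
            mapping[cols[0]] = cols[1]
    return mapping
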