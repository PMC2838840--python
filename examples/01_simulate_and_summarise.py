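"""Generate a synthetic EST library and summarise its assembly.

Builds a ground-truthed toy dataset (genome, transcripts, 5' reads, clusters)
and computes the assembly composition statistics and pooled GC content of the
unique-sequence set.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from estkit.formats import read_clusters, read_fasta
from estkit.library_stats import assembly_summary, gc_content
from estkit.synthetic_data import SimConfig, simulate

with TemporaryDirectory() as tmp:
    gt, _ = simulate(SimConfig(seed=1), tmp)
    d = Path(tmp)
    clusters = read_clusters(d / "clusters.txt")
    unique = read_fasta(d / "unique.fasta")

    s = assembly_summary(clusters, unique)
    print(f"ESTs sequenced:        {s.n_ests}")
    print(f"contigs / singletons:  {s.n_contigs} / {s.n_singletons}")
    print(f"unique sequences:      {s.n_unique}")
    print(f"mean ESTs per contig:  {s.mean_per_contig:.2f} (max {s.max_per_contig})")
    print(f"contig length mean/max: {s.contig_len_mean:.0f} / {s.contig_len_max}")
    print(f"GC content:            {gc_content(unique) * 100:.1f}%")

# The unique sequences (contig consensi + singleton reads) are the unit all
# downstream stages work on; GC is pooled over all unambiguous bases, not a
# mean of per-sequence fractions.
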