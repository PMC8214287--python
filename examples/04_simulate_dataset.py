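"""Build a complete toy SV-calling dataset: genome, variants, truth, reads.

Everything is seeded and reproducible; the truth VCF applied back to the
original genome reconstructs the altered genome byte for byte.
"""

from collections import Counter

from svpipe import apply_truth, inject_svs, simulate_reads
from svpipe.simulate import ReadSimParams, SVSpec, coverage_of, toy_genome, write_fasta, write_fastq
from svpipe.svmerge import write_sv_vcf

genome = toy_genome({"contig1": 100_000, "contig2": 100_000}, gc=0.42, seed=11)
spec = SVSpec(counts={"DEL": 3, "INS": 3, "INV": 2, "DUP": 2, "TRA": 1}, seed=11)
altered, truth = inject_svs(genome, spec)

write_fasta(genome, "reference.fasta")
write_sv_vcf(truth, "truth.vcf", contigs={c: len(s) for c, s in genome.items()})

params = ReadSimParams(coverage=10, mean_length=8000, sub_rate=0.04,
                       ins_rate=0.05, del_rate=0.04, seed=11)
reads = simulate_reads(altered, params)
write_fastq(reads, "reads.fastq")

print("injected:", dict(Counter(t.sv_type for t in truth)))
print(f"altered genome: {sum(map(len, altered.values()))} bp "
      f"(original {sum(map(len, genome.values()))} bp)")
print(f"reads: {len(reads)}, realized coverage {coverage_of(reads, altered):.1f}x")
print("round trip exact:", apply_truth(genome, truth) == altered)
print(
    "\nReads are drawn from the ALTERED genome (the donor), while truth "
    "breakpoints are reported on the original reference — the situation a "
    "real SV caller faces."
)
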