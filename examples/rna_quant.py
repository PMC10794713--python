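"""Encapsidated-RNA quantification from synthetic two-replicate alignments.

Simulates nanopore-style alignments (70% of reads from the CP coding
sequence, full 3' anchoring, 90% at MAPQ 60) over a small CDS universe,
then runs the full quantification: MAPQ-60 retention, 50 nt 3'-window
filter, per-CDS counts, TPM, replicate-adjusted TPM, normalized/smoothed
coverage and per-class base-pair percentages.
"""

from capsidmorph.rnaquant import quantify_replicates
from capsidmorph.synthetic import AlignmentSimSpec, gen_read_alignments

spec = AlignmentSimSpec(
    references=(("CP", 807, "CP"), ("p97", 2421, "p97"), ("rrsA", 1542, "rRNA"), ("hns", 414, "other")),
    composition=(0.70, 0.05, 0.15, 0.10),
    read_length_dist=(400.0, 80.0),
    three_prime_bias=1.0,
    n_reads=4000,
    mapq_high_fraction=0.9,
    seed=4,
)
refs = spec.reference_set()
result = quantify_replicates(gen_read_alignments(spec), refs)

print("per-CDS adjusted TPM (mean of two replicates, % of the per-million total):")
for ref_id, row in result.adjusted.sort_values("mean", ascending=False).iterrows():
    print(f"  {ref_id:<6} {row['mean'] / 1e4:6.1f} %")

print("\nbase-pair share per RNA class (MAPQ-retained alignments):")
for cls, pct in sorted(result.bp_percent.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:<6} {pct:6.1f} %")

cp = result.coverage_smooth["CP"]
print(f"\nsmoothed normalized CP coverage: {cp.mean():.1f} per base on average,")
print(f"3' end {cp[-40:].mean():.1f} vs 5' end {cp[:40].mean():.1f} -- the 3' excess")
print("reflects full 3' anchoring of the simulated reads.")
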