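"""Genomic-architecture covariates of a small constructed locus.

Shows the nearest reversely oriented neighbor and its gap distance, the
windowed strand-specific neighbor counts, exon/intron co-residence and the
local-alignment identity of an inverted pair.
"""

from alueditability import (
    GeneModel,
    RepeatElement,
    build_feature_table,
    neighbor_counts,
    nearest_reverse_neighbor,
    pair_gap_distance,
    pair_identity,
    select_genic_alus,
)

gene = GeneModel("g1", "chr1", "+", 0, 30_000,
                 ((0, 500), (12_000, 13_000), (29_500, 30_000)))
repeats = [
    RepeatElement("focal", "chr1", 5_000, 5_300, "+", "AluSx"),
    RepeatElement("partner", "chr1", 6_000, 6_290, "-", "AluSx"),
    RepeatElement("decoy", "chr1", 9_500, 9_800, "-", "AluJb"),
    RepeatElement("same1", "chr1", 3_000, 3_300, "+", "AluY"),
    RepeatElement("far", "chr1", 26_000, 26_300, "-", "AluSg"),
]

focal = repeats[0]
nb, d = nearest_reverse_neighbor(focal, repeats)
print(f"nearest reverse neighbor of 'focal': {nb.id} at gap {d} bp")
print(f"gap focal..decoy = {pair_gap_distance(focal, repeats[2])} bp")
print(f"counts within +-10 kb (same, reverse): "
      f"{neighbor_counts(focal, repeats, 10_000)}")

genic = select_genic_alus(repeats, [gene])
seq = ("GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGA"
       "TCACGAGGTCAGGAGATCGAGACCATCCTGGCTAACACGGTGAAACCCCGTCTCTACTAA")
revcomp = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
swap = "T" if revcomp[40] != "T" else "C"
mutated = revcomp[:40] + swap + revcomp[41:]
sequences = {"focal": seq, "partner": mutated,
             "decoy": seq, "same1": seq, "far": seq}

for feat in build_feature_table(genic, repeats, [gene], sequences):
    print(f"\n{feat.alu_id}: d={feat.d} bp to {feat.neighbor_id}, "
          f"Nss/Nrs(10k)={feat.nss_10k}/{feat.nrs_10k}, "
          f"segment relation: {feat.segment_relation}")
    if feat.pair_identity_pct is not None:
        print(f"  identity to neighbor (after reverse-complementing it): "
              f"{feat.pair_identity_pct:.1f}%")

print(f"\ndirect pair identity check: "
      f"{pair_identity(seq, mutated):.1f}% (one substitution in 120 bp)")
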