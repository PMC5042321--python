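"""Concordance screening of a ten-clone panel.

Builds the fixed synthetic panel (57 variants across 10 clones, with two
planted phenotype-linked variants), writes per-clone VarScan-style VCFs,
reads them back and screens for variants present in every
syntrophy-positive clone and absent from every negative one.
"""

import tempfile

from syntherm import (
    annotate_indel_frame, concordance_screen, make_paper_fixture,
    read_vcf_set, summarize_variant_counts, write_vcf_files,
)

matrix, labels = make_paper_fixture()
counts = summarize_variant_counts(matrix)
print(f"Panel: {len(matrix.clones)} clones, {counts['total']} variants "
      f"({counts['by_replicon']})")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_vcf_files(matrix, tmp)
    matrix = read_vcf_set(paths)  # full VCF round trip
print(f"Round-tripped through {len(paths)} per-clone VCF files.\n")

for mode in ("strict", "permissive"):
    res = concordance_screen(matrix, labels, mode)
    print(f"{mode:10s} screen → {len(res.candidates)} candidate(s)")
    for v in res.candidates:
        extra = f", {annotate_indel_frame(v)}" if v.vclass == "INDEL" else ""
        print(f"  {v.replicon}:{v.position} {v.ref}>{v.alt} ({v.vclass}{extra})")

print("\nThe strict screen finds nothing because two positive clones carry a"
      "\nmixed allele signature (~50% read support) at the causal loci;"
      "\npermissive mode accepts mixed evidence in positives and recovers"
      "\nexactly the two planted variants.")
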