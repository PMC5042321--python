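"""Codon-level consequences of screen hits on a coding sequence.

Demonstrates the two mutation classes the screen is built to explain: a
missense point mutation (Asp→Asn) and an in-frame 3-base deletion that
replaces a TGA codon — read either as a stop or as selenocysteine — with
TCG (serine).
"""

from syntherm import VariantRecord, annotate_indel_frame, codon_effect

# --- missense SNP, regulator-gene style -----------------------------------
cds = "ATGGATAAATAA"  # ATG | GAT | AAA | TAA
snp = VariantRecord("chromosome", 3_142_197, "G", "A")
ref_c, alt_c, note = codon_effect(cds, 3, snp)
print(f"SNP {snp.ref}>{snp.alt}: {ref_c[0]} → {alt_c[0]}  [{note}]")
print("  A single base exchange in the codon flips aspartate to asparagine.\n")

# --- in-frame GAG deletion, hydrogenase-subunit style ----------------------
cds = "ATGTGAGCGAAA"  # ATG | TGA | GCG | AAA
deletion = VariantRecord("chromosome", 2_381_876, "TGAG", "T")
print(f"Deletion {deletion.ref}>{deletion.alt}: {annotate_indel_frame(deletion)} "
      f"({len(deletion.ref) - len(deletion.alt)} bases removed)")
ref_c, alt_c, note = codon_effect(cds, 3, deletion)
print(f"  codons {'/'.join(ref_c)} → {'/'.join(alt_c)}  [{note}]")
print("  Removing GAG across a codon boundary converts TGA to TCG: the"
      "\n  stop-or-selenocysteine codon becomes serine, preserving the frame.")
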