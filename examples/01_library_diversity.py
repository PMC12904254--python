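"""Degenerate-codon expansion and theoretical library diversity.

The 11-position library randomizes five positions on chain A and six on
chain B with the DTS degenerate codon, which encodes the five hydrophobic
amino acids M/F/L/I/V through six DNA codons.
"""

from coevoscape import default_scheme, expand_degenerate_codon, theoretical_diversity

exp = expand_degenerate_codon("DTS")
print(f"DTS codons ({exp.codon_count}):", ", ".join(sorted(exp.codons)))
print(f"amino acids ({exp.aa_count}):", ", ".join(sorted(exp.amino_acids)))

scheme = default_scheme()
div = theoretical_diversity(scheme)
print(f"nucleotide diversity over {scheme.total_positions} positions: "
      f"{div.nucleotide:,} (~{div.nucleotide:.2e})")
print(f"protein diversity: {div.protein:,} (~{div.protein:.2e})")
# The DNA-level diversity (~3.6e8) is what a yeast-display library must
# cover; the protein-level diversity (5^11 ~ 4.9e7) is the size of the
# sequence space every downstream landscape analysis works on.
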