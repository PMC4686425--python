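"""Exact viability inference for allele-replacement clone counts.

After loop-in/loop-out allele replacement, 7 of 10 clones retained a
tolerated AA substitution, while 0 of 20 and 0 of 12 clones retained the
two phosphomimetic substitutions (DD, EE).  Fisher's exact test (computed
here by exact hypergeometric enumeration) quantifies how unlikely such a
complete absence is if the mutants were as viable as the AA strain.
"""

from kogbody.contingency import ContingencyTable, fisher_exact

cases = {
    "DD vs AA (0/20 vs 7/10)": ContingencyTable(7, 3, 0, 20),
    "EE vs AA (0/12 vs 7/10)": ContingencyTable(7, 3, 0, 12),
    "DD+EE vs AA (0/32 vs 7/10)": ContingencyTable(7, 3, 0, 32),
}
for name, table in cases.items():
    p1 = fisher_exact(table, "greater")
    p2 = fisher_exact(table, "two_sided")
    print(f"{name}: one-sided p = {p1:.3g}, two-sided p = {p2:.3g}")
print("\nSmall p-values mean the phosphomimetic alleles are very unlikely to "
      "be as recoverable as AA — i.e. they are effectively inviable.")
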