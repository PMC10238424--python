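"""How many dyes does each individual protein carry at a given aDoL?

The aDoL is a mean; with stochastic lysine labeling the per-molecule
label count is Poisson distributed around it.  Even at a modest aDoL of
2, a sizable minority of molecules is heavily labeled — the quantitative
argument for keeping the aDoL low.
"""

from clicklabel import fraction_at_least, multiplicity_table, pmf

table = multiplicity_table(adol=2.0, max_k=8)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print(f"\nexactly 3 labels:  {100 * pmf(3, 2.0):.1f}% of molecules")
print(f"4 or more labels:  {100 * fraction_at_least(4, 2.0):.1f}% of molecules")
print(f"unlabeled:         {100 * pmf(0, 2.0):.1f}% of molecules")
# At aDoL 2, ~18% of proteins carry exactly 3 dyes and ~14% carry 4 or
# more, while ~14% carry none at all.
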