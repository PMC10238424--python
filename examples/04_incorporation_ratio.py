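"""Count azide attachments by intact-protein mass spectrometry.

Simulates the deconvoluted mass ladder of apomyoglobin activated to an
incorporation ratio of 4.6 (each azidoacetyl adds 83.05 Da), assigns a
label count to every peak, and computes the intensity-weighted mean —
the I.R. — plus the activation efficiency for the 15x NHS excess used.
"""

from clicklabel import gen_ms_peaks, incorporation_ratio, lookup_protein

apomb = lookup_protein("apoMb")
peaks = gen_ms_peaks(apomb, ir=4.6, n_max=15, noise_rel=0.02, seed=1)

res = incorporation_ratio(peaks, molar_excess=15)
print("mass (Da)   intensity   labels")
for m, i, n in zip(peaks.masses, peaks.intensities, res.per_peak_counts):
    print(f"{m:9.1f}   {i:9.4f}   {n:6d}")
print(f"\nI.R. = {res.ir:.2f} azides/protein")
print(f"activation efficiency = {res.efficiency_pct}% of the 15x NHS excess")
# An I.R. of ~4.6 from a 15x excess is ~31% efficiency — the typical
# ~30% seen for incorporation ratios below about 5.
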