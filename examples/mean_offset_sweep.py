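"""Effect of unequal pathway means on phantom heritability.

Sweeps the mean offset between two pathway phenotypes (in sd units).  As
the offset grows, one pathway dominates the maximum, the trait becomes
effectively single-pathway, and the epistatic (phantom) component shrinks.
"""

from lptwin import fig2_sweeps

df = fig2_sweeps("mean_offset", grid=[0.0, 0.5, 1.0, 2.0],
                 n_families=30_000, n_reps=6, seed=1)

print("mean offset (sd)  phantom heritability")
for _, row in df.iterrows():
    print(f"{row.swept_value:15.1f}  {row.phantom:8.3f} +/- {row.phantom_se:.3f}")
print()
print("A one-sd mean difference roughly halves the phantom heritability")
print("relative to equal means; by two sd the second pathway rarely sets")
print("the maximum and almost no epistatic variance remains.")
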