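"""Minimal read counts from the binomial power model.

How many uniquely mapped reads does a depth-based caller need before a
single-copy CNV of a given length stands out from binomial sampling
noise?  The closed form n = 4 Z² (lg − lc) / lc answers this directly.
"""

from cnvscreen import min_length, min_reads, theory_table

LG = 3.1e9  # mappable genome length, bp

for z in (4, 7, 8):
    r = min_reads(z, 100_000, LG)
    print(f"Z = {z}: {r.exact/1e6:6.2f} M reads for a 100 kb CNV")

# The Z = 7 row says ~6.08 M reads: a 100 kb single-copy event needs at
# least 6 M uniquely mapped reads for Z > 7; at Z = 8 the requirement
# rounds to 8 M, a practical working depth with safety margin.

n = min_reads(8, 100_000, LG).exact
print(f"\nAt {n/1e6:.1f} M reads, the smallest Z=8-detectable CNV is "
      f"{min_length(8, n, LG)/1e3:.0f} kb (round trip of the formula).")

table = theory_table([4, 6, 8], [50_000, 100_000, 200_000, 1_000_000], LG)
print("\nminimal reads (millions) by Z and CNV length:")
print((table.pivot(index="cnv_length", columns="z", values="min_reads") / 1e6).round(2))
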