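"""D-statistics and F(A|B) derived-allele sharing for lineage assignment.

Four genomes with known topology ((P1, P3), P2) plus an outgroup:
D(P1, P2; P3, OUT) must be significantly positive (P3 shares more derived
alleles with its sister P1), and P3 carries a much larger share of the
derived alleles unique to P1 than of those unique to P2.
"""

from paleodiff import d_statistic, f_a_given_b, simulate_dataset, trio_config

cfg = trio_config(seed=5, topology="asymmetric", n_chrom=8, chrom_length=10e6)
table, gmap, _ = simulate_dataset(cfg)

d = d_statistic(table, "P1_0", "P2_0", "P3_0", "OUT_0", gmap=gmap)
print(f"D(P1, P2; P3, OUT) = {d.d:+.3f}  Z = {d.z:+.1f}  "
      f"({'significant' if d.significant else 'not significant'})")

shared = f_a_given_b(table, "P3_0", ["P1_0", "P2_0"])
uniq1 = f_a_given_b(table, "P3_0", ["P1_0"], exclude_derived_in=["P2_0"])
uniq2 = f_a_given_b(table, "P3_0", ["P2_0"], exclude_derived_in=["P1_0"])
print(f"F(P3 | derived in both P1 and P2)  = {shared.fraction:.2f}")
print(f"F(P3 | unique to P1)               = {uniq1.fraction:.2f}")
print(f"F(P3 | unique to P2)               = {uniq2.fraction:.2f}")
print()
print("Positive D with |Z| >= 3 rejects a symmetric relationship; the")
print("F(A|B) contrast assigns P3 to the P1 lineage, the same logic used")
print("to place an unknown archaic genome among reference genomes.")
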