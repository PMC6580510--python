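"""The reporting statistics: percentages, z tests, rank-sum tests.

Shows the arithmetic used for association tables on two published count
pairs, a worked two-proportion z test, and a small exact rank-sum test.
"""

from coldchrom import percent, proportion_ztest, wilcoxon_rank_sum

# percentage arithmetic used throughout the association tables
print("21430/50531 ->", percent(21430, 50531), "%")   # 42.4
print("6442/19482  ->", percent(6442, 19482), "%")    # 33.1

# pooled two-proportion z test, two-tailed probability
res = proportion_ztest(50, 100, 25, 100)
print(f"z = {res.z:.4f}, p = {res.p_two_tailed:.2e}")

# exact rank-sum on a tiny fully-separated pair: p = 2/C(6,3) = 0.1
u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
print(f"U = {u:.0f}, exact two-tailed p = {p}")
# The z test compares the fraction of genes in two classes harboring
# specific DHSs; the rank-sum test compares signal distributions.
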