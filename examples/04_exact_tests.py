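"""Exact small-sample nonparametric tests by full enumeration.

With groups of 3-6 participants, asymptotic p-values are unreliable; the
package enumerates the full null distribution instead: every rank
arrangement for the Mann-Whitney U, every permutation for Spearman.
"""

from nfloop import mannwhitney_exact, mannwhitney_exact_from_u, spearman_exact

# From a printed U statistic and group sizes (all C(12,6)=924 arrangements):
r = mannwhitney_exact_from_u(5, 6, 6)
print(f"U = 5, n = (6,6):  exact two-tailed p = {r.p:.4f}")
r = mannwhitney_exact_from_u(7, 5, 5)
print(f"U = 7, n = (5,5):  exact two-tailed p = {r.p:.4f}")

# From raw data (reaction times, ms):
fast = [3100, 3291, 3400, 2900, 3600, 3250]
slow = [5054, 4800, 5300, 4600, 5100, 3500]
r = mannwhitney_exact(fast, slow)
print(f"two samples of 6: U = {r.statistic:.0f}, exact p = {r.p:.4f} ({r.method})")

# Spearman with exact permutation p (all 5! = 120 pairings):
ados = [6, 8, 9, 12, 15]          # clinical severity scores
upreg = [0.10, 0.15, 0.21, 0.26, 0.40]  # per-subject mean up-regulation, %
r = spearman_exact(ados, upreg)
print(f"Spearman rho = {r.statistic:+.2f}, exact two-tailed p = {r.p:.4f}")
# A perfectly monotone pairing of 5 subjects: only 2 of 120 permutations
# are as extreme, so the smallest achievable p at n=5 is 0.0167.
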