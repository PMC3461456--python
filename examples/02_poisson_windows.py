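"""The Poisson scan arithmetic: window plan and p-values.

Shows how the window-size plan is derived from the total insertion count,
and how an anchored window's p-value responds to event count and window
size.
"""

from tnscan import ScanConfig, anchored_window_p, bonferroni_correct, \
    determine_window_sizes, poisson_upper_tail

cfg = ScanConfig(genome_size=2.5e9)

for total in (1_500, 20_000, 250_000):
    plan = determine_window_sizes(total, cfg)
    kind = "derived" if 2_000 <= total <= 200_000 else "default"
    print(f"{total:>7} insertions -> {len(plan):>2} window sizes ({kind}): "
          f"{plan[-1]:,} .. {plan[0]:,} bp")

# 8 insertions within a 25 kb window, 20,000 insertions genome-wide:
total, w = 20_000, 25_000
u = total * w / cfg.genome_size
p = anchored_window_p(8, u)
print(f"\nu = {u:.3f} expected events per {w:,} bp window")
print(f"P(7 more events join an anchored window) = {p:.3e}")
print(f"corrected by {total:,} windows: {bonferroni_correct(p, total):.3e}")

# The plain upper tail is exposed separately:
print(f"plain tail P(X >= 8 | u) = {poisson_upper_tail(8, u):.3e}")

# A window is called only when significant under insert, library AND
# region counting; the corrected p-values are what the CIS table reports.
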