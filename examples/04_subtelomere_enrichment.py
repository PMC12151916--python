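"""Test whether a gene set is enriched within 10 Mb of chromosome ends.

A 46-chromosome diploid karyotype contributes 92 subtelomeric windows.
The exact hypergeometric upper tail asks how surprising it is to see the
observed number of in-window genes when drawing the set uniformly from
the universe; the chi-square variant compares the in/out counts to the
universe proportion.
"""

from telomir import count_in_windows, enrichment_test, make_subtelomere_windows

sizes = {f"chr{i}": 120_000_000 for i in range(1, 47)}
windows = make_subtelomere_windows(sizes, span_bp=10_000_000)
print(f"{len(windows)} chromosome-end windows (two per chromosome)")

# a toy universe: 1000 genes, 200 of them subtelomeric; a query set of 50
# genes of which 18 are subtelomeric
universe_in, universe_n = 200, 1000
set_in, set_n = 18, 50
res = enrichment_test(set_in, set_n, universe_in, universe_n, "hypergeometric")
print(f"expected proportion {res.expected_proportion:.2f}, "
      f"observed {res.observed_proportion:.2f}")
print(f"hypergeometric upper-tail p = {res.p_value:.4f}")
res_chi = enrichment_test(set_in, set_n, universe_in, universe_n, "chisq")
print(f"chi-square statistic {res_chi.statistic:.2f}, p = {res_chi.p_value:.4f}")
# p < 0.05 would indicate the set concentrates near chromosome ends more
# than gene density alone explains.
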