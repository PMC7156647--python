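"""Independent brute-force oracles shared by the test suite.

These deliberately use naive O(n^2) loops rather than the package's
vectorized implementations, so agreement is a genuine cross-check.
"""


def brute_force_c(risk, times, events):
    """Exhaustive pairwise Harrell's concordance count."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            first_i = (times[i] < times[j] and events[i]) or (
                times[i] == times[j] and events[i] and not events[j]
            )
            if not first_i:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den
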