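"""Score a DASS-42 self-report and band each scale.

Builds a response with elevated depression items, sums each scale's 14
items, and maps the raw scores onto the five severity bands.
"""

from audass import SAQResponse, score_saq

# items 1-14 depression (high), 15-28 anxiety (low), 29-42 stress (moderate)
items = (3, 2, 3, 2, 3, 3, 2, 3, 2, 3, 3, 2, 3, 2) \
    + (0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0) \
    + (2, 1, 2, 1, 1, 2, 1, 2, 1, 1, 2, 1, 2, 1)

report = score_saq(SAQResponse(item_scores=items))
for scale, r in report.items():
    print(f"{scale:>10}: raw={r['raw']:>2}  band={r['band'].label}")

# The raw score is the sum of the scale's 14 item scores (0..42); the band
# is the severity interval containing it (e.g. depression 28+ is
# Extremely Severe).
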