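"""Locate the eye and mouth blocks in a binary face mask.

Simulates an elliptical face mask with row-profile peaks at 30% and 65%
of face height, then recovers the block median rows from the row profile
and validates them against the canonical face-height ratios (eyes in
[2/20, 9/20], mouth in [11/20, 15/20]).
"""

from audass import detect_blocks
from audass.synth import generate_face_mask

mask = generate_face_mask(H=120, W=100, eye_row_frac=0.30,
                          mouth_row_frac=0.65, noise=0.01, seed=42)
result = detect_blocks(mask)
print(f"eye block median row:   {result.eye_median_row:>3} "
      f"(fraction {result.eye_median_row / 120:.2f}, "
      f"valid={result.eye_valid})")
print(f"mouth block median row: {result.mouth_median_row:>3} "
      f"(fraction {result.mouth_median_row / 120:.2f}, "
      f"valid={result.mouth_valid})")

# A block is valid when the row with the most face pixels in its half of
# the mask falls inside the anatomical band for that feature.
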