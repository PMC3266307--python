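"""Show how perfect-match length maps to bit score and alignment tier.

A perfect n-base ungapped match scores n with +1/-3 scoring; the
Karlin-Altschul normalization (lambda = 1.374, K = 0.711) turns that into
roughly 2n bits, so the strong threshold of 48 bits corresponds to 24
identical bases and the moderate threshold of 32 bits to 16.
"""

from probemap import ScoringParams, bits, classify_bits

params = ScoringParams()

print(f"{'matches':>8}{'bits':>8}  tier")
for length in range(14, 26):
    b = bits(length, params)
    print(f"{length:>8}{b:>8.2f}  {classify_bits(b, params)}")

print(
    "\nA probe needs 24 of its 25 bases identical to a transcript to count\n"
    "as a strong (reliable) detector; 16-23 bases give an ambiguous\n"
    "moderate alignment, and anything shorter is unlikely to hybridize."
)
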