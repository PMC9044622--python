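"""Estimate a nucleus threshold from a histogram's first peak and valley.

Builds one synthetic blood-smear image, walks through the estimation
steps explicitly — initial value, histogram, smoothed-segment extrema,
branch rule — and prints each intermediate quantity.
"""

import numpy as np

from lminseg import (
    FixtureSpec,
    compute_histogram,
    compute_initial_value,
    estimate_threshold,
    generate_cell_image,
    search_extrema_with_extension,
)

spec = FixtureSpec(random_seed=42)
gray, truth, _ = generate_cell_image(spec)

t0 = compute_initial_value(gray, n1=3, n2=3)
hist = compute_histogram(gray, nbins=256)
pair = search_extrema_with_extension(hist)
est = estimate_threshold(t0, pair, Er=0.07)

print(f"image extremes        Min={gray.min():.4f}  Max={gray.max():.4f}")
print(f"initial value T_nc0   {t0:.4f}   (Max/3 + Min/3, near 1/3)")
print(f"first peak x_c        {pair.x_c:.4f}   (first turning point of the")
print(f"first valley x_c1     {pair.x_c1:.4f}    smoothed histogram)")
print(f"branch                {est.branch!r}")
print(f"threshold eps_t       {est.epsilon_t:.4f}")
print()
print(
    "eps_t separates the dark nucleus from the brighter cytoplasm: it lies\n"
    f"between the class means {spec.nucleus_mean} and {spec.cytoplasm_mean} "
    "used to render the image."
)
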