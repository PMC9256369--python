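"""Apply each contrast-enhancement operator to one phantom green channel
and compare no-reference quality measures.

Sharpness is the mean gradient magnitude; entropy (bits, 256 bins)
summarizes how widely the intensities are spread.
"""

from gaborvessel import (
    PhantomConfig,
    PsoConfig,
    adaptive_usm_enhance_gray,
    gcadw_enhance,
    generate_phantom,
    homomorphic_enhance,
    jeh_equalize,
    pso_usm_enhance,
    shannon_entropy,
    sharpness_measure,
    unsharp_enhance,
)

img, _, _ = generate_phantom(PhantomConfig(seed=0))
green = img.green

variants = {
    "green channel": green,
    "gcadw": gcadw_enhance(green),
    "homomorphic": homomorphic_enhance(green),
    "jeh": jeh_equalize(green),
    "unsharp": unsharp_enhance(green),
    "adaptive unsharp": adaptive_usm_enhance_gray(green),
    "pso unsharp": pso_usm_enhance(green, PsoConfig(max_iterations=20, swarm_size=15, seed=0)),
}

print(f"{'variant':<18} {'sharpness':>9} {'entropy':>8}")
for name, out in variants.items():
    print(f"{name:<18} {sharpness_measure(out):>9.4f} {shannon_entropy(out):>8.3f}")
print()
print("Every operator raises sharpness and/or spreads the histogram relative")
print("to the raw green channel; which one helps segmentation depends on how")
print("much background noise it amplifies along with the vessels.")
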