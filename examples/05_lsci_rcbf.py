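"""Relative blood flow from speckle contrast: conventional vs n=0.5 model.

Simulates baseline and 10x-slowed multiple-scattering (n = 0.5) speckle,
emulates a ~5 ms exposure, and compares the conventional contrast-ratio
flow estimate against inversion of the n = 0.5 contrast model.
"""

from dlsi.validation import lsci_directional_benchmark

r = lsci_directional_benchmark(1, h=6, w=6)
print(f"mean contrast: baseline K = {r['K_baseline']:.3f}, "
      f"slowed K = {r['K_slowed']:.3f}")
print(f"true relative flow:            {r['true_rcbf']:.2f}")
print(f"conventional contrast ratio:   {r['rcbf_lsci']:.3f}"
      f"  (error {abs(r['rcbf_lsci'] - 0.1):.3f})")
print(f"n=0.5 model inversion:         {r['rcbf_lsci_n05']:.3f}"
      f"  (error {abs(r['rcbf_lsci_n05'] - 0.1):.3f})")
print("Assuming n=1 dynamics (the conventional contrast-ratio model) badly"
      " overestimates residual flow when the true dynamics follow n=0.5;"
      " inverting the n=0.5 model removes most of that error.")
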