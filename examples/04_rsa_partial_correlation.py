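"""Representational similarity analysis with image-property control.

Builds synthetic face rasters whose pixel structure tracks identity, a
128-dimensional face-embedding set, and a neural dissimilarity structure
containing an identity component (partly image-driven) plus an
image-independent expression component.  Correlating model RDMs with the
neural RDM, with and without partialling out the image-similarity model,
reproduces the logic of controlling low-level visual properties: the
identity correlation is diminished, the expression correlation is not.
"""

import warnings

warnings.filterwarnings("ignore")

from facedecode import protocols

res = protocols.attenuation_recovery(seed=0)

print("Spearman correlation of the neural RDM with each model RDM:")
print(f"  identity model:   plain rho = {res['identity_plain']:.3f}, "
      f"image partialled out = {res['identity_partial_image']:.3f}")
print(f"  expression model: plain rho = {res['expression_plain']:.3f}, "
      f"image partialled out = {res['expression_partial_image']:.3f}")
print()
print("controlling for maximum image cross-correlation attenuates the")
print("identity correlation (identity structure is partly carried by the")
print("images themselves) but leaves the expression correlation intact —")
print("an image-independent neural effect survives the partial correlation.")
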