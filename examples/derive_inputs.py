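"""Derive the model's input rasters from raw bands and history layers.

Synthetic Red/NIR/SWIR reflectances are built as mixtures of the three
spectral endmembers (green vegetation, dry vegetation, soil), then the
preprocessing chain recovers: NDWI moisture, the dry-biomass (fuel)
fraction by constrained unmixing, the burn probability from fuel x
relative historical burn frequency, and combustion rates from
vegetation height classes.
"""

import numpy as np

from pyrocell.preprocess import (BurnHistory, EndmemberSet,
                                 burn_probability, dry_biomass_fraction,
                                 ndwi, vegetation_class)

rng = np.random.default_rng(3)
shape = (8, 8)
em = EndmemberSet()

# pixels are random green/dry/soil mixtures -> known dry fraction
weights = rng.dirichlet(np.ones(3), size=shape)
m = em.matrix()
spectra = weights @ m.T
red, nir, swir = spectra[..., 0], spectra[..., 1], spectra[..., 2]

moisture = ndwi(nir, swir)
fuel = dry_biomass_fraction(red, nir, swir, em)
true_dry = weights[..., 1]
print(f"moisture (scaled NDWI): {moisture.min():.3f} .. {moisture.max():.3f}")
print(f"unmixing error on the dry fraction: "
      f"{np.abs(fuel - true_dry).max():.2e}")

history = BurnHistory(burn_frequency=rng.poisson(3.0, shape))
prob = burn_probability(fuel, history)
print(f"burn probability: mean {prob.mean():.3f}, "
      f"zero wherever fuel or history is zero")

height = rng.uniform(0.0, 4.0, shape)
classes, rates = vegetation_class(height)
for code, label in {1: "grass", 2: "herbaceous", 3: "shrub",
                    4: "tree"}.items():
    n = int((classes == code).sum())
    if n:
        rate = rates[classes == code][0]
        print(f"class {label}: {n} cells, combustion rate {rate}")
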