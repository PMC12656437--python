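"""The three false-positive rules on crafted spectra.

Builds one pixel of each interesting kind, runs the rule stage, and prints
what happened and why.
"""

import numpy as np

from hyperfod import default_taxonomy
from hyperfod.cube_io import Hypercube, default_wavelength_grid
from hyperfod.postproc import PredictionMap, apply_spectral_rules

tax = default_taxonomy()
wl = default_wavelength_grid()[20:204]
band = lambda w: int(np.argmin(np.abs(wl - w)))

cases = []  # (description, spectrum, predicted class)

fat_like = np.full(184, 0.5)
fat_like[band(1225.5)] = 0.70  # 1222 nm rise, no 1409 nm step
fat_like[band(1211.5)] = 0.50
cases.append(("fat-like pixel the model called PEHD", fat_like, "pehd"))

true_pehd = fat_like.copy()
true_pehd[band(1411.0)] = 0.85  # the sharp PEHD step: ratio >= 1.04
true_pehd[band(1117.0)] = 0.45
true_pehd[band(1099.5)] = 0.55
cases.append(("true PEHD pixel (sharp 1409 nm step)", true_pehd, "pehd"))

belt_like = np.full(184, 0.5)
belt_like[band(1117.0)] = 0.68  # belt-like rise toward 1117 nm
belt_like[band(1099.5)] = 0.45
belt_like[band(1225.5)] = 0.40  # rule 1 diff clause false
cases.append(("belt-like pixel the model called PEHD", belt_like, "pehd"))

meat_like = np.full(184, 0.5)
meat_like[band(1232.5)] = 0.70  # no sharp 1225 nm peak
meat_like[band(1012.0)] = 0.40
cases.append(("meat-like pixel the model called PA-PP", meat_like, "pa_pp"))

for description, spectrum, predicted in cases:
    cube = Hypercube(
        data=spectrum.reshape(1, 1, 184).astype(np.float32), wavelengths=wl, state="normalized184"
    )
    pred = PredictionMap(labels=np.array([[tax.index_of(predicted)]], dtype=np.uint8))
    out = apply_spectral_rules(pred, cube)
    print(f"{description}:")
    print(f"   predicted {predicted!r} -> relabelled {tax.name_of(int(out.labels[0, 0]))!r}")

print()
print("The rules only ever move pixels toward background classes; genuine")
print("PEHD and PA-PP spectra keep their labels via the 1409 nm step and the")
print("1225 nm peak respectively.")
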